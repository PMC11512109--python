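"""Method-agreement statistics for validating automated angle measurement.

Implements the comparison toolkit used to validate an automated
measurement method against manual references: Pearson correlation, mean
absolute error, Model II regression by Ordinary Least Products (the
geometric-mean / standardized-major-axis fit, appropriate when both
methods carry measurement error), Bland-Altman limits of agreement,
pairwise annotator-agreement matrices, and a permutation analysis of how
the correlation stabilizes as the number of measured images grows.

Orientation convention: the manual (reference) measurement is the
response and the automated one the predictor, so the fitted line reads
``manual = intercept + slope * automated``; differences in the
Bland-Altman analysis are ``manual - automated``, making automated
overestimation a negative bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements", "OLPFit", "BlandAltman", "pearson", "mae",
    "fit_olp", "bland_altman", "apply_olp_correction", "annotator_matrix",
    "stability_curve",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Automated (``a``) and manual/reference (``m``) angle vectors, and
    optionally the simulated truth they were generated from."""

    a: np.ndarray
    m: np.ndarray
    truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "m", m)
        if a.shape != m.shape or a.ndim != 1:
            raise ValueError("a and m must be 1-D vectors of equal length")
        if np.isnan(a).any() or np.isnan(m).any():
            raise ValueError("missing entries are not allowed")

    @property
    def n(self) -> int:
        return int(self.a.size)


@dataclass(frozen=True)
class OLPFit:
    """Ordinary Least Products (SMA) fit of manual on automated.

    ``fixed_bias_flag`` is set when the intercept's 95% CI excludes zero,
    ``proportional_bias_flag`` when the slope's 95% CI excludes one.
    """

    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    r: float
    n: int

    @property
    def fixed_bias_flag(self) -> bool:
        lo, hi = self.intercept_ci
        return not (lo <= 0.0 <= hi)

    @property
    def proportional_bias_flag(self) -> bool:
        lo, hi = self.slope_ci
        return not (lo <= 1.0 <= hi)


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman summary of differences manual - automated."""

    bias: float
    sd_diff: float

    @property
    def loa_low(self) -> float:
        return self.bias - 1.96 * self.sd_diff

    @property
    def loa_high(self) -> float:
        return self.bias + 1.96 * self.sd_diff


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def mae(x: Sequence[float], y: Sequence[float]) -> float:
    """Mean absolute error between two measurement vectors (degrees)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    return float(np.mean(np.abs(x - y)))


def fit_olp(paired: PairedMeasurements) -> OLPFit:
    """Model II regression of manual on automated by Ordinary Least
    Products (geometric-mean / SMA estimator).

    slope = sign(r) * sd(m) / sd(a); intercept = mean(m) - slope*mean(a).
    95% CIs use the standard SMA closed form: the slope interval is
    slope*(sqrt(B+1) +/- sqrt(B)) with B = (1-r^2)*F(0.95; 1, n-2)/(n-2),
    and the intercept interval is propagated through the slope interval at
    the sample means.
    """
    a, m = paired.a, paired.m
    _check_pair(a, m)
    n = a.size
    if np.ptp(a) == 0 or np.ptp(m) == 0:
        raise ValueError("OLP fit undefined for constant measurements")
    r = pearson(a, m)
    if r == 0.0:
        raise ValueError("OLP slope sign undefined at r = 0")
    sd_a = float(np.std(a, ddof=1))
    sd_m = float(np.std(m, ddof=1))
    slope = float(np.sign(r)) * sd_m / sd_a
    intercept = float(np.mean(m)) - slope * float(np.mean(a))
    fcrit = float(stats.f.ppf(0.95, 1, n - 2))
    B = (1.0 - r * r) * fcrit / (n - 2)
    ends = sorted((slope * (np.sqrt(B + 1.0) - np.sqrt(B)),
                   slope * (np.sqrt(B + 1.0) + np.sqrt(B))))
    slope_ci = (float(ends[0]), float(ends[1]))
    icpts = sorted(float(np.mean(m)) - b * float(np.mean(a)) for b in slope_ci)
    return OLPFit(
        slope=slope,
        intercept=intercept,
        slope_ci=slope_ci,
        intercept_ci=(icpts[0], icpts[1]),
        r=r,
        n=n,
    )


def bland_altman(paired: PairedMeasurements) -> BlandAltman:
    """Mean difference (manual - automated) and its sample sd; limits of
    agreement are bias +/- 1.96 sd."""
    if paired.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = paired.m - paired.a
    return BlandAltman(bias=float(np.mean(d)), sd_diff=float(np.std(d, ddof=1)))


def apply_olp_correction(a: Sequence[float], fit: OLPFit) -> np.ndarray:
    """Map automated measurements onto the manual scale through the fitted
    line: corrected = intercept + slope * a.

    Refitting corrected-vs-manual then yields slope ~ 1 and intercept ~ 0.
    Refuses to correct when the slope CI contains zero (direction of the
    relationship not established).
    """
    lo, hi = fit.slope_ci
    if lo <= 0.0 <= hi:
        raise ValueError("slope CI contains 0; correction refused")
    return fit.intercept + fit.slope * np.asarray(a, dtype=float)


def annotator_matrix(measurements: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Pairwise Pearson r and MAE between annotator measurement vectors.

    Returns a tidy frame with one row per unordered pair plus summary
    rows ("mean", "sd") aggregating each statistic across pairs.
    """
    vecs = [np.asarray(v, dtype=float) for v in measurements]
    if len(vecs) < 2:
        raise ValueError("need at least two annotators")
    rows = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            rows.append(
                {
                    "pair": f"{i}-{j}",
                    "r": pearson(vecs[i], vecs[j]),
                    "mae": mae(vecs[i], vecs[j]),
                }
            )
    df = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "pair": ["mean", "sd"],
            "r": [df["r"].mean(), df["r"].std(ddof=1) if len(df) > 1 else 0.0],
            "mae": [df["mae"].mean(), df["mae"].std(ddof=1) if len(df) > 1 else 0.0],
        }
    )
    return pd.concat([df, summary], ignore_index=True)


def stability_curve(
    paired: PairedMeasurements,
    n_permutations: int = 100,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """How the running correlation stabilizes with the number of images.

    For each random permutation of the pairs, computes Pearson r over
    growing prefixes (count = 3..n); returns mean and sd of r across
    permutations at each count. Deterministic given ``rng_seed``.
    """
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    a, m = paired.a, paired.m
    _check_pair(a, m)
    n = a.size
    rng = np.random.default_rng(rng_seed)
    counts = np.arange(3, n + 1)
    rs = np.empty((n_permutations, counts.size))
    for k in range(n_permutations):
        idx = rng.permutation(n)
        x, y = a[idx], m[idx]
        cx, cy = np.cumsum(x), np.cumsum(y)
        cxx, cyy, cxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
        c = counts.astype(float)
        i = counts - 1
        sxy = cxy[i] - cx[i] * cy[i] / c
        sxx = cxx[i] - cx[i] ** 2 / c
        syy = cyy[i] - cy[i] ** 2 / c
        with np.errstate(invalid="ignore", divide="ignore"):
            rs[k] = sxy / np.sqrt(sxx * syy)
    return pd.DataFrame(
        {
            "count": counts,
            "mean_r": rs.mean(axis=0),
            "sd_r": rs.std(axis=0, ddof=1),
        }
    )
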