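"""Bayesian variable selection (BVS) for QTL mapping of root traits.

Linear mixed model for a root trait y (total root length or seminal root
angle) over n plants and p markers:

    y = 1*mu + X beta + Z gamma + W delta + V alpha [+ Y phi] + eps

where X holds genotypes coded -1/0/1 and column-centred, and the Z/W/V/Y
terms are random effects for glasshouse block, position nested in block,
growth-degree-days nested in line, and (for the angle trait) the combined
seed x replicate x block effect, each ~ N(0, I sigma^2) with improper
uniform priors on all variances.

Marker effects carry a spike-and-slab mixture prior: beta_i ~ N(0, tau0^2)
if the indicator zeta_i = 0 (spike, negligible effects) and N(0, tau1^2)
if zeta_i = 1 (slab, real effects), with the spike locked to the slab by
tau0^2 = 0.01 tau1^2. P(zeta_i = 0) = pi0 with prior pi0 ~ Beta(100, 1),
so a priori almost all markers are spike members.

The MCMC sampler follows the blocked scheme the model was designed for:
marker effects are drawn jointly in blocks of 10 from their conditional
multivariate normal; indicators are drawn jointly in random pairs with the
pair's effects integrated out (all four configurations scored by marginal
likelihood); the slab variance moves by a log-scale Metropolis-Hastings
step with the spike locked in ratio; pi0 and all remaining effects and
variances are Gibbs updates. Markers are processed in genome order
(chromosome, position), making results invariant to input column order.

Evidence per marker is the posterior inclusion probability (PIP, the
posterior mean of zeta) and the Bayes factor of posterior to prior
inclusion odds; BF > 5 is "strong" evidence, 3.2-5 "putative".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("rootangle")

__all__ = [
    "GenotypeMatrix", "DesignMatrices", "BVSPriors", "ChainConfig",
    "BVSResult", "center_genotypes", "run_bvs", "bayes_factors",
    "classify_qtls", "cohens_d", "simulate_qtl_data",
]


@dataclass
class GenotypeMatrix:
    """Genotypes for n individuals at p markers.

    ``raw`` holds the -1/0/1 allele-count coding; ``X`` the column-centred
    view used by the model. ``maf`` is the minor allele frequency computed
    from the raw coding.
    """

    raw: np.ndarray
    ids: List[str]
    chrom: np.ndarray
    pos: np.ndarray
    X: np.ndarray = field(init=False)
    maf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw)
        if not np.isin(raw, (-1, 0, 1)).all():
            raise ValueError("raw genotype entries must be -1, 0 or 1")
        self.raw = raw.astype(np.int8)
        self.X = np.ascontiguousarray(raw - raw.mean(axis=0), dtype=np.float64)
        f = (self.raw + 1).mean(axis=0) / 2.0  # frequency of the +1 allele
        self.maf = np.minimum(f, 1.0 - f)

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    @property
    def p(self) -> int:
        return self.raw.shape[1]


@dataclass(frozen=True)
class DesignMatrices:
    """Random-effect factor assignments, one level index per individual.

    Each entry maps a factor name ("block", "position", "gdd", and
    optionally "seed_rep_block" for the angle model) to an integer level
    vector of length n; levels are 0-based and dense. Equivalent to 0/1
    incidence matrices whose rows each sum to one.
    """

    factors: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, idx in self.factors.items():
            idx = np.asarray(idx)
            if idx.ndim != 1 or idx.min() < 0:
                raise ValueError(f"factor {name}: need a 1-D 0-based level vector")
            object.__setattr__(
                self, "factors",
                {**self.factors, name: idx.astype(np.intp)},
            )

    def n_levels(self, name: str) -> int:
        return int(self.factors[name].max()) + 1


@dataclass(frozen=True)
class BVSPriors:
    """Mixture-prior hyperparameters.

    ``tau_ratio`` locks the spike to the slab (tau0^2 = tau_ratio*tau1^2);
    ``pi0_beta`` parameterizes the Beta prior on the spike probability;
    variances carry improper uniform priors on (0, inf).
    """

    tau_ratio: float = 0.01
    pi0_beta: Tuple[float, float] = (100.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_ratio < 1.0):
            raise ValueError("tau_ratio must lie in (0, 1)")
        if min(self.pi0_beta) <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def prior_inclusion_odds(self) -> float:
        """Prior odds of inclusion at the prior mean of pi0."""
        a, b = self.pi0_beta
        e_pi0 = a / (a + b)
        return (1.0 - e_pi0) / e_pi0


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run-length and blocking configuration.

    Production default is a single long chain of 250 000 sweeps with a
    20 000-sweep burn-in; calibration and test runs scale this down.
    """

    iterations: int = 250_000
    burn_in: int = 20_000
    thinning: int = 10
    rng_seed: int = 0
    beta_block_size: int = 10
    zeta_group_size: int = 2
    mh_initial_step: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("require 0 <= burn_in < iterations")
        if self.beta_block_size < 1 or self.zeta_group_size < 1:
            raise ValueError("block/group sizes must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class BVSResult:
    """Posterior summaries per marker plus model-level posteriors."""

    marker_ids: List[str]
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    pip: np.ndarray
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    bf: np.ndarray
    classes: np.ndarray
    mu_mean: float
    mu_sd: float
    pi0_mean: float
    tau1sq_mean: float
    sigma_e2_mean: float
    variance_means: Dict[str, float]
    variance_sds: Dict[str, float]
    mh_acceptance: float
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        """Per-marker results table (one row per marker, genome order of
        the input)."""
        return pd.DataFrame(
            {
                "snpID": self.marker_ids,
                "chr": self.chrom,
                "pos": self.pos,
                "MAF": self.maf,
                "effect": self.beta_mean,
                "effect_sd": self.beta_sd,
                "PIP": self.pip,
                "BF": self.bf,
                "class": self.classes,
            }
        )


def center_genotypes(
    raw: np.ndarray,
    ids: Optional[Sequence[str]] = None,
    chrom: Optional[Sequence] = None,
    pos: Optional[Sequence[int]] = None,
) -> GenotypeMatrix:
    """Validate and column-centre a raw -1/0/1 genotype matrix.

    Missing genotypes are an error (imputation is out of scope);
    monomorphic columns are dropped with a warning.
    """
    raw = np.asarray(raw)
    if np.ma.isMaskedArray(raw) or (
        np.issubdtype(raw.dtype, np.floating) and np.isnan(raw.astype(float)).any()
    ):
        raise ValueError("missing genotypes are not supported")
    if raw.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (individuals x markers)")
    if not np.isin(raw, (-1, 0, 1)).all():
        raise ValueError("genotype entries must be coded -1, 0 or 1")
    p = raw.shape[1]
    ids = list(ids) if ids is not None else [f"M{j:05d}" for j in range(p)]
    chrom = np.asarray(chrom if chrom is not None else ["1"] * p)
    pos = np.asarray(pos if pos is not None else np.arange(p))
    poly = raw.min(axis=0) != raw.max(axis=0)
    if not poly.all():
        dropped = [ids[j] for j in np.nonzero(~poly)[0]]
        logger.warning("dropping %d monomorphic markers: %s",
                       len(dropped), ", ".join(dropped[:10]))
    keep = np.nonzero(poly)[0]
    return GenotypeMatrix(
        raw=raw[:, keep],
        ids=[ids[j] for j in keep],
        chrom=chrom[keep],
        pos=pos[keep],
    )


def bayes_factors(pip: np.ndarray, priors: BVSPriors = BVSPriors()) -> np.ndarray:
    """Bayes factor per marker: posterior over prior inclusion odds.

    Prior odds are evaluated at the prior mean of pi0 (1/100 under the
    default Beta(100, 1)). A PIP of exactly 1 yields +inf.
    """
    pip = np.asarray(pip, dtype=float)
    if ((pip < 0) | (pip > 1)).any():
        raise ValueError("PIP values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        post_odds = pip / (1.0 - pip)
    return post_odds / priors.prior_inclusion_odds


def classify_qtls(bf: np.ndarray) -> np.ndarray:
    """Evidence classes: BF > 5 'strong', 3.2 <= BF <= 5 'putative',
    else 'none' (both boundaries counted as putative)."""
    bf = np.asarray(bf, dtype=float)
    out = np.full(bf.shape, "none", dtype=object)
    out[(bf >= 3.2) & (bf <= 5.0)] = "putative"
    out[bf > 5.0] = "strong"
    return out


def cohens_d(y: np.ndarray, raw_genotypes: np.ndarray) -> float:
    """Standardized trait difference between minor-allele carriers and
    major-allele homozygotes (pooled-sd denominator, n-1 variances)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(raw_genotypes)
    if not np.isin(g, (-1, 0, 1)).all():
        raise ValueError("genotype column must be coded -1, 0 or 1")
    f_plus = (g + 1).mean() / 2.0
    minor_is_plus = f_plus <= 0.5
    carriers = g >= 0 if minor_is_plus else g <= 0
    majors = ~carriers
    y1, y2 = y[carriers], y[majors]
    if y1.size < 2 or y2.size < 2:
        raise ValueError("each allele group needs at least 2 members")
    s1, s2 = y1.var(ddof=1), y2.var(ddof=1)
    pooled = math.sqrt(
        ((y1.size - 1) * s1 + (y2.size - 1) * s2) / (y1.size + y2.size - 2)
    )
    if pooled == 0:
        raise ValueError("pooled sd is zero")
    return float((y1.mean() - y2.mean()) / pooled)


# ---------------------------------------------------------------------------
# MCMC sampler


def _chi2_draw(rng: np.random.Generator, df: float) -> float:
    return float(rng.chisquare(df))


def run_bvs(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    design: Optional[DesignMatrices],
    priors: BVSPriors = BVSPriors(),
    chain: ChainConfig = ChainConfig(),
    include_intercept: bool = True,
    fix_zeta: Optional[np.ndarray] = None,
    fix_variances: Optional[Dict[str, float]] = None,
) -> BVSResult:
    """Run the blocked MCMC sampler and summarize the posterior.

    Fully reproducible given ``chain.rng_seed``. ``fix_zeta`` pins the
    indicator vector (e.g. all ones, reducing the marker tier to ridge
    regression) and ``fix_variances`` pins named variance parameters
    ("tau1sq", "sigma_e2"); both exist for calibration and validation.

    Raises on non-finite state; warns if the slab-variance MH acceptance
    rate ends outside [0.1, 0.7].
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != genotypes.n:
        raise ValueError("phenotype and genotype dimensions differ")
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    fixed = dict(fix_variances or {})

    # genome order makes the blocking invariant to input column order
    order = np.lexsort(
        (np.asarray(genotypes.ids, dtype=object),
         np.asarray(genotypes.pos),
         np.asarray(genotypes.chrom, dtype=object))
    )
    X = np.ascontiguousarray(genotypes.X[:, order])
    p = X.shape[1]
    rng = np.random.default_rng(chain.rng_seed)

    factors: Dict[str, Tuple[np.ndarray, int, np.ndarray]] = {}
    if design is not None:
        for name, idx in design.factors.items():
            nlev = int(idx.max()) + 1
            counts = np.bincount(idx, minlength=nlev).astype(float)
            factors[name] = (idx, nlev, counts)

    # --- initial state
    var_y = float(np.var(y)) or 1.0
    mu = float(np.mean(y)) if include_intercept else 0.0
    beta = np.zeros(p)
    if fix_zeta is not None:
        zeta = np.asarray(fix_zeta, dtype=bool).copy()
        if zeta.size != p:
            raise ValueError("fix_zeta length mismatch")
        zeta = zeta[order]
    else:
        zeta = np.zeros(p, dtype=bool)
    tau1sq = fixed.get("tau1sq", var_y / 10.0)
    sigma_e2 = fixed.get("sigma_e2", var_y / 2.0)
    pi0 = priors.pi0_beta[0] / sum(priors.pi0_beta)
    effects = {name: np.zeros(nlev) for name, (idx, nlev, _) in factors.items()}
    variances = {name: var_y / 10.0 for name in factors}

    r = y - mu  # running residual (all current effects subtracted)

    # precomputations for the marker updates
    bs = chain.beta_block_size
    blocks = [np.arange(s, min(s + bs, p)) for s in range(0, p, bs)]
    grams = [X[:, b].T @ X[:, b] for b in blocks]
    G = X.T @ X  # p x p Gram for the pair-marginal zeta update
    diag_G = np.ascontiguousarray(np.diag(G))
    Xcols = [np.ascontiguousarray(X[:, j]) for j in range(p)]

    mh_step = chain.mh_initial_step
    mh_acc = mh_att = 0
    mh_acc_window = mh_att_window = 0
    a0, b0 = priors.pi0_beta

    # accumulators
    keep = 0
    zeta_sum = np.zeros(p)
    beta_sum = np.zeros(p)
    beta_sumsq = np.zeros(p)
    mu_sum = mu_sumsq = 0.0
    pi0_sum = tau1_sum = sige_sum = 0.0
    var_sums = {name: 0.0 for name in factors}
    var_sumsqs = {name: 0.0 for name in factors}

    log_ratio = math.log(priors.tau_ratio)

    for sweep in range(chain.iterations):
        tau0sq = priors.tau_ratio * tau1sq
        # (i) beta in consecutive blocks from conditional MVN
        inv_se = 1.0 / sigma_e2
        for b, Gb in zip(blocks, grams):
            Xb = X[:, b]
            r += Xb @ beta[b]
            prior_prec = np.where(zeta[b], 1.0 / tau1sq, 1.0 / tau0sq)
            A = Gb * inv_se
            A[np.diag_indices_from(A)] += prior_prec
            rhs = (r @ Xb) * inv_se
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, rhs)
            z = rng.standard_normal(b.size)
            draw = mean + np.linalg.solve(L.T, z)
            beta[b] = draw
            r -= Xb @ draw

        # (ii) zeta in random pairs, marker effects integrated out
        if fix_zeta is None:
            perm = rng.permutation(p)
            log_pi0 = math.log(pi0)
            log_pi1 = math.log(1.0 - pi0)
            n_pairs = p // 2
            unif = rng.random(n_pairs)
            norms = rng.standard_normal((n_pairs, 2))
            for k in range(n_pairs):
                i = int(perm[2 * k])
                j = int(perm[2 * k + 1])
                xi, xj = Xcols[i], Xcols[j]
                bi, bj = beta[i], beta[j]
                if bi != 0.0 or bj != 0.0:
                    r += xi * bi + xj * bj
                vi = float(xi @ r)
                vj = float(xj @ r)
                sii = diag_G[i] * inv_se
                sjj = diag_G[j] * inv_se
                sij = G[i, j] * inv_se
                scores = []
                cache = []
                for zi in (0, 1):
                    ti = tau1sq if zi else tau0sq
                    for zj in (0, 1):
                        tj = tau1sq if zj else tau0sq
                        m11 = 1.0 / ti + sii
                        m22 = 1.0 / tj + sjj
                        det = m11 * m22 - sij * sij
                        # quadratic form v^T M^{-1} v / sigma_e2^2
                        q = (
                            (m22 * vi * vi - 2.0 * sij * vi * vj + m11 * vj * vj)
                            / det
                        ) * inv_se * inv_se
                        score = (
                            (log_pi1 if zi else log_pi0)
                            + (log_pi1 if zj else log_pi0)
                            - 0.5 * (math.log(ti) + math.log(tj) + math.log(det))
                            + 0.5 * q
                        )
                        scores.append(score)
                        cache.append((m11, m22, det, ti, tj))
                mx = max(scores)
                ws = [math.exp(s - mx) for s in scores]
                tot = ws[0] + ws[1] + ws[2] + ws[3]
                u = unif[k] * tot
                cfg = 0
                acc = ws[0]
                while acc < u and cfg < 3:
                    cfg += 1
                    acc += ws[cfg]
                zeta[i] = bool(cfg >> 1)
                zeta[j] = bool(cfg & 1)
                # redraw the pair's effects from their joint conditional
                m11, m22, det, ti, tj = cache[cfg]
                # posterior covariance = M^{-1}; mean = M^{-1} v / sigma_e2
                mean_i = (m22 * vi - sij * vj) / det * inv_se
                mean_j = (m11 * vj - sij * vi) / det * inv_se
                # Cholesky of M^{-1} from M (2x2)
                l11 = math.sqrt(m11)
                l21 = sij / l11
                l22 = math.sqrt(max(m22 - l21 * l21, 1e-300))
                z1, z2 = norms[k]
                # solve L^T u = z for u: upper triangular back-substitution
                u2 = z2 / l22
                u1 = (z1 - l21 * u2) / l11
                bi_new = mean_i + u1
                bj_new = mean_j + u2
                beta[i] = bi_new
                beta[j] = bj_new
                r -= xi * bi_new + xj * bj_new

        # (iii) slab variance by log-scale random-walk MH, spike locked
        if "tau1sq" not in fixed:
            n1 = int(zeta.sum())
            n0 = p - n1
            ssq1 = float(beta[zeta] @ beta[zeta]) if n1 else 0.0
            ssq0 = float(beta[~zeta] @ beta[~zeta]) if n0 else 0.0

            def log_target(t1: float) -> float:
                t0 = priors.tau_ratio * t1
                return -0.5 * (
                    n1 * math.log(t1) + n0 * math.log(t0)
                    + ssq1 / t1 + ssq0 / t0
                )

            prop = tau1sq * math.exp(mh_step * rng.standard_normal())
            log_acc = (
                log_target(prop) - log_target(tau1sq)
                + math.log(prop) - math.log(tau1sq)  # Jacobian, flat prior
            )
            mh_att += 1
            mh_att_window += 1
            if math.log(rng.random()) < log_acc:
                tau1sq = prop
                mh_acc += 1
                mh_acc_window += 1
            if sweep < chain.burn_in and mh_att_window >= 50:
                rate = mh_acc_window / mh_att_window
                if rate > 0.5:
                    mh_step *= 1.15
                elif rate < 0.3:
                    mh_step /= 1.15
                mh_acc_window = mh_att_window = 0
            tau1sq = max(tau1sq, 1e-12)

        # (iv) pi0 from its Beta conditional
        if fix_zeta is None:
            n1 = int(zeta.sum())
            pi0 = float(rng.beta(a0 + (p - n1), b0 + n1))
            pi0 = min(max(pi0, 1e-12), 1.0 - 1e-12)

        # (v) random effects, intercept and variances by Gibbs
        for name, (idx, nlev, counts) in factors.items():
            vals = effects[name]
            r += vals[idx]
            sums = np.bincount(idx, weights=r, minlength=nlev)
            prec = counts / sigma_e2 + 1.0 / variances[name]
            mean = sums / sigma_e2 / prec
            vals = mean + rng.standard_normal(nlev) / np.sqrt(prec)
            effects[name] = vals
            r -= vals[idx]
            df = max(nlev - 2, 1)
            ssq = float(vals @ vals)
            variances[name] = max(ssq / _chi2_draw(rng, df), 1e-12)

        if include_intercept:
            r += mu
            mu = float(np.mean(r) + rng.standard_normal() * math.sqrt(sigma_e2 / n))
            r -= mu

        if "sigma_e2" not in fixed:
            sigma_e2 = max(float(r @ r) / _chi2_draw(rng, max(n - 2, 1)), 1e-12)

        if not math.isfinite(sigma_e2) or not math.isfinite(tau1sq):
            raise FloatingPointError(
                f"divergent state at sweep {sweep}: sigma_e2={sigma_e2}, "
                f"tau1sq={tau1sq}"
            )

        # (vi) accumulate post-burn-in thinned samples
        if sweep >= chain.burn_in and (sweep - chain.burn_in) % chain.thinning == 0:
            keep += 1
            zeta_sum += zeta
            beta_sum += beta
            beta_sumsq += beta * beta
            mu_sum += mu
            mu_sumsq += mu * mu
            pi0_sum += pi0
            tau1_sum += tau1sq
            sige_sum += sigma_e2
            for name in factors:
                var_sums[name] += variances[name]
                var_sumsqs[name] += variances[name] ** 2

    if keep == 0:
        raise RuntimeError("no post-burn-in samples retained")
    mh_rate = mh_acc / mh_att if mh_att else float("nan")
    if mh_att and not (0.1 <= mh_rate <= 0.7):
        logger.warning("slab-variance MH acceptance rate %.2f outside [0.1, 0.7]",
                       mh_rate)

    inv_order = np.empty(p, dtype=np.intp)
    inv_order[order] = np.arange(p)
    pip = (zeta_sum / keep)[inv_order]
    b_mean = (beta_sum / keep)[inv_order]
    b_var = np.maximum(beta_sumsq / keep - (beta_sum / keep) ** 2, 0.0)
    b_sd = np.sqrt(b_var)[inv_order]
    bf = bayes_factors(pip, priors)
    var_means = {k: var_sums[k] / keep for k in factors}
    var_sds = {
        k: math.sqrt(max(var_sumsqs[k] / keep - var_means[k] ** 2, 0.0))
        for k in factors
    }
    return BVSResult(
        marker_ids=list(genotypes.ids),
        chrom=np.asarray(genotypes.chrom),
        pos=np.asarray(genotypes.pos),
        maf=genotypes.maf.copy(),
        pip=pip,
        beta_mean=b_mean,
        beta_sd=b_sd,
        bf=bf,
        classes=classify_qtls(bf),
        mu_mean=mu_sum / keep,
        mu_sd=math.sqrt(max(mu_sumsq / keep - (mu_sum / keep) ** 2, 0.0)),
        pi0_mean=pi0_sum / keep,
        tau1sq_mean=tau1_sum / keep,
        sigma_e2_mean=sige_sum / keep,
        variance_means=var_means,
        variance_sds=var_sds,
        mh_acceptance=mh_rate,
        n_samples=keep,
    )


# ---------------------------------------------------------------------------
# simulator


def simulate_qtl_data(
    n: int = 300,
    p: int = 500,
    n_qtl: int = 5,
    qtl_variance_fraction: float = 0.30,
    variance_components: Optional[Dict[str, float]] = None,
    maf_range: Tuple[float, float] = (0.1, 0.5),
    n_blocks: int = 15,
    positions_per_block: int = 4,
    n_gdd_levels: int = 10,
    seed_rep_block: bool = False,
    rng_seed: int = 0,
) -> Tuple[np.ndarray, GenotypeMatrix, DesignMatrices, Dict]:
    """Simulate a QTL mapping dataset emulating the glasshouse design.

    Genotypes are drawn per marker as binomial(2, f) - 1 with minor allele
    frequency uniform on ``maf_range``. ``n_qtl`` markers receive effects
    scaled so that the marker term explains ``qtl_variance_fraction`` of
    the (unit) phenotypic variance; block, position-in-block,
    growth-degree-day and optionally seed x replicate x block random
    effects take the fractions in ``variance_components`` (defaults 0.05
    each); the residual absorbs the remainder. Returns the phenotype,
    genotypes, design and a truth dict with QTL indices and effects.
    """
    rng = np.random.default_rng(rng_seed)
    vc = dict(variance_components or {})
    vc.setdefault("block", 0.05)
    vc.setdefault("position", 0.05)
    vc.setdefault("gdd", 0.05)
    if seed_rep_block:
        vc.setdefault("seed_rep_block", 0.05)
    var_e = 1.0 - qtl_variance_fraction - sum(vc.values())
    if var_e <= 0:
        raise ValueError("variance fractions exceed the unit budget")

    raw = np.empty((n, p), dtype=np.int8)
    for j in range(p):
        while True:
            f = rng.uniform(*maf_range)
            col = rng.binomial(2, f, size=n).astype(np.int8) - 1
            if col.min() != col.max():
                raw[:, j] = col
                break
    chrom = np.repeat(
        [f"{c}H" for c in range(1, 8)], math.ceil(p / 7)
    )[:p]
    pos = np.arange(p) * 1000
    geno = GenotypeMatrix(raw=raw, ids=[f"M{j:05d}" for j in range(p)],
                          chrom=chrom, pos=pos)

    qtl_idx = np.sort(rng.choice(p, size=n_qtl, replace=False)) if n_qtl else np.array([], dtype=int)
    effects = np.zeros(p)
    if n_qtl:
        raw_eff = rng.normal(0.0, 1.0, size=n_qtl)
        raw_eff[np.abs(raw_eff) < 0.3] += 0.3 * np.sign(raw_eff[np.abs(raw_eff) < 0.3] + 1e-9)
        g = geno.X[:, qtl_idx] @ raw_eff
        scale = math.sqrt(qtl_variance_fraction / max(np.var(g), 1e-12))
        effects[qtl_idx] = raw_eff * scale

    fac = {
        "block": rng.integers(0, n_blocks, size=n),
        "gdd": rng.integers(0, n_gdd_levels, size=n),
    }
    # position nested within block: level = block * per-block positions + slot
    slot = rng.integers(0, positions_per_block, size=n)
    fac["position"] = fac["block"] * positions_per_block + slot
    if seed_rep_block:
        fac["seed_rep_block"] = rng.integers(0, n_blocks * 4, size=n)
    design = DesignMatrices(factors={k: v for k, v in fac.items()})

    y = geno.X @ effects
    for name, frac in vc.items():
        idx = design.factors[name]
        nlev = design.n_levels(name)
        vals = rng.normal(0.0, math.sqrt(frac), size=nlev)
        y = y + vals[idx]
    y = y + rng.normal(0.0, math.sqrt(var_e), size=n)

    truth = {
        "qtl_indices": qtl_idx,
        "qtl_ids": [geno.ids[j] for j in qtl_idx],
        "effects": effects[qtl_idx],
        "variance_components": vc,
        "residual_variance": var_e,
    }
    return y, geno, design, truth
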