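"""Synthetic rhizobox scenes with known ground truth.

Generates paired root/seed segmentation masks that emulate the structure
the measurement pipeline sees in real rhizobox images: a seed blob per
plant, two seminal roots diverging at a known angle, optional lateral
roots, sub-threshold noise specks and soil-occlusion gaps. Every stage of
the pipeline is testable against the analytic truth with no real data.

Also simulates paired manual/automated angle measurements with
configurable noise and bias for exercising the agreement statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from rootangle.agreement import PairedMeasurements
from rootangle.mask_io import save_mask


@dataclass(frozen=True)
class LateralSpec:
    """A lateral root branching off one seminal root."""

    side: str  # "left" or "right"
    attach_distance: float  # px along the parent root from the seed
    rel_angle_deg: float  # rotation relative to the parent direction
    length: float


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one synthetic plant.

    ``true_angle`` is the full angle between the two seminal roots;
    ``half_angles`` (left, right, degrees from vertical) override the
    symmetric-about-vertical default, e.g. to rotate the whole root system
    rigidly. Distances and the seed location are in pixels.
    """

    seed_xy: Tuple[int, int] = (400, 150)
    true_angle: float = 90.0
    half_angles: Optional[Tuple[float, float]] = None
    root_length: float = 380.0
    root_width: int = 5
    seed_half_width: int = 15
    seed_height: int = 20
    laterals: Tuple[LateralSpec, ...] = ()
    n_specks: int = 0
    speck_max_area: int = 99
    occlusions: Tuple[Tuple[str, float, float], ...] = ()  # (side, start, end)
    rng_seed: int = 0

    def ray_angles(self) -> Tuple[float, float]:
        """(left, right) angles from vertical-down, degrees, tilt outward."""
        if self.half_angles is not None:
            left, right = self.half_angles
        else:
            left = right = self.true_angle / 2.0
        return float(left), float(right)

    @property
    def analytic_angle(self) -> float:
        """Angle between the two ray directions, computed analytically."""
        left, right = self.ray_angles()
        return left + right


@dataclass(frozen=True)
class PairedSimSpec:
    """Simulation of paired manual/automated angle measurements.

    True angles are uniform on ``angle_range``; the manual measurement
    adds N(0, noise_sd^2); the automated one applies a fixed bias
    (intercept) and proportional bias (slope) before adding its own noise.
    """

    n: int = 132
    angle_range: Tuple[float, float] = (40.0, 150.0)
    noise_sd: float = 5.0
    fixed_bias: float = 0.0
    proportional_bias: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3 pairs")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _ray_direction(angle_from_vertical_deg: float, side: str) -> Tuple[float, float]:
    a = math.radians(angle_from_vertical_deg)
    sx = -math.sin(a) if side == "left" else math.sin(a)
    return sx, math.cos(a)


def _stamp_segment(mask: np.ndarray, p0, p1, width: float) -> None:
    """Rasterize a thick segment: pixels within (width-1)/2 of the
    centerline (plus the Bresenham line itself for width <= 1)."""
    h, w = mask.shape
    x0, y0 = p0
    x1, y1 = p1
    halfwidth = max((width - 1.0) / 2.0, 0.0)
    pad = int(math.ceil(halfwidth)) + 1
    xmin = max(0, int(math.floor(min(x0, x1))) - pad)
    xmax = min(w - 1, int(math.ceil(max(x0, x1))) + pad)
    ymin = max(0, int(math.floor(min(y0, y1))) - pad)
    ymax = min(h - 1, int(math.ceil(max(y0, y1))) + pad)
    if xmin > xmax or ymin > ymax:
        return
    xs = np.arange(xmin, xmax + 1, dtype=np.float64)
    ys = np.arange(ymin, ymax + 1, dtype=np.float64)
    X, Y = np.meshgrid(xs, ys)
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        t = np.zeros_like(X)
    else:
        t = np.clip(((X - x0) * dx + (Y - y0) * dy) / seg2, 0.0, 1.0)
    d2 = (X - (x0 + t * dx)) ** 2 + (Y - (y0 + t * dy)) ** 2
    mask[ymin : ymax + 1, xmin : xmax + 1] |= d2 <= halfwidth**2 + 1e-12


def _check_inside(p, size, what: str) -> None:
    x, y = p
    w, h = size
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"{what} at ({x:.1f}, {y:.1f}) exits the {w}x{h} image")


def add_specks(
    mask: np.ndarray,
    n_specks: int,
    rng: np.random.Generator,
    max_area: int = 99,
    clear_margin: int = 3,
) -> int:
    """Scatter small disk-shaped noise specks (< ``max_area`` px each) on a
    mask, keeping them clear of existing foreground so component areas are
    unchanged. Returns the number of specks actually placed."""
    h, w = mask.shape
    placed = 0
    attempts = 0
    while placed < n_specks and attempts < n_specks * 50:
        attempts += 1
        r = rng.uniform(1.0, 5.0)
        cx = rng.uniform(r + 1, w - r - 2)
        cy = rng.uniform(r + 1, h - r - 2)
        xs = np.arange(int(cx - r) - 1, int(cx + r) + 2)
        ys = np.arange(int(cy - r) - 1, int(cy + r) + 2)
        X, Y = np.meshgrid(xs, ys)
        disk = (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
        if int(disk.sum()) == 0 or int(disk.sum()) > max_area:
            continue
        m = clear_margin
        y0, y1 = max(0, ys[0] - m), min(h, ys[-1] + 1 + m)
        x0, x1 = max(0, xs[0] - m), min(w, xs[-1] + 1 + m)
        if mask[y0:y1, x0:x1].any():
            continue
        mask[ys[0] : ys[-1] + 1, xs[0] : xs[-1] + 1] |= disk
        placed += 1
    return placed


def generate_scene(
    truth: SceneTruth,
    image_size: Tuple[int, int] = (800, 1200),
) -> Tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Rasterize one plant into a (root_mask, seed_mask) pair.

    The seed mask holds one elliptical blob whose top-centre is exactly
    ``truth.seed_xy``; the root mask holds two thick straight roots from
    the seed point diverging at the ray angles, with laterals, occlusion
    gaps and noise specks applied per the truth spec. Pure function of
    (truth, image_size).
    """
    w, h = image_size
    if w < 1 or h < 1:
        raise ValueError("image size must be positive")
    sx, sy = truth.seed_xy
    if truth.root_width < 1:
        raise ValueError("root width must be >= 1")
    if not (0.0 < truth.analytic_angle < 180.0):
        raise ValueError("true angle must lie in (0, 180)")
    _check_inside((sx, sy), image_size, "seed point")

    seed_mask = np.zeros((h, w), dtype=bool)
    a, b = truth.seed_half_width, truth.seed_height / 2.0
    xs = np.arange(max(0, sx - a - 1), min(w, sx + a + 2), dtype=np.float64)
    ys = np.arange(max(0, sy - 1), min(h, sy + truth.seed_height + 2), dtype=np.float64)
    X, Y = np.meshgrid(xs, ys)
    blob = ((X - sx) / a) ** 2 + ((Y - (sy + b)) / b) ** 2 <= 1.0 + 1e-12
    seed_mask[int(ys[0]) : int(ys[-1]) + 1, int(xs[0]) : int(xs[-1]) + 1] |= blob

    root_mask = np.zeros((h, w), dtype=bool)
    left_a, right_a = truth.ray_angles()
    directions = {"left": _ray_direction(left_a, "left"),
                  "right": _ray_direction(right_a, "right")}
    for side, (dx, dy) in directions.items():
        end = (sx + dx * truth.root_length, sy + dy * truth.root_length)
        _check_inside(end, image_size, f"{side} root tip")
        gaps = sorted(
            (g[1], g[2]) for g in truth.occlusions if g[0] == side
        )
        pos = 0.0
        for g0, g1 in gaps + [(truth.root_length, truth.root_length)]:
            if g0 > pos:
                _stamp_segment(
                    root_mask,
                    (sx + dx * pos, sy + dy * pos),
                    (sx + dx * min(g0, truth.root_length), sy + dy * min(g0, truth.root_length)),
                    truth.root_width,
                )
            pos = max(pos, g1)
    for lat in truth.laterals:
        dx, dy = directions[lat.side]
        base = (sx + dx * lat.attach_distance, sy + dy * lat.attach_distance)
        rel = math.radians(lat.rel_angle_deg)
        ldx = dx * math.cos(rel) - dy * math.sin(rel)
        ldy = dx * math.sin(rel) + dy * math.cos(rel)
        tip = (base[0] + ldx * lat.length, base[1] + ldy * lat.length)
        _check_inside(tip, image_size, "lateral root tip")
        _stamp_segment(root_mask, base, tip, max(1, truth.root_width - 2))

    if truth.n_specks > 0:
        rng = np.random.default_rng(truth.rng_seed)
        add_specks(seed_mask, truth.n_specks, rng, truth.speck_max_area)
    return root_mask, seed_mask, truth


def generate_multi_scene(
    truths: Sequence[SceneTruth],
    image_size: Tuple[int, int] = (800, 1200),
) -> Tuple[np.ndarray, np.ndarray, List[SceneTruth]]:
    """Union of several plants in one image (multi-plant rhizobox)."""
    w, h = image_size
    root = np.zeros((h, w), dtype=bool)
    seed = np.zeros((h, w), dtype=bool)
    for t in truths:
        r, s, _ = generate_scene(t, image_size)
        root |= r
        seed |= s
    return root, seed, list(truths)


def ideal_root_length(truth: SceneTruth) -> float:
    """Analytic centerline length of all drawn roots (px)."""
    total = 2.0 * truth.root_length
    for side, g0, g1 in truth.occlusions:
        total -= min(g1, truth.root_length) - min(g0, truth.root_length)
    total += sum(l.length for l in truth.laterals)
    return total


def generate_dataset(
    n_scenes: int,
    out_dir: Path | str,
    angle_range: Tuple[float, float] = (40.0, 150.0),
    image_size: Tuple[int, int] = (800, 1200),
    root_length: float = 380.0,
    root_width: int = 5,
    n_specks: int = 0,
    rng_seed: int = 0,
    force: bool = False,
) -> pd.DataFrame:
    """Write ``n_scenes`` mask pairs plus a ``truth.csv`` manifest.

    Layout: ``out_dir/root_masks/scene_XXX.png``,
    ``out_dir/seed_masks/scene_XXX.png``, ``out_dir/truth.csv``. True
    angles are drawn uniformly from ``angle_range``; seed locations
    jittered around the top-centre of the image. Deterministic given
    ``rng_seed``. Refuses to overwrite a non-empty directory without
    ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"output directory {out_dir} is not empty (use force)")
    root_dir = out_dir / "root_masks"
    seed_dir = out_dir / "seed_masks"
    root_dir.mkdir(parents=True, exist_ok=True)
    seed_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(rng_seed)
    w, _ = image_size
    rows = []
    for i in range(n_scenes):
        angle = float(rng.uniform(*angle_range))
        # jitter kept small enough that a 150-degree spread at full root
        # length stays inside the default 800-px-wide image
        sx = int(rng.integers(w // 2 - 20, w // 2 + 21))
        sy = int(rng.integers(120, 181))
        truth = SceneTruth(
            seed_xy=(sx, sy),
            true_angle=angle,
            root_length=root_length,
            root_width=root_width,
            n_specks=n_specks,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        root_mask, seed_mask, _ = generate_scene(truth, image_size)
        image_id = f"scene_{i:03d}"
        save_mask(root_mask, root_dir / f"{image_id}.png")
        save_mask(seed_mask, seed_dir / f"{image_id}.png")
        rows.append(
            {
                "image_id": image_id,
                "true_angle": truth.analytic_angle,
                "seed_x": sx,
                "seed_y": sy,
                "ideal_root_length_px": ideal_root_length(truth),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "truth.csv", index=False, float_format="%.6f")
    return manifest


def simulate_paired_measurements(spec: PairedSimSpec) -> PairedMeasurements:
    """Draw simulated (automated, manual) angle pairs under the spec's
    noise and bias model; deterministic given the spec's rng seed."""
    rng = np.random.default_rng(spec.rng_seed)
    t = rng.uniform(*spec.angle_range, size=spec.n)
    m = t + rng.normal(0.0, spec.noise_sd, size=spec.n)
    a = (
        spec.fixed_bias
        + spec.proportional_bias * t
        + rng.normal(0.0, spec.noise_sd, size=spec.n)
    )
    return PairedMeasurements(a=a, m=m, truth=t)
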