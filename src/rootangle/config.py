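"""Run configuration shared by the measurement pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


@dataclass
class RunConfig:
    """Parameters controlling one measurement run.

    Attributes
    ----------
    inner_radius, outer_radius
        Bounds (pixels) of the annulus around each seed point within which
        root-skeleton segments contribute to the angle. Root pixels closer
        than ``inner_radius`` (where the seminal roots are still merged, or
        hidden by the seed) are excluded; the square analysis window has
        half-width ``outer_radius``.
    min_seed_area
        Seed-mask connected components smaller than this many pixels are
        treated as segmentation noise and discarded.
    min_root_area
        Root-mask components smaller than this are removed before the
        per-image total-root-length skeleton is measured (same
        noise rationale as ``min_seed_area``); annulus angle geometry is
        not affected by this filter.
    max_seeds_per_image
        Upper bound on seed points per image (rhizoboxes hold a known
        number of plants); the largest components by area are kept.
    debug_dir
        If set, per-seed step-by-step debug renderings are written here.
    rng_seed
        Seed for any stochastic stage downstream of the measurement.
    """

    inner_radius: float = 50.0
    outer_radius: float = 300.0
    min_seed_area: int = 100
    min_root_area: int = 100
    max_seeds_per_image: int = 2
    connectivity: int = 8
    seed_vertex: str = "top_centre"  # or "centroid"
    debug_dir: Optional[Path] = None
    log_file: Optional[Path] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.inner_radius < self.outer_radius):
            raise ValueError(
                f"require 0 <= inner_radius < outer_radius, got "
                f"{self.inner_radius}, {self.outer_radius}"
            )
        if self.min_seed_area < 1:
            raise ValueError("min_seed_area must be >= 1")
        if self.max_seeds_per_image < 1:
            raise ValueError("max_seeds_per_image must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.seed_vertex not in ("top_centre", "centroid"):
            raise ValueError("seed_vertex must be 'top_centre' or 'centroid'")
        if self.debug_dir is not None:
            self.debug_dir = Path(self.debug_dir)
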