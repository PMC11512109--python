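"""Seed point localization from the seed-region segmentation mask.

A seed point anchors every per-plant measurement. It is the *top-centre*
of a segmented seed blob: the horizontal coordinate is the mean x of all
pixels in the connected component (sub-pixel), the vertical coordinate the
minimum y (topmost row). Components below an area threshold are treated as
segmentation noise and discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from skimage.measure import label, regionprops

logger = logging.getLogger("rootangle")


@dataclass(frozen=True)
class PixelComponent:
    """A connected set of foreground pixels.

    ``xs``/``ys`` are parallel integer coordinate arrays; ``bbox`` is the
    tight bounding box (xmin, ymin, xmax, ymax), inclusive.
    """

    xs: np.ndarray
    ys: np.ndarray

    @property
    def area(self) -> int:
        return int(self.xs.size)

    @property
    def bbox(self) -> Tuple[int, int, int, int]:
        return (
            int(self.xs.min()),
            int(self.ys.min()),
            int(self.xs.max()),
            int(self.ys.max()),
        )

    @property
    def centroid(self) -> Tuple[float, float]:
        """(mean x, mean y) of the member pixels."""
        return float(self.xs.mean()), float(self.ys.mean())


@dataclass(frozen=True)
class SeedPoint:
    """Top-centre coordinate of a seed component.

    ``x`` is the sub-pixel mean of member x coordinates, ``y`` the integer
    minimum member y (topmost visible row).
    """

    x: float
    y: int
    area: int
    seed_index: int = 0


def connected_components(mask: np.ndarray, connectivity: int = 8) -> List[PixelComponent]:
    """Partition foreground pixels into maximal connected components.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    Output order is deterministic: sorted by (bbox ymin, bbox xmin).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    lab = label(mask, connectivity=1 if connectivity == 4 else 2)
    comps = []
    for rp in regionprops(lab):
        ys, xs = rp.coords[:, 0], rp.coords[:, 1]
        comps.append(PixelComponent(xs=np.ascontiguousarray(xs), ys=np.ascontiguousarray(ys)))
    comps.sort(key=lambda c: (c.bbox[1], c.bbox[0]))
    return comps


def seed_coordinate(component: PixelComponent) -> SeedPoint:
    """Top-centre rule: x = mean of member x's (not rounded), y = min member y."""
    if component.area < 1:
        raise ValueError("empty component")
    return SeedPoint(
        x=float(component.xs.mean()),
        y=int(component.ys.min()),
        area=component.area,
    )


def locate_seed_points(
    seed_mask: np.ndarray,
    min_seed_area: int = 100,
    max_seeds: Optional[int] = None,
    connectivity: int = 8,
    image_id: str = "",
) -> List[SeedPoint]:
    """Find seed points in a seed-segmentation mask.

    Components with fewer than ``min_seed_area`` pixels are discarded as
    noise. If more than ``max_seeds`` survive, the largest by area are
    kept (ties broken by smaller bbox xmin) with a warning. Survivors are
    ordered left-to-right by x and numbered 0..k-1.
    """
    comps = [
        c for c in connected_components(seed_mask, connectivity)
        if c.area >= min_seed_area
    ]
    if max_seeds is not None and len(comps) > max_seeds:
        logger.warning(
            "%s %d seed components exceed max_seeds=%d; keeping largest",
            image_id, len(comps), max_seeds,
        )
        comps.sort(key=lambda c: (-c.area, c.bbox[0]))
        comps = comps[:max_seeds]
    points = sorted((seed_coordinate(c) for c in comps), key=lambda s: s.x)
    return [
        SeedPoint(x=p.x, y=p.y, area=p.area, seed_index=i)
        for i, p in enumerate(points)
    ]
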