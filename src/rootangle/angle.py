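"""Seminal root angle and total root length from segmentation masks.

The core measurement: around each seed point, skeletonize the root mask
within a square window, keep only skeleton pixels in an annulus between an
inner and outer radius of the seed (excluding the region near the seed
where the seminal roots are still merged), pick the leftmost and rightmost
skeleton segments by centroid, and measure the unsigned angle at the seed
between the two segment centroids. Total root length is the step-weighted
length of the skeleton of the whole root mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from rootangle.config import RunConfig
from rootangle.mask_io import ImagePairing, load_mask, load_photo
from rootangle.seeds import (
    PixelComponent,
    SeedPoint,
    connected_components,
    locate_seed_points,
)

logger = logging.getLogger("rootangle")

SQRT2 = math.sqrt(2.0)

#: per-seed failure codes carried in AngleRecord.error
ERROR_CODES = ("", "no_seed", "no_root_segments", "one_root_segment")


class SegmentSelectionError(RuntimeError):
    """Raised when the annulus does not contain two usable root segments."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code


@dataclass(frozen=True)
class AngleRecord:
    """One measured (or failed) seminal root angle.

    ``angle_degrees`` is present iff ``error`` is empty, in which case both
    segment centroids are present and lie within the annulus.
    """

    image_id: str
    seed_index: Optional[int] = None
    seed_x: Optional[float] = None
    seed_y: Optional[int] = None
    angle_degrees: Optional[float] = None
    total_root_length_px: float = 0.0
    left_centroid: Optional[Tuple[float, float]] = None
    right_centroid: Optional[Tuple[float, float]] = None
    error: str = ""

    def __post_init__(self) -> None:
        if self.error not in ERROR_CODES:
            raise ValueError(f"unknown error code {self.error!r}")
        ok = self.error == ""
        if ok != (self.angle_degrees is not None):
            raise ValueError("angle present iff error empty")
        if ok != (self.left_centroid is not None and self.right_centroid is not None):
            raise ValueError("centroids present iff error empty")


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to its 1-px-wide medial skeleton.

    The skeleton is a subset of the input and preserves the
    8-connectivity of each input component; isolated single pixels
    survive thinning. Uses Lee's thinning scheme, whose deletion rule is
    symmetric under horizontal reflection, so mirrored scenes yield
    mirrored skeletons exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _sk_skeletonize(mask, method="lee").astype(bool)


def annulus_filter(
    skeleton: np.ndarray,
    seed_point: SeedPoint,
    inner_radius: float,
    outer_radius: float,
    origin: Tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Keep skeleton pixels whose distance from the seed lies in
    ``[inner_radius, outer_radius]`` (closed on both ends).

    ``origin`` is the (x, y) image coordinate of the array's top-left
    pixel, so the filter can be applied to a cropped window.
    """
    if not (0 <= inner_radius < outer_radius):
        raise ValueError("require 0 <= inner_radius < outer_radius")
    skeleton = np.asarray(skeleton, dtype=bool)
    h, w = skeleton.shape
    ox, oy = origin
    xs = np.arange(w, dtype=np.float64) + ox - seed_point.x
    ys = np.arange(h, dtype=np.float64) + oy - seed_point.y
    d2 = ys[:, None] ** 2 + xs[None, :] ** 2
    ring = (d2 >= inner_radius**2) & (d2 <= outer_radius**2)
    return skeleton & ring


def select_extreme_segments(
    annulus_skeleton: np.ndarray,
    connectivity: int = 8,
    origin: Tuple[int, int] = (0, 0),
) -> Tuple[PixelComponent, PixelComponent]:
    """Pick the leftmost and rightmost skeleton segments by centroid x.

    Ties on centroid x are broken by smaller centroid y. Raises
    :class:`SegmentSelectionError` with code ``no_root_segments`` (zero
    components) or ``one_root_segment`` (exactly one).
    """
    comps = connected_components(annulus_skeleton, connectivity)
    if origin != (0, 0):
        ox, oy = origin
        comps = [PixelComponent(xs=c.xs + ox, ys=c.ys + oy) for c in comps]
    if len(comps) == 0:
        raise SegmentSelectionError("no_root_segments")
    if len(comps) == 1:
        raise SegmentSelectionError("one_root_segment")
    keyed = sorted(comps, key=lambda c: (c.centroid[0], c.centroid[1]))
    return keyed[0], keyed[-1]


def angle_between(
    seed_xy: Tuple[float, float],
    left_centroid: Tuple[float, float],
    right_centroid: Tuple[float, float],
) -> float:
    """Unsigned angle (degrees, in [0, 180]) at the seed vertex between the
    rays seed->left and seed->right.

    Uses the two-argument arctangent of the cross and dot products, which
    is numerically stable for nearly parallel and nearly antiparallel
    rays. A centroid coinciding with the seed point is degenerate.
    """
    ax = left_centroid[0] - seed_xy[0]
    ay = left_centroid[1] - seed_xy[1]
    bx = right_centroid[0] - seed_xy[0]
    by = right_centroid[1] - seed_xy[1]
    if (ax == 0.0 and ay == 0.0) or (bx == 0.0 and by == 0.0):
        raise SegmentSelectionError("no_root_segments")
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    return math.degrees(math.atan2(abs(cross), dot))


def _remove_small_components(mask: np.ndarray, min_area: int, connectivity: int) -> np.ndarray:
    if min_area <= 1 or not mask.any():
        return mask
    out = np.zeros_like(mask)
    for c in connected_components(mask, connectivity):
        if c.area >= min_area:
            out[c.ys, c.xs] = True
    return out


def total_root_length(
    root_mask: np.ndarray,
    min_component_area: int = 0,
    connectivity: int = 8,
) -> float:
    """Total root length (pixels): step-weighted length of the skeleton.

    Each 4-neighbour adjacency between skeleton pixels contributes 1, each
    diagonal adjacency sqrt(2); every adjacent pair is counted once. An
    empty mask has length 0. With ``min_component_area`` > 0, components
    smaller than that are dropped (segmentation-noise filter) before
    skeletonizing.
    """
    mask = np.asarray(root_mask, dtype=bool)
    mask = _remove_small_components(mask, min_component_area, connectivity)
    if not mask.any():
        return 0.0
    s = skeletonize_mask(mask)
    horiz = int(np.count_nonzero(s[:, :-1] & s[:, 1:]))
    vert = int(np.count_nonzero(s[:-1, :] & s[1:, :]))
    diag1 = int(np.count_nonzero(s[:-1, :-1] & s[1:, 1:]))
    diag2 = int(np.count_nonzero(s[:-1, 1:] & s[1:, :-1]))
    return float(horiz + vert) + SQRT2 * float(diag1 + diag2)


def measure_seed(
    root_mask: np.ndarray,
    seed: SeedPoint,
    config: RunConfig,
    collect_debug: Optional[dict] = None,
) -> Tuple[Optional[float], Optional[Tuple[float, float]], Optional[Tuple[float, float]], str]:
    """Measure one seed's angle; returns (angle, left, right, error_code).

    Crops a square window of half-width ``outer_radius`` around the seed,
    skeletonizes the root mask within it, restricts to the annulus and
    takes the angle between the extreme segments' centroids at the seed.
    """
    h, w = root_mask.shape
    cx, cy = int(round(seed.x)), int(seed.y)
    r = int(math.ceil(config.outer_radius))
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    window = root_mask[y0:y1, x0:x1]
    skel = skeletonize_mask(window)
    ring = annulus_filter(
        skel, seed, config.inner_radius, config.outer_radius, origin=(x0, y0)
    )
    if collect_debug is not None:
        collect_debug.update(
            window=window, skeleton=skel, annulus=ring, origin=(x0, y0)
        )
    try:
        left, right = select_extreme_segments(
            ring, config.connectivity, origin=(x0, y0)
        )
        lc, rc = left.centroid, right.centroid
        vertex = (seed.x, float(seed.y))
        angle = angle_between(vertex, lc, rc)
    except SegmentSelectionError as exc:
        return None, None, None, exc.code
    if collect_debug is not None:
        collect_debug.update(left=left, right=right, angle=angle)
    return angle, lc, rc, ""


def measure_image(pairing: ImagePairing, config: RunConfig) -> List[AngleRecord]:
    """Measure every seed point in one image; never raises per-seed errors.

    Emits one record per surviving seed point, or a single ``no_seed``
    record when no seed component passes the area filter. Total root
    length is computed once per image on the (noise-filtered) full root
    mask and repeated on every row.
    """
    root_mask = load_mask(pairing.root_mask_path)
    seed_mask = load_mask(pairing.seed_mask_path)
    if root_mask.shape != seed_mask.shape:
        raise ValueError(
            f"{pairing.image_id}: root mask {root_mask.shape} and seed mask "
            f"{seed_mask.shape} differ in size"
        )
    return measure_masks(root_mask, seed_mask, config,
                         image_id=pairing.image_id, pairing=pairing)


def measure_masks(
    root_mask: np.ndarray,
    seed_mask: np.ndarray,
    config: RunConfig,
    image_id: str = "image",
    pairing: Optional[ImagePairing] = None,
) -> List[AngleRecord]:
    """In-memory counterpart of :func:`measure_image`."""
    trl = total_root_length(
        root_mask, min_component_area=config.min_root_area,
        connectivity=config.connectivity,
    )
    seed_points = locate_seed_points(
        seed_mask,
        min_seed_area=config.min_seed_area,
        max_seeds=config.max_seeds_per_image,
        connectivity=config.connectivity,
        image_id=image_id,
    )
    if not seed_points:
        logger.warning("%s no seed point after filtering", image_id)
        return [
            AngleRecord(
                image_id=image_id,
                total_root_length_px=trl,
                error="no_seed",
            )
        ]
    records = []
    for seed in seed_points:
        debug: Optional[dict] = {} if config.debug_dir is not None else None
        angle, lc, rc, code = measure_seed(root_mask, seed, config, debug)
        if code:
            logger.warning("%s seed %d: %s", image_id, seed.seed_index, code)
        records.append(
            AngleRecord(
                image_id=image_id,
                seed_index=seed.seed_index,
                seed_x=seed.x,
                seed_y=seed.y,
                angle_degrees=angle,
                total_root_length_px=trl,
                left_centroid=lc,
                right_centroid=rc,
                error=code,
            )
        )
        if debug is not None:
            if pairing is None:
                pairing = ImagePairing(image_id, Path(""), Path(""))
            render_debug(pairing, seed, debug, config)
    return records


def measure_batch(pairings, config: RunConfig) -> List[AngleRecord]:
    """Measure a list of pairings; per-image failures never abort the batch."""
    records: List[AngleRecord] = []
    n_fail = 0
    for pairing in pairings:
        try:
            records.extend(measure_image(pairing, config))
        except Exception as exc:  # unreadable masks, size mismatch
            logger.error("%s skipped: %s", pairing.image_id, exc)
            n_fail += 1
    by_code: dict = {}
    for r in records:
        by_code[r.error or "ok"] = by_code.get(r.error or "ok", 0) + 1
    logger.info(
        "processed %d images (%d unreadable), %d seed records: %s",
        len(pairings), n_fail, len(records),
        " ".join(f"{k}={v}" for k, v in sorted(by_code.items())),
    )
    return records


def render_debug(
    pairing: ImagePairing,
    seed: SeedPoint,
    debug: dict,
    config: RunConfig,
) -> None:
    """Write per-seed step renderings mirroring the measurement stages:
    window, skeleton, annulus and, on success, the chosen segments with
    angle rays (plus a photo overlay when a photograph is available).

    Filenames are ``{image_id}_seed{k}_step{n}.png``. An unwritable debug
    directory produces a warning; measurement continues.
    """
    from PIL import Image, ImageDraw

    out_dir = config.debug_dir
    if out_dir is None:
        return
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        logger.warning("%s debug dir unwritable (%s); skipping renders",
                       pairing.image_id, exc)
        return

    stem = f"{pairing.image_id}_seed{seed.seed_index}"
    ox, oy = debug["origin"]

    def as_rgb(mask: np.ndarray) -> Image.Image:
        return Image.fromarray(
            (np.asarray(mask, bool) * np.uint8(255))
        ).convert("RGB")

    def mark_seed(im: Image.Image) -> Image.Image:
        d = ImageDraw.Draw(im)
        sx, sy = seed.x - ox, seed.y - oy
        d.ellipse([sx - 3, sy - 3, sx + 3, sy + 3], outline=(255, 0, 0))
        return im

    panels = [
        ("step1", mark_seed(as_rgb(debug["window"]))),
        ("step2", mark_seed(as_rgb(debug["skeleton"]))),
        ("step3", mark_seed(as_rgb(debug["annulus"]))),
    ]
    if "angle" in debug:
        im = as_rgb(debug["annulus"])
        d = ImageDraw.Draw(im)
        sx, sy = seed.x - ox, seed.y - oy
        for comp, colour in ((debug["left"], (0, 160, 255)), (debug["right"], (255, 160, 0))):
            cx, cy = comp.centroid
            d.line([sx, sy, cx - ox, cy - oy], fill=colour, width=1)
            d.ellipse([cx - ox - 2, cy - oy - 2, cx - ox + 2, cy - oy + 2], fill=colour)
        d.text((4, 4), f"{debug['angle']:.1f} deg", fill=(255, 0, 0))
        panels.append(("step4", im))
    else:
        im = panels[-1][1].copy()
        ImageDraw.Draw(im).text((4, 4), "measurement failed", fill=(255, 0, 0))
        panels.append(("step4", im))
    if pairing.photo_path is not None:
        photo = load_photo(pairing.photo_path)
        h, w = debug["window"].shape
        crop = photo[oy : oy + h, ox : ox + w]
        im = Image.fromarray(crop).convert("RGB")
        panels.append(("step5", mark_seed(im)))
    for i, (_, im) in enumerate(panels, start=1):
        im.save(out_dir / f"{stem}_step{i}.png")
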