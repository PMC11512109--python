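"""Reading and writing segmentation masks, photographs and result CSVs.

Masks are carried in memory as 2-D boolean numpy arrays indexed
``[row (y), column (x)]`` with the origin at the top-left and y increasing
downward, matching image convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from PIL import Image
from skimage.filters import threshold_yen

logger = logging.getLogger("rootangle")

CSV_HEADER = (
    "image,seed_index,seed_x,seed_y,angle_degrees,total_root_length_px,"
    "left_centroid_x,left_centroid_y,right_centroid_x,right_centroid_y,error"
)

#: file extensions recognised when pairing segmentation directories
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


class MaskIOError(RuntimeError):
    """Fatal input/output problem (unreadable mask, no pairings, ...)."""


@dataclass(frozen=True)
class ImagePairing:
    """A root mask and seed mask belonging to the same photograph."""

    image_id: str
    root_mask_path: Path
    seed_mask_path: Path
    photo_path: Optional[Path] = None


def setup_logging(log_file: Optional[Path] = None, level: int = logging.INFO) -> None:
    """Route ``rootangle`` log lines (``LEVEL image_id message``) to stderr
    and optionally a file."""
    logger.setLevel(level)
    fmt = logging.Formatter("%(levelname)s %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def load_mask(path: Path | str) -> np.ndarray:
    """Load a raster image as a boolean mask.

    A pixel is foreground iff its first-channel intensity is nonzero,
    which tolerates both 0/255 and 0/1 mask dialects.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # unreadable / undecodable
        raise MaskIOError(f"cannot read mask image {path}: {exc}") from exc
    if arr.size == 0:
        raise MaskIOError(f"zero-size image {path}")
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr != 0


def save_mask(mask: np.ndarray, path: Path | str) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG (inverse of load_mask)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(Path(path))


def load_photo(path: Path | str) -> np.ndarray:
    """Load a photograph as an 8-bit greyscale array (for debug overlays)."""
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("L"))


def pair_directories(
    root_dir: Path | str,
    seed_dir: Path | str,
    photo_dir: Optional[Path | str] = None,
) -> List[ImagePairing]:
    """Match root- and seed-segmentation files by filename stem.

    Matching is case-sensitive on the stem; extensions may differ.
    Unmatched files are logged as warnings and skipped. Zero matches is a
    fatal error. Pairings are returned sorted by image id.
    """
    root_dir, seed_dir = Path(root_dir), Path(seed_dir)
    for d in (root_dir, seed_dir):
        if not d.is_dir():
            raise MaskIOError(f"segmentation directory does not exist: {d}")

    def stems(d: Path) -> dict:
        out = {}
        for p in sorted(d.iterdir()):
            if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS:
                out[p.stem] = p
        return out

    roots, seeds = stems(root_dir), stems(seed_dir)
    photos = stems(Path(photo_dir)) if photo_dir is not None else {}

    pairings = []
    for stem in sorted(set(roots) | set(seeds)):
        if stem in roots and stem in seeds:
            pairings.append(
                ImagePairing(stem, roots[stem], seeds[stem], photos.get(stem))
            )
        else:
            where = "seed" if stem in roots else "root"
            logger.warning("%s missing %s segmentation; skipped", stem, where)
    if not pairings:
        raise MaskIOError(
            f"no matched root/seed mask pairs between {root_dir} and {seed_dir}"
        )
    return pairings


def brightness_correct(photo: np.ndarray) -> np.ndarray:
    """Brightness-correct a greyscale photograph for visualisation.

    Computes Yen's maximum-correlation threshold from the intensity
    histogram and linearly rescales intensities so the occupied range
    around the threshold maps onto the full 0..255 output range. This is a
    debug/visualisation aid only; measurement consumes masks, never photos.
    """
    photo = np.asarray(photo)
    if photo.ndim == 3:
        photo = np.asarray(Image.fromarray(photo).convert("L"))
    lo, hi = int(photo.min()), int(photo.max())
    if lo == hi:
        logger.warning("constant image; brightness correction skipped")
        return photo.copy()
    t = float(threshold_yen(photo))
    # piecewise-linear rescale around the Yen threshold: the sub-threshold
    # range [lo, t] maps onto [0, 127] and the above-threshold range
    # (t, hi] onto (128, 255], so the occupied range fills the 8-bit range
    out = np.empty(photo.shape, dtype=np.float64)
    below = photo <= t
    span_lo = max(t - lo, 1e-9)
    span_hi = max(hi - t, 1e-9)
    out[below] = (photo[below] - lo) / span_lo * 127.0
    out[~below] = 128.0 + (photo[~below] - t) / span_hi * 127.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _fmt(value, digits: int = 6) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and not math.isfinite(value):
        return repr(value)
    if isinstance(value, float):
        return f"{value:.{digits}f}"
    return str(value)


def write_angle_csv(records: Sequence, path: Path | str) -> None:
    """Write measurement records to CSV (one row per seed point).

    Failed measurements carry an empty angle field and a non-empty error
    code; the row count always equals the number of records.
    """
    path = Path(path)
    lines = [CSV_HEADER]
    for r in records:
        lc = r.left_centroid or (None, None)
        rc = r.right_centroid or (None, None)
        lines.append(
            ",".join(
                [
                    r.image_id,
                    _fmt(r.seed_index),
                    _fmt(r.seed_x),
                    _fmt(r.seed_y),
                    _fmt(r.angle_degrees),
                    _fmt(r.total_root_length_px),
                    _fmt(lc[0]),
                    _fmt(lc[1]),
                    _fmt(rc[0]),
                    _fmt(rc[1]),
                    r.error,
                ]
            )
        )
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise MaskIOError(f"cannot write CSV to {path}: {exc}") from exc
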