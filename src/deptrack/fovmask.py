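"""Valid-observation-region (FoV) mask.

DEP microscopy frames show a bright circular field of view surrounded by
unilluminated corners and border bands with illumination artifacts.  The
mask is built once from the first frame: binarize, fill enclosed holes,
open with a disk structuring element, keep the dominant component and blank
the unstable top/bottom pixel rows.  Downstream stages use it to decide
whether a tracked centroid is inside the valid region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

__all__ = [
    "FoVMask",
    "DegenerateMaskError",
    "make_fov_mask",
    "contains",
    "contains_many",
]


class DegenerateMaskError(ValueError):
    """Raised when binarization yields no usable foreground/background split."""


@dataclass
class FoVMask:
    """Binary validity mask plus a record of how it was built."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def contains(self, point) -> bool:
        return contains(self, point)


def make_fov_mask(
    frame: np.ndarray,
    disk_radius: float = 50,
    strip_rows: int = 10,
    threshold_method: str | float = "otsu",
) -> FoVMask:
    """Build the FoV mask from a first frame.

    Pipeline: binarize (Otsu by default, or a fixed numeric threshold) ->
    fill enclosed holes -> morphological opening with a disk of
    ``disk_radius`` px -> keep the largest connected component -> zero the
    top and bottom ``strip_rows`` rows.  Raises :class:`DegenerateMaskError`
    when binarization is all-background or all-foreground.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("frame is empty")
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {threshold_method!r}")
        if np.ptp(frame) == 0:
            raise DegenerateMaskError("frame has no contrast")
        thr = threshold_otsu(frame)
    else:
        thr = float(threshold_method)
    binary = frame > thr
    if not binary.any() or binary.all():
        raise DegenerateMaskError("binarization produced a degenerate mask")

    filled = ndimage.binary_fill_holes(binary)
    # exact-disk opening via the Euclidean distance transform (fast for r=50)
    opened = morphology.isotropic_opening(filled, radius=disk_radius)
    if opened.any():
        labels, n = ndimage.label(opened)
        if n > 1:
            sizes = ndimage.sum_labels(opened, labels, index=np.arange(1, n + 1))
            opened = labels == (1 + int(np.argmax(sizes)))
    mask = opened.copy()
    if strip_rows > 0:
        mask[:strip_rows, :] = False
        mask[-strip_rows:, :] = False
    if not mask.any():
        raise DegenerateMaskError("mask is empty after opening/strip removal")
    return FoVMask(
        mask=mask,
        provenance={
            "threshold": float(thr),
            "disk_radius": float(disk_radius),
            "strip_rows": int(strip_rows),
            "ud_bar_applied": strip_rows > 0,
        },
    )


def contains(mask: FoVMask, point) -> bool:
    """True iff ``point`` (x, y) rounds to an in-grid pixel where the mask is set.

    Off-grid and non-finite points return False.
    """
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        return False
    col, row = int(round(x)), int(round(y))
    rows, cols = mask.mask.shape
    if not (0 <= row < rows and 0 <= col < cols):
        return False
    return bool(mask.mask[row, col])


def contains_many(mask: FoVMask, points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`contains` for an (n, 2) array of (x, y) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(len(pts), dtype=bool)
    finite = np.all(np.isfinite(pts), axis=1)
    cols_i = np.round(pts[finite, 0]).astype(int)
    rows_i = np.round(pts[finite, 1]).astype(int)
    rows, cols = mask.mask.shape
    ok = (rows_i >= 0) & (rows_i < rows) & (cols_i >= 0) & (cols_i < cols)
    vals = np.zeros(ok.shape, dtype=bool)
    vals[ok] = mask.mask[rows_i[ok], cols_i[ok]]
    out[finite] = vals
    return out
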