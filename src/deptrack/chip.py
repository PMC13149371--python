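"""Chip geometry and the analytic electric-field proxy.

The electrode is a regular array of circular holes etched in a planar
electrode layer.  The field-gradient magnitude |grad E_rms^2| peaks on each
hole rim (the high-field annulus where pDEP cells collect) and decays toward
hole centers and the far field (the low-field loci where nDEP cells
collect).  Rather than importing a finite-element field map, the proxy
models this topology as a sum of isotropic Gaussian bumps centred on the
hole rims; the direction field points toward the nearest rim point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChipLayout", "FieldProxy", "make_chip_layout", "field_proxy"]


@dataclass(frozen=True)
class ChipLayout:
    """Geometry of the circular-hole electrode array, in pixel units.

    ``fov_center``/``fov_radius`` describe the illuminated circular
    field of view inscribed in the image.  All hole discs must lie inside
    the FoV disk.
    """

    hole_centers: np.ndarray  # (n, 2) float, (x, y) px
    hole_radius: float
    image_shape: tuple[int, int]  # (rows, cols)
    fov_center: tuple[float, float]  # (x, y)
    fov_radius: float

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.hole_centers, dtype=float))
        object.__setattr__(self, "hole_centers", centers)
        if self.hole_radius <= 0:
            raise ValueError("hole_radius must be positive")
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape must be positive")
        d = np.hypot(
            centers[:, 0] - self.fov_center[0], centers[:, 1] - self.fov_center[1]
        )
        if np.any(d + self.hole_radius > self.fov_radius + 1e-9):
            raise ValueError("all hole discs must lie inside the FoV disk")

    @property
    def n_holes(self) -> int:
        return len(self.hole_centers)


def make_chip_layout(
    rows: int,
    cols: int,
    pitch: float,
    hole_radius: float,
    image_shape: tuple[int, int],
) -> ChipLayout:
    """Regular ``rows x cols`` hole grid centred in the FoV disk.

    The FoV disk is inscribed in ``image_shape`` and centred on the image.
    Rejects geometries where holes would overlap (``pitch <= 2*hole_radius``)
    or extend beyond the FoV disk.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if pitch <= 2 * hole_radius:
        raise ValueError(
            f"holes overlap: pitch {pitch} must exceed twice hole_radius {hole_radius}"
        )
    n_rows, n_cols = image_shape
    cx, cy = (n_cols - 1) / 2.0, (n_rows - 1) / 2.0
    xs = (np.arange(cols) - (cols - 1) / 2.0) * pitch + cx
    ys = (np.arange(rows) - (rows - 1) / 2.0) * pitch + cy
    centers = np.array([(x, y) for y in ys for x in xs], dtype=float)
    fov_radius = min(n_rows, n_cols) / 2.0
    return ChipLayout(
        hole_centers=centers,
        hole_radius=float(hole_radius),
        image_shape=(int(n_rows), int(n_cols)),
        fov_center=(cx, cy),
        fov_radius=fov_radius,
    )


class FieldProxy:
    """Analytic stand-in for the field-gradient map over the chip.

    ``grad_e2`` holds |grad E_rms^2| (arbitrary calibrated units, >= 0) on
    the pixel grid and ``direction`` the unit vector toward the local
    high-field locus (the nearest hole rim); ``direction_valid`` is False
    where the direction is undefined (exactly on a hole centre).  Grids are
    computed lazily; the same quantities can be queried at float positions
    via :meth:`grad_at` and :meth:`direction_at`.
    """

    def __init__(self, layout: ChipLayout, sigma_bump: float):
        if sigma_bump <= 0:
            raise ValueError("sigma_bump must be positive")
        self.layout = layout
        self.sigma_bump = float(sigma_bump)
        self._grad_e2: np.ndarray | None = None
        self._direction: np.ndarray | None = None
        self._direction_valid: np.ndarray | None = None

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FieldProxy(n_holes={self.layout.n_holes}, "
            f"sigma_bump={self.sigma_bump})"
        )

    # ---- analytic queries -------------------------------------------------
    def _dists(self, pts: np.ndarray) -> np.ndarray:
        """(n_pts, n_holes) centre distances."""
        pts = np.atleast_2d(pts)
        diff = pts[:, None, :] - self.layout.hole_centers[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])

    def grad_at(self, pts: np.ndarray) -> np.ndarray:
        """Sum of Gaussian rim bumps evaluated at float positions."""
        d = self._dists(pts)
        rim = np.abs(d - self.layout.hole_radius)
        return np.exp(-(rim**2) / (2 * self.sigma_bump**2)).sum(axis=1)

    def nearest_hole(self, pts: np.ndarray) -> np.ndarray:
        """Index of the hole whose rim is nearest; ties go to the lower index."""
        d = self._dists(pts)
        return np.argmin(np.abs(d - self.layout.hole_radius), axis=1)

    def direction_at(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors toward the nearest rim point, plus a validity mask.

        Inside a hole the vector points radially outward (toward the rim);
        outside it points radially inward.  On a hole centre the direction is
        undefined and flagged invalid (zero vector).
        """
        pts = np.atleast_2d(pts)
        d = self._dists(pts)
        idx = np.argmin(np.abs(d - self.layout.hole_radius), axis=1)
        centers = self.layout.hole_centers[idx]
        radial = pts - centers
        dist = d[np.arange(len(pts)), idx]
        ok = dist > 1e-9
        unit = np.zeros_like(radial)
        unit[ok] = radial[ok] / dist[ok, None]
        sign = np.where(dist < self.layout.hole_radius, 1.0, -1.0)
        return unit * sign[:, None], ok

    def radial_state(
        self, pts: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-point ``(hole_index, centre_distance, outward_unit_vector)``.

        The hole is the one whose rim is nearest (the cell's current basin);
        the unit vector points radially away from that hole's centre and is
        zero on the centre itself.
        """
        pts = np.atleast_2d(pts)
        d = self._dists(pts)
        idx = np.argmin(np.abs(d - self.layout.hole_radius), axis=1)
        dist = d[np.arange(len(pts)), idx]
        radial = pts - self.layout.hole_centers[idx]
        unit = np.zeros_like(radial)
        ok = dist > 1e-9
        unit[ok] = radial[ok] / dist[ok, None]
        return idx, dist, unit

    # ---- lazy grids -------------------------------------------------------
    def _build_grids(self) -> None:
        rows, cols = self.layout.image_shape
        grad = np.empty((rows, cols))
        direc = np.empty((rows, cols, 2))
        valid = np.empty((rows, cols), dtype=bool)
        xs = np.arange(cols, dtype=float)
        chunk = max(1, int(2_000_000 // max(cols * self.layout.n_holes, 1)))
        for r0 in range(0, rows, chunk):
            r1 = min(r0 + chunk, rows)
            ys = np.arange(r0, r1, dtype=float)
            yy, xx = np.meshgrid(ys, xs, indexing="ij")
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            grad[r0:r1] = self.grad_at(pts).reshape(r1 - r0, cols)
            d, ok = self.direction_at(pts)
            direc[r0:r1] = d.reshape(r1 - r0, cols, 2)
            valid[r0:r1] = ok.reshape(r1 - r0, cols)
        self._grad_e2, self._direction, self._direction_valid = grad, direc, valid

    @property
    def grad_e2(self) -> np.ndarray:
        if self._grad_e2 is None:
            self._build_grids()
        return self._grad_e2

    @property
    def direction(self) -> np.ndarray:
        if self._direction is None:
            self._build_grids()
        return self._direction

    @property
    def direction_valid(self) -> np.ndarray:
        if self._direction_valid is None:
            self._build_grids()
        return self._direction_valid


def field_proxy(layout: ChipLayout, sigma_bump: float | None = None) -> FieldProxy:
    """Build the field proxy for ``layout``.

    ``sigma_bump`` is the Gaussian rim-bump width in px (default:
    ``hole_radius / 4``).
    """
    if sigma_bump is None:
        sigma_bump = layout.hole_radius / 4.0
    return FieldProxy(layout=layout, sigma_bump=float(sigma_bump))
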