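"""Ground-truthed synthetic DEP experiments.

Cell kinematics use a force-balance surrogate: in the overdamped Stokes
regime the DEP drift velocity is proportional to Re[CM] * r_cell^2 *
|grad E_rms^2| along the local field-gradient direction.  The surrogate
replaces Re[CM](f) with a smooth odd sigmoid S(f) that changes sign exactly
at the cell's crossover frequency, so the observable the pipeline estimates
— the direction reversal at f_co — is preserved without integrating full
dielectric spectra:

    v = mobility_gain * S(f(t)) * r_cell^2 * grad_e2(p) * direction(p) + jitter

Radial steps never overshoot the current attractor (hole rim under pDEP,
hole centre under nDEP), which emulates trapping without sub-frame dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from deptrack.chip import ChipLayout, FieldProxy
from deptrack.schedule import FrequencySchedule

__all__ = [
    "CellSpec",
    "GroundTruthTrack",
    "simulate_tracks",
    "render_background",
    "render_frame",
    "corrupt_detections",
    "logistic_sign",
]

#: Default width (natural-log frequency units) of the sigmoidal pDEP/nDEP
#: transition.  Re[CM] of the single-shell model crosses zero on a
#: log-frequency scale, reaching ~2/3 of its low-frequency plateau about one
#: octave below f_co; 0.4 ln-units reproduces that slope.  See
#: docs/methods.md.
DEFAULT_TRANSITION_WIDTH_LN = 0.4


@dataclass(frozen=True)
class CellSpec:
    """Simulated-cell parameters: true crossover frequency (Hz), visible
    radius (px) and the start position (px)."""

    fco_true: float
    r_cell: float
    start_xy: tuple[float, float]


@dataclass
class GroundTruthTrack:
    """Per-frame ground-truth states of one simulated cell."""

    cell_id: int
    fco_true: float
    r_cell: float
    states: np.ndarray  # (n_frames, 2) of (x, y)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if not np.all(np.isfinite(self.states)):
            raise ValueError("ground-truth positions must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.states)


def logistic_sign(f, fco: float, width: float = DEFAULT_TRANSITION_WIDTH_LN):
    """Smooth polarity factor S(f) in (-1, 1), odd around ``fco`` in log-f.

    Low frequency => -1 (nDEP, motion toward low-field loci), high frequency
    => +1 (pDEP, motion toward the high-field rim); S(fco) = 0.  ``width``
    is the logistic scale in natural-log frequency units, mirroring the
    log-frequency transition of the single-shell Re[CM] curve.
    """
    return np.tanh(np.log(np.asarray(f, dtype=float) / fco) / (2.0 * width))


def simulate_tracks(
    layout: ChipLayout,
    field: FieldProxy,
    cells: list[CellSpec],
    schedule: FrequencySchedule,
    mobility_gain: float = 0.17,
    diffusion_sigma: float = 0.15,
    seed: int = 0,
    transition_width: float = DEFAULT_TRANSITION_WIDTH_LN,
    n_frames: int | None = None,
    rim_offset: float = 3.0,
    trapped_jitter_factor: float = 0.1,
) -> list[GroundTruthTrack]:
    """Integrate cell positions over the schedule at the schedule's frame rate.

    ``mobility_gain`` converts ``r_cell^2 * grad_e2`` (px^2 * proxy units) to
    px/s; ``diffusion_sigma`` is the per-frame, per-axis Gaussian jitter (px).
    Cells resting on their attractor (hole rim under pDEP, hole centre under
    nDEP) are in mechanical contact with the substrate and their Brownian
    jitter is damped by ``trapped_jitter_factor``; they are released the
    moment the polarity factor changes sign.  Randomness comes from one
    generator per cell, seeded by ``(seed, cell_id)`` so that results are
    independent of the cell count.  Positions are clamped to the image by
    reflection.  With ``diffusion_sigma=0`` the result is bitwise
    reproducible.
    """
    if n_frames is None:
        n_frames = schedule.n_frames
    rows, cols = layout.image_shape
    n_cells = len(cells)
    pos = np.array([c.start_xy for c in cells], dtype=float)
    if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] > cols - 1):
        raise ValueError("cells must start inside the image")
    if np.any(pos[:, 1] < 0) or np.any(pos[:, 1] > rows - 1):
        raise ValueError("cells must start inside the image")
    fco = np.array([c.fco_true for c in cells])
    r2 = np.array([c.r_cell for c in cells]) ** 2
    dt = 1.0 / schedule.fps
    R = layout.hole_radius

    if diffusion_sigma > 0:
        jitter = np.stack(
            [
                np.random.default_rng([seed, i]).normal(
                    0.0, diffusion_sigma, size=(n_frames, 2)
                )
                for i in range(n_cells)
            ],
            axis=1,
        )  # (n_frames, n_cells, 2)
    else:
        jitter = np.zeros((n_frames, n_cells, 2))

    times = schedule.t_start + np.arange(n_frames) / schedule.fps
    freqs = np.asarray(schedule.freq_at(times))
    states = np.empty((n_frames, n_cells, 2))
    states[0] = pos

    for t in range(1, n_frames):
        s_pol = logistic_sign(freqs[t - 1], fco, transition_width)
        idx, d, unit = field.radial_state(pos)
        grad = field.grad_at(pos)
        speed = mobility_gain * np.abs(s_pol) * r2 * grad * dt  # px/frame
        inside = d < R
        pdep = s_pol > 0
        # Radial step toward/away from the current attractor without
        # overshoot.  The pDEP trap point sits ``rim_offset`` px inside the
        # rim line: a finite-size cell resting against the hole wall keeps
        # its centroid slightly inside, so nDEP departures start inward.
        # The nDEP clamp stops just short of the centre, where the radial
        # direction is undefined.
        rim_target = R - rim_offset
        new_d = np.where(
            pdep,
            d + np.sign(rim_target - d) * np.minimum(speed, np.abs(rim_target - d)),
            np.where(inside, np.maximum(d - speed, 0.01), d + speed),
        )
        attractor = np.where(pdep, rim_target, 0.01)
        pinned = (np.abs(new_d - attractor) < 1e-9) & (speed > 0) & (inside | pdep)
        jit = jitter[t] * np.where(pinned, trapped_jitter_factor, 1.0)[:, None]
        centers = layout.hole_centers[idx]
        pos = centers + unit * new_d[:, None] + jit
        # reflecting clamp at the image bounds
        pos[:, 0] = np.abs(pos[:, 0])
        pos[:, 0] = (cols - 1) - np.abs((cols - 1) - pos[:, 0])
        pos[:, 1] = np.abs(pos[:, 1])
        pos[:, 1] = (rows - 1) - np.abs((rows - 1) - pos[:, 1])
        states[t] = pos

    return [
        GroundTruthTrack(
            cell_id=i, fco_true=cells[i].fco_true, r_cell=cells[i].r_cell,
            states=states[:, i],
        )
        for i in range(n_cells)
    ]


# ---- rendering -----------------------------------------------------------

BACKGROUND_LEVEL = 120.0
HOLE_INTERIOR_LEVEL = 100.0
RIM_LEVEL = 60.0
CELL_PEAK_LEVEL = 220.0
VIGNETTE_FLOOR = 20.0


def render_background(layout: ChipLayout, vignette: bool = True) -> np.ndarray:
    """Deterministic float background: electrode plane with darker hole
    interiors, dark rim annuli and an optional circular vignette."""
    rows, cols = layout.image_shape
    bg = np.full((rows, cols), BACKGROUND_LEVEL)
    yy, xx = np.mgrid[0:rows, 0:cols]
    for cx, cy in layout.hole_centers:
        d = np.hypot(xx - cx, yy - cy)
        bg[d < layout.hole_radius] = HOLE_INTERIOR_LEVEL
        bg[np.abs(d - layout.hole_radius) < 1.5] = RIM_LEVEL
    if vignette:
        cx, cy = layout.fov_center
        out = np.hypot(xx - cx, yy - cy) > layout.fov_radius
        bg[out] = VIGNETTE_FLOOR
    return bg


def _paint_cell(img: np.ndarray, x: float, y: float, r: float) -> None:
    """Draw one radially shaded cell disc (soft 1-px edge) into ``img``."""
    rows, cols = img.shape
    x0, x1 = int(np.floor(x - r - 2)), int(np.ceil(x + r + 2)) + 1
    y0, y1 = int(np.floor(y - r - 2)), int(np.ceil(y + r + 2)) + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, cols), min(y1, rows)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - x, yy - y)
    cover = np.clip(r + 0.5 - d, 0.0, 1.0)  # anti-aliased sharp disc
    patch = img[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = patch + cover * (CELL_PEAK_LEVEL - patch)


def render_frame(
    layout: ChipLayout,
    tracks: list[GroundTruthTrack],
    t: int,
    noise_sigma: float = 3.0,
    vignette: bool = True,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Render frame ``t`` as an 8-bit grayscale image.

    ``background`` may be precomputed with :func:`render_background` to
    amortize the static part over a sequence.  Noise is additive Gaussian,
    seeded by ``(seed, t)`` so individual frames are reproducible.
    """
    if background is None:
        background = render_background(layout, vignette=vignette)
    img = background.copy()
    for tr in tracks:
        if not (0 <= t < tr.n_frames):
            raise ValueError(f"frame {t} outside track span")
        x, y = tr.states[t]
        _paint_cell(img, x, y, tr.r_cell)
    if noise_sigma > 0:
        rng = np.random.default_rng([seed, t])
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---- detection-stream corruption ------------------------------------------


def corrupt_detections(
    tracks: list[GroundTruthTrack],
    p_miss: float = 0.0,
    p_fp: float = 0.0,
    pos_sigma: float = 0.0,
    seed: int = 0,
    layout: ChipLayout | None = None,
    fp_radius: float | None = None,
) -> pd.DataFrame:
    """Derive a corrupted detection stream from ground-truth tracks.

    Each ground-truth state survives with probability ``1 - p_miss`` and is
    jittered by N(0, pos_sigma^2) per axis; ``Poisson(p_fp)`` spurious
    detections per frame are placed uniformly in the FoV disk (requires
    ``layout`` when ``p_fp > 0``).  Returns a DataFrame with columns
    ``frame, x, y, w, h, score`` (w = h = 2 r).
    """
    if not (0 <= p_miss < 1) or p_fp < 0:
        raise ValueError("p_miss must be in [0, 1) and p_fp >= 0")
    rng = np.random.default_rng([seed, 0xD_EC])
    n_frames = tracks[0].n_frames if tracks else 0
    rows = []
    for tr in tracks:
        keep = rng.random(n_frames) >= p_miss
        noise = (
            rng.normal(0.0, pos_sigma, size=(n_frames, 2))
            if pos_sigma > 0
            else np.zeros((n_frames, 2))
        )
        frames = np.nonzero(keep)[0]
        xy = tr.states[frames] + noise[frames]
        for f, (x, y) in zip(frames, xy):
            rows.append((int(f), x, y, 2 * tr.r_cell, 2 * tr.r_cell, 1.0))
    if p_fp > 0:
        if layout is None:
            raise ValueError("layout required to place false positives")
        if fp_radius is None:
            fp_radius = float(np.median([tr.r_cell for tr in tracks])) if tracks else 6.0
        cx, cy = layout.fov_center
        for f in range(n_frames):
            for _ in range(rng.poisson(p_fp)):
                ang = rng.uniform(0, 2 * np.pi)
                rad = layout.fov_radius * np.sqrt(rng.random())
                rows.append(
                    (
                        f,
                        cx + rad * np.cos(ang),
                        cy + rad * np.sin(ang),
                        2 * fp_radius,
                        2 * fp_radius,
                        0.5,
                    )
                )
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "w", "h", "score"])
    return df.sort_values(["frame", "x", "y"], kind="stable").reset_index(drop=True)
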