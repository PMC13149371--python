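"""Bundled synthetic experiments: study-condition defaults and end-to-end
estimator drivers.

The default chip is a regular array of 20-px circular holes at 72-px pitch
with a broad rim field bump (``sigma_bump = hole_radius``), sized so the
grid sits inside the circular FoV.  Cells get true crossover frequencies
drawn uniformly in 15-35 kHz, visible radii of 5-7 px, and start trapped
near their hole centres; the kinematic gain is set so a 6-px cell drifts at
roughly 6 px/s in the rim annulus.  See docs/methods.md for the rationale
behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from deptrack.chip import ChipLayout, FieldProxy, field_proxy, make_chip_layout
from deptrack.fco import (
    FcoEstimate,
    MobilitySample,
    fit_zero_crossing,
    intensity_fco,
    probe_intensity,
    ring_velocity,
    select_ring,
    trapped_site,
)
from deptrack.schedule import FrequencySchedule, Segment, default_protocol
from deptrack.simulate import (
    CellSpec,
    GroundTruthTrack,
    corrupt_detections,
    render_background,
    render_frame,
    simulate_tracks,
)

__all__ = [
    "ExperimentConfig",
    "SyntheticExperiment",
    "make_experiment",
    "tracking_schedule",
    "velocity_estimates",
    "intensity_estimates",
]

HOLE_RADIUS_PX = 20.0
HOLE_PITCH_PX = 96.0  # wide enough that neighbouring rim bumps do not couple
SIGMA_BUMP_PX = HOLE_RADIUS_PX  # broad rim bump: finite gradient at hole centres
MOBILITY_GAIN = 0.17  # px/s per (px^2 * proxy gradient unit)
# Stokes-Einstein: D = kT/(6 pi eta r) ~ 4.4e-14 m^2/s for r = 9.5 um in
# water; at ~1.07 um/px and 10 fps, sigma = sqrt(2 D dt) ~ 0.09 px per axis.
DIFFUSION_SIGMA_PX = 0.09
RENDER_NOISE_SIGMA = 3.0
FCO_RANGE_KHZ = (15.0, 35.0)
CELL_RADIUS_RANGE_PX = (5.0, 7.0)


@dataclass(frozen=True)
class ExperimentConfig:
    n_cells: int = 50
    seed: int = 0
    fco_range_hz: tuple[float, float] = (FCO_RANGE_KHZ[0] * 1e3, FCO_RANGE_KHZ[1] * 1e3)
    r_cell_range_px: tuple[float, float] = CELL_RADIUS_RANGE_PX
    mobility_gain: float = MOBILITY_GAIN
    diffusion_sigma: float = DIFFUSION_SIGMA_PX
    noise_sigma: float = RENDER_NOISE_SIGMA


@dataclass
class SyntheticExperiment:
    """A generated chip + cell population + schedule, before integration."""

    layout: ChipLayout
    field: FieldProxy
    cells: list[CellSpec]
    schedule: FrequencySchedule
    config: ExperimentConfig
    tracks: list[GroundTruthTrack] = dc_field(default_factory=list)

    def run(self, n_frames: int | None = None) -> list[GroundTruthTrack]:
        self.tracks = simulate_tracks(
            self.layout,
            self.field,
            self.cells,
            self.schedule,
            mobility_gain=self.config.mobility_gain,
            diffusion_sigma=self.config.diffusion_sigma,
            seed=self.config.seed,
            n_frames=n_frames,
        )
        return self.tracks


def _grid_for(n_cells: int) -> tuple[int, int]:
    cols = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / cols))
    return rows, cols


def _layout_for(rows: int, cols: int) -> ChipLayout:
    half_w = (cols - 1) / 2.0 * HOLE_PITCH_PX
    half_h = (rows - 1) / 2.0 * HOLE_PITCH_PX
    half_diag = float(np.hypot(half_w, half_h))
    side = int(np.ceil((half_diag + HOLE_RADIUS_PX + 24) * 2 / 16.0)) * 16
    return make_chip_layout(rows, cols, HOLE_PITCH_PX, HOLE_RADIUS_PX, (side, side))


def tracking_schedule(fps: float = 10.0) -> FrequencySchedule:
    """Short protocol for tracking benchmarks: nDEP hold, pDEP hold, nDEP
    hold (two polarity switches, 500 frames at 10 fps)."""
    return FrequencySchedule(
        [
            Segment(0.0, 15.0, "static", 1e3, 1e3, role="trap"),
            Segment(15.0, 35.0, "static", 41e3, 41e3, role="trap"),
            Segment(35.0, 50.0, "static", 1e3, 1e3, role="trap"),
        ],
        fps=fps,
    )


def make_experiment(
    config: ExperimentConfig = ExperimentConfig(),
    schedule: FrequencySchedule | None = None,
) -> SyntheticExperiment:
    """Build the default chip and cell population for ``config``.

    One cell per hole: each starts 2 px off its hole centre (trapped under
    the initial nDEP hold), with f_co and radius drawn from the configured
    ranges using the experiment seed.
    """
    rows, cols = _grid_for(config.n_cells)
    layout = _layout_for(rows, cols)
    field = field_proxy(layout, sigma_bump=SIGMA_BUMP_PX)
    rng = np.random.default_rng([config.seed, 0xCE11])
    fco = rng.uniform(*config.fco_range_hz, size=config.n_cells)
    r_cell = rng.uniform(*config.r_cell_range_px, size=config.n_cells)
    angles = rng.uniform(0, 2 * np.pi, size=config.n_cells)
    cells = []
    for i in range(config.n_cells):
        cx, cy = layout.hole_centers[i]
        cells.append(
            CellSpec(
                fco_true=float(fco[i]),
                r_cell=float(r_cell[i]),
                start_xy=(cx + 2 * np.cos(angles[i]), cy + 2 * np.sin(angles[i])),
            )
        )
    if schedule is None:
        schedule = default_protocol()
    return SyntheticExperiment(layout, field, cells, schedule, config)


# ---- velocity-method driver ------------------------------------------------


def velocity_estimates(
    tracks: list[GroundTruthTrack] | list,
    field: FieldProxy,
    schedule: FrequencySchedule,
    cv_max: float = 0.10,
) -> list[FcoEstimate]:
    """Velocity-based f_co for every track over the schedule's test segments.

    For each static test segment the cell's radial distance to its nearest
    hole centre is scanned for a transit through the shared measurement
    annulus; the signed transit velocities across all test frequencies are
    fitted for the zero crossing.
    """
    ring = select_ring(field, cv_max=cv_max)
    tests = schedule.tests()
    out = []
    for tr in tracks:
        pts = _positions(tr)
        samples = []
        for seg in tests:
            frames = schedule.segment_frames(seg)
            frames = frames[frames < len(pts)]
            if len(frames) < 3:
                continue
            _, d, _ = field.radial_state(pts[frames])
            v = ring_velocity(d, ring, schedule.fps)
            if v is not None:
                samples.append(
                    MobilitySample(f=seg.f_start, v_signed=v, r_cell=_radius(tr))
                )
        est = fit_zero_crossing(samples, cell_id=_cell_id(tr))
        est.diagnostics["n_samples"] = len(samples)
        out.append(est)
    return out


# ---- intensity-method driver ------------------------------------------------


def intensity_estimates(
    layout: ChipLayout,
    tracks: list[GroundTruthTrack],
    schedule: FrequencySchedule,
    seed: int = 0,
    noise_sigma: float = RENDER_NOISE_SIGMA,
    baseline_frames: int = 50,
    probe_margin: float = 0.0,
    k_sigma: float = 3.0,
) -> list[FcoEstimate]:
    """Trapped-intensity f_co per cell, averaged over all sweep segments.

    For each sweep, each cell's trapped site is estimated from the tail of
    the preceding static hold, and frames spanning the baseline window plus
    the sweep are rendered on the fly to extract probe-intensity traces.
    Per-sweep estimates are averaged per cell; cells with no valid trigger
    on any sweep are returned invalid.
    """
    sweeps = schedule.sweeps()
    background = render_background(layout)
    per_cell: dict[int, list[FcoEstimate]] = {tr.cell_id: [] for tr in tracks}
    for sweep in sweeps:
        seg_idx = schedule.segments.index(sweep)
        if seg_idx == 0:
            continue
        hold = schedule.segments[seg_idx - 1]
        hold_frames = schedule.segment_frames(hold)
        base = hold_frames[-baseline_frames:]
        sweep_frames = schedule.segment_frames(sweep)
        if len(sweep_frames) == 0 or sweep_frames[-1] >= tracks[0].n_frames:
            continue
        sites = [
            trapped_site(tr.states, static_window=(int(base[0]), int(base[-1]) + 1))
            for tr in tracks
        ]
        window = np.arange(base[0], sweep_frames[-1] + 1)
        traces = np.empty((len(tracks), len(window)))
        for k, t in enumerate(window):
            frame = render_frame(
                layout,
                tracks,
                int(t),
                noise_sigma=noise_sigma,
                seed=seed,
                background=background,
            )
            for i, (tr, site) in enumerate(zip(tracks, sites)):
                traces[i, k] = probe_intensity(
                    frame, site.center, tr.r_cell + probe_margin
                )
        for i, tr in enumerate(tracks):
            if not sites[i].valid:
                continue
            est = intensity_fco(
                traces[i],
                schedule,
                sweep,
                baseline_frames=base,
                k_sigma=k_sigma,
                trace_offset=int(window[0]),
                cell_id=tr.cell_id,
            )
            if est.valid:
                per_cell[tr.cell_id].append(est)
    out = []
    for tr in tracks:
        ests = per_cell[tr.cell_id]
        if ests:
            # median across sweeps: robust to one spurious trigger
            fco = float(np.median([e.fco for e in ests]))
            out.append(
                FcoEstimate(
                    tr.cell_id,
                    fco,
                    "intensity",
                    {"n_sweeps": len(ests), "per_sweep": [e.fco for e in ests]},
                    valid=True,
                )
            )
        else:
            out.append(
                FcoEstimate(tr.cell_id, float("nan"), "intensity",
                            {"reason": "no valid sweep trigger"}, valid=False)
            )
    return out


# ---- corrupted-stream shortcut ----------------------------------------------


def benchmark_detections(
    exp: SyntheticExperiment,
    p_miss: float = 0.0,
    p_fp: float = 0.0,
    pos_sigma: float = 0.0,
):
    """Detection stream for the experiment's simulated tracks."""
    return corrupt_detections(
        exp.tracks,
        p_miss=p_miss,
        p_fp=p_fp,
        pos_sigma=pos_sigma,
        seed=exp.config.seed,
        layout=exp.layout,
    )


def _positions(tr) -> np.ndarray:
    if hasattr(tr, "positions"):
        return tr.positions()
    return np.asarray(tr.states, dtype=float)


def _radius(tr) -> float:
    if hasattr(tr, "r_cell"):
        return float(tr.r_cell)
    return float(np.mean([s.r for s in tr.states]))


def _cell_id(tr) -> int:
    return int(tr.cell_id)
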