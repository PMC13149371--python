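"""Crossover-frequency (f_co) estimation from reconstructed trajectories.

Two complementary estimators:

* **Trapped-intensity method** (frequency sweeps): a cell trapped at a
  static frequency sits at a fixed locus; during a sweep, the image
  intensity at that locus deviates abruptly when the DEP force reverses and
  the cell escapes.  The first sweep frame whose probe intensity deviates
  from the trapped baseline by more than ``k_sigma`` baseline standard
  deviations marks the crossover, and the applied frequency at that frame
  is the estimate.

* **Velocity method** (static test frequencies): in an annulus of nearly
  constant field-gradient magnitude, the drift velocity satisfies
  Re[CM] = 3 eta v / (r^2 eps_medium |grad E_rms^2|), i.e. the
  radius-normalised mobility v / r^2 is proportional to Re[CM].  Signed
  mobilities sampled across test frequencies are fitted with a four-
  parameter logistic whose root is the frequency where Re[CM] = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from deptrack.chip import FieldProxy
from deptrack.schedule import FrequencySchedule, Segment

__all__ = [
    "TrappedSite",
    "RingRegion",
    "MobilitySample",
    "FcoEstimate",
    "trapped_site",
    "intensity_trace",
    "probe_intensity",
    "intensity_fco",
    "select_ring",
    "ring_velocity",
    "recm_from_velocity",
    "fit_zero_crossing",
    "population_summary",
]


@dataclass
class TrappedSite:
    """Robust mean/covariance of a trapped cell's position."""

    center: np.ndarray  # (x, y)
    covariance: np.ndarray  # 2x2
    gate: float  # Mahalanobis^2 threshold used
    n_used: int = 0
    valid: bool = True


@dataclass(frozen=True)
class RingRegion:
    """Annulus of nearly constant gradient magnitude around a hole centre.

    ``center=None`` denotes the generic annulus shared by every hole of a
    symmetric layout; radial coordinates are then taken relative to the
    cell's current nearest hole.
    """

    r_in: float
    r_out: float
    grad_e2_ref: float
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.r_in < self.r_out):
            raise ValueError("require 0 < r_in < r_out")


@dataclass(frozen=True)
class MobilitySample:
    """One (frequency, signed velocity) observation for one cell."""

    f: float  # Hz
    v_signed: float  # px/s, positive toward the high-field rim
    r_cell: float  # px

    @property
    def mobility(self) -> float:
        """Radius-normalised velocity v / r^2 (px^-1 s^-1)."""
        return self.v_signed / self.r_cell**2


@dataclass
class FcoEstimate:
    cell_id: int
    fco: float  # Hz (nan when invalid)
    method: str  # "intensity" | "velocity"
    diagnostics: dict = field(default_factory=dict)
    valid: bool = True


# ---- trapped-site estimation ----------------------------------------------


def trapped_site(
    track,
    static_window: tuple[int, int] | None = None,
    gate_p: float = 0.975,
    max_iter: int = 25,
) -> TrappedSite:
    """Robust trapped-position estimate over a static-frequency window.

    Iteratively fits mean and covariance to the window positions, discards
    points whose squared Mahalanobis distance exceeds the chi-square(2)
    quantile at ``gate_p``, and refits until the inlier set is stable.
    Requires at least 10 states; a degenerate covariance (e.g. a perfectly
    still cell) yields an invalid site carrying the plain mean.
    """
    pts = track.states if hasattr(track, "states") else np.asarray(track, dtype=float)
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    if static_window is not None:
        t0, t1 = static_window
        pts = pts[t0:t1]
    if len(pts) < 10:
        raise ValueError("trapped_site needs at least 10 states")
    gate = stats.chi2.ppf(gate_p, df=2)
    keep = np.ones(len(pts), dtype=bool)
    for _ in range(max_iter):
        mean = pts[keep].mean(axis=0)
        cov = np.cov(pts[keep].T)
        if not np.all(np.isfinite(cov)) or np.linalg.det(cov) < 1e-12:
            return TrappedSite(mean, np.asarray(cov), gate, int(keep.sum()), valid=False)
        inv = np.linalg.inv(cov)
        diff = pts - mean
        m2 = np.einsum("ni,ij,nj->n", diff, inv, diff)
        new_keep = m2 <= gate
        if not new_keep.any():
            return TrappedSite(mean, cov, gate, 0, valid=False)
        if np.array_equal(new_keep, keep):
            return TrappedSite(mean, cov, gate, int(keep.sum()), valid=True)
        keep = new_keep
    return TrappedSite(mean, cov, gate, int(keep.sum()), valid=True)


# ---- intensity method ------------------------------------------------------


def probe_intensity(frame: np.ndarray, center, probe_radius: float) -> float:
    """Mean pixel intensity over the probe disc; off-grid pixels excluded."""
    rows, cols = frame.shape
    cx, cy = float(center[0]), float(center[1])
    x0 = max(int(np.floor(cx - probe_radius)), 0)
    x1 = min(int(np.ceil(cx + probe_radius)) + 1, cols)
    y0 = max(int(np.floor(cy - probe_radius)), 0)
    y1 = min(int(np.ceil(cy + probe_radius)) + 1, rows)
    if x0 >= x1 or y0 >= y1:
        return float("nan")
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = np.hypot(xx - cx, yy - cy) <= probe_radius
    if not sel.any():
        return float("nan")
    return float(np.asarray(frame, dtype=float)[y0:y1, x0:x1][sel].mean())


def intensity_trace(frames, site: TrappedSite, probe_radius: float) -> np.ndarray:
    """Per-frame mean probe intensity at ``site.center``.

    ``frames`` is any iterable of 2-D arrays (a full stack or a generator).
    """
    return np.array([probe_intensity(f, site.center, probe_radius) for f in frames])


def intensity_fco(
    trace: np.ndarray,
    schedule: FrequencySchedule,
    sweep: Segment,
    baseline_frames: np.ndarray,
    k_sigma: float = 3.0,
    persistence: int = 3,
    trace_offset: int = 0,
    cell_id: int = -1,
) -> FcoEstimate:
    """Crossover frequency from a trapped-intensity trace.

    ``trace[t - trace_offset]`` is the probe intensity of absolute frame
    ``t``.  Baseline mean/std come from ``baseline_frames`` (typically the
    tail of the trap hold preceding the sweep); the estimate is the applied
    frequency at the first sweep frame opening a run of at least
    ``persistence`` consecutive frames with ``|I - mu| > k_sigma * sigma``.
    (A single-frame 3-sigma excursion recurs by chance about every 370
    frames of Gaussian noise; a genuine escape deviates for hundreds of
    consecutive frames, so persistence suppresses false triggers without
    delaying real ones.)  A flat baseline (sigma = 0) or the absence of a
    trigger yields an invalid estimate.
    """
    trace = np.asarray(trace, dtype=float)
    base = trace[np.asarray(baseline_frames, dtype=int) - trace_offset]
    mu, sigma = float(np.nanmean(base)), float(np.nanstd(base))
    diag = {"mu": mu, "sigma": sigma, "k_sigma": k_sigma}
    if sigma == 0 or not np.isfinite(sigma):
        return FcoEstimate(cell_id, float("nan"), "intensity",
                           {**diag, "reason": "degenerate baseline"}, valid=False)
    frames = schedule.segment_frames(sweep)
    vals = trace[frames - trace_offset]
    over = np.isfinite(vals) & (np.abs(vals - mu) > k_sigma * sigma)
    run = 0
    for i in range(len(frames)):
        run = run + 1 if over[i] else 0
        if run >= persistence:
            t = int(frames[i - persistence + 1])
            fco = float(schedule.freq_at(schedule.frame_time(t)))
            return FcoEstimate(
                cell_id, fco, "intensity", {**diag, "trigger_frame": t}, valid=True
            )
    return FcoEstimate(cell_id, float("nan"), "intensity",
                       {**diag, "reason": "no crossover observed"}, valid=False)


# ---- velocity method -------------------------------------------------------


def select_ring(
    field: FieldProxy,
    cv_max: float = 0.10,
    margin: float = 4.0,
    step: float = 0.25,
) -> RingRegion:
    """Widest inner annulus with gradient coefficient of variation <= cv_max.

    The annulus lies strictly inside the hole, ending ``margin`` px short of
    the rim to exclude the arrival/trapping zone where pDEP cells dwell.
    Returned radii are relative to any hole centre of the (symmetric)
    layout.
    """
    R = field.layout.hole_radius
    cx, cy = field.layout.hole_centers[0]
    r_out = R - margin
    if r_out <= step:
        raise ValueError("hole too small for a measurement annulus")
    radii = np.arange(step, r_out + step / 2, step)
    pts = np.column_stack([cx + radii, np.full_like(radii, cy)])
    g = field.grad_at(pts)
    best = None
    for i in range(len(radii)):
        vals = g[i:]
        cv = vals.std() / vals.mean()
        if cv <= cv_max:
            best = (radii[i], r_out, float(vals.mean()))
            break
    if best is None:
        best = (radii[-1], r_out, float(g[-1]))
    return RingRegion(r_in=best[0], r_out=best[1], grad_e2_ref=best[2])


def ring_velocity(
    radial_dist: np.ndarray,
    ring: RingRegion,
    fps: float,
    min_frames: int = 2,
    min_span_frac: float = 0.5,
    estimator: str = "slope",
) -> float | None:
    """Signed radial transit velocity (px/s) through the annulus.

    ``radial_dist[t]`` is the distance of the cell from its hole centre in
    consecutive frames of one static-frequency segment.  The first
    contiguous in-ring run spanning at least ``min_span_frac`` of the ring
    width yields the travel-distance-over-transit-time velocity: with
    ``estimator="endpoints"`` literally ``(d_last - d_first) / transit_time``;
    the default ``"slope"`` is the least-squares radial slope over the run,
    which is identical for uniform motion but insensitive to the +/- one
    frame timing noise of the boundary crossings.  Positive values mean
    outward motion toward the high-field rim.  Returns None when the track
    never crosses the ring (or merely grazes it).
    """
    d = np.asarray(radial_dist, dtype=float)
    inside = (d >= ring.r_in) & (d <= ring.r_out)
    width = ring.r_out - ring.r_in
    t = 0
    n = len(d)
    while t < n:
        if not inside[t]:
            t += 1
            continue
        t1 = t
        while t1 + 1 < n and inside[t1 + 1]:
            t1 += 1
        span = abs(d[t1] - d[t])
        if t1 - t + 1 >= min_frames and span >= min_span_frac * width:
            if estimator == "endpoints" or t1 - t < 2:
                return float((d[t1] - d[t]) / ((t1 - t) / fps))
            # boundary frames are selection-biased (diffusive entry/exit
            # lingers near the ring edges); trim them from long runs
            a, b = t, t1
            if b - a + 1 >= 10:
                a, b = a + 2, b - 2
            times = np.arange(a, b + 1) / fps
            return float(np.polyfit(times, d[a : b + 1], 1)[0])
        t = t1 + 1
    return None


def recm_from_velocity(
    v: float, r_cell: float, eta: float, eps_medium: float, grad_e2: float
) -> float:
    """Re[CM] from the DEP/drag force balance, 3*eta*v / (r^2 * eps * grad).

    All quantities in SI units (``eps_medium`` absolute, F/m).  The sign of
    the result is the sign of ``v``.
    """
    denom = r_cell**2 * eps_medium * grad_e2
    if denom == 0 or eta <= 0:
        raise ValueError("denominator terms must be positive")
    return 3.0 * eta * v / denom


def _logistic4(f, l1, l2, k, f0):
    return l1 + (l2 - l1) / (1.0 + np.exp(-np.clip(k * (f - f0), -500, 500)))


def fit_zero_crossing(
    samples: list[MobilitySample], cell_id: int = -1, x_scale: str = "log"
) -> FcoEstimate:
    """Four-parameter logistic fit of mobility vs frequency; f_co is its root.

    Requires at least four samples with both mobility signs present.  By
    default the logistic is fitted against log-frequency — the protocol's
    test frequencies span almost two decades and the Re[CM] transition is
    sigmoidal on a log axis; ``x_scale="linear"`` fits against frequency
    directly.  The fit is initialised from the sign-change bracket, with
    the plateaus loosely bounded by the observed mobility extremes (the
    outermost test frequencies sit far from any plausible crossover, so the
    extreme samples are near-saturated; unbounded, the 4PL depth/slope
    trade-off is ill-posed when one branch is sampled over a narrow band).
    The root ``x0 - ln((l2 - l1)/(-l1) - 1)/k`` exists whenever the fitted
    plateaus straddle zero; estimates outside the sampled frequency hull
    (with a one-bracket margin) are marked invalid.
    """
    if len(samples) < 4:
        return FcoEstimate(cell_id, float("nan"), "velocity",
                           {"reason": "too few samples"}, valid=False)
    order = np.argsort([s.f for s in samples])
    f = np.array([samples[i].f for i in order])
    m = np.array([samples[i].mobility for i in order])
    if m.min() >= 0 or m.max() <= 0:
        return FcoEstimate(cell_id, float("nan"), "velocity",
                           {"reason": "no crossover in tested range"}, valid=False)
    x = np.log(f) if x_scale == "log" else f.copy()
    sc = np.nonzero(np.diff(np.sign(m)) != 0)[0]
    i = sc[0]
    x_lo, x_hi = x[i], x[i + 1]
    span = x[-1] - x[0]
    p0 = [m.min(), m.max(), 4.0 / max(x_hi - x_lo, 1e-9), 0.5 * (x_lo + x_hi)]
    lo = [3.0 * m.min(), 0.5 * m.max(), 0.5 / span, x[0]]
    hi = [0.5 * m.min(), 3.0 * m.max(), 1e4 / span, x[-1]]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = optimize.curve_fit(
            _logistic4, x, m, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError):
        return FcoEstimate(cell_id, float("nan"), "velocity",
                           {"reason": "fit failed"}, valid=False)
    l1, l2, k, x0 = popt
    if not (l1 < 0 < l2) or k == 0:
        return FcoEstimate(cell_id, float("nan"), "velocity",
                           {"reason": "fitted plateaus do not straddle zero"},
                           valid=False)
    ratio = (l2 - l1) / (-l1) - 1.0
    if ratio <= 0:
        return FcoEstimate(cell_id, float("nan"), "velocity",
                           {"reason": "no root"}, valid=False)
    root = x0 - np.log(ratio) / k
    margin = x_hi - x_lo
    valid = (x[0] - margin) <= root <= (x[-1] + margin)
    fco = float(np.exp(root)) if x_scale == "log" else float(root)
    return FcoEstimate(
        cell_id,
        fco,
        "velocity",
        {"l1": float(l1), "l2": float(l2), "k": float(k), "x0": float(x0),
         "x_scale": x_scale},
        valid=bool(valid),
    )


# ---- population summary ----------------------------------------------------


def population_summary(estimates: list[FcoEstimate], bins: int = 10) -> dict:
    """Per-method population statistics of the valid estimates."""
    out: dict = {"n_total": len(estimates)}
    methods = sorted({e.method for e in estimates})
    for meth in methods:
        vals = np.array([e.fco for e in estimates if e.method == meth and e.valid])
        n_invalid = sum(1 for e in estimates if e.method == meth and not e.valid)
        entry = {"n_valid": int(len(vals)), "n_invalid": int(n_invalid)}
        if len(vals):
            q1, q3 = np.percentile(vals, [25, 75])
            hist, edges = np.histogram(vals, bins=bins)
            entry.update(
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=0)),
                median=float(np.median(vals)),
                iqr=float(q3 - q1),
                hist_counts=hist.tolist(),
                hist_edges=edges.tolist(),
            )
        out[meth] = entry
    return out
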