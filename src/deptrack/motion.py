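"""Frame-wise displacement profile and rapid-motion detection.

Polarity switching between pDEP and nDEP causes abrupt, population-wide
displacement bursts.  Before any identities exist, the per-frame mean
displacement is estimated from mutual-nearest-neighbour pairs between
consecutive detection sets; frames where this series has a local maximum
exceeding a fraction ``lam`` of the global maximum are flagged as rapid,
and the tracker relaxes its association gates in a halo around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from deptrack.detection import Detection

__all__ = [
    "MotionProfile",
    "frame_displacement",
    "rapid_motion_frames",
    "merge_intervals",
    "regime_of_frame",
    "motion_profile",
]


def _xy(dets) -> np.ndarray:
    return np.array(
        [[d.x, d.y] if isinstance(d, Detection) else d[:2] for d in dets], dtype=float
    ).reshape(-1, 2)


def frame_displacement(dets_t, dets_t1, pair_cap: float) -> tuple[float, int]:
    """Mean displacement between consecutive frames over mutual-NN pairs.

    Points in frame t and t+1 are paired when each is the other's nearest
    neighbour and their distance is at most ``pair_cap`` px.  Returns
    ``(mean distance, n_pairs)``; with zero pairs the displacement is
    undefined and returned as ``(nan, 0)``.
    """
    a, b = _xy(dets_t), _xy(dets_t1)
    if len(a) == 0 or len(b) == 0:
        return float("nan"), 0
    dist = np.hypot(a[:, 0:1] - b[None, :, 0], a[:, 1:2] - b[None, :, 1])
    fwd = np.argmin(dist, axis=1)
    bwd = np.argmin(dist, axis=0)
    i = np.arange(len(a))
    mutual = bwd[fwd] == i
    within = dist[i, fwd] <= pair_cap
    sel = mutual & within
    if not sel.any():
        return float("nan"), 0
    return float(dist[i[sel], fwd[sel]].mean()), int(sel.sum())


def rapid_motion_frames(
    delta: np.ndarray, lam: float = 0.5, window: int = 5
) -> np.ndarray:
    """Frames that are strict local maxima of the displacement series and
    reach at least ``lam * max(delta)``.

    A frame is a strict local maximum when its displacement exceeds every
    defined value within ``+/- window`` frames; NaN gaps are ignored.  The
    global maximum is taken over the whole series (two-pass, offline).
    """
    delta = np.asarray(delta, dtype=float)
    if len(delta) < 3:
        raise ValueError("series too short")
    if np.all(np.isnan(delta)):
        return np.array([], dtype=int)
    thr = lam * np.nanmax(delta)
    out = []
    for t in range(len(delta)):
        v = delta[t]
        if np.isnan(v) or v < thr:
            continue
        lo, hi = max(0, t - window), min(len(delta), t + window + 1)
        neigh = np.concatenate([delta[lo:t], delta[t + 1 : hi]])
        neigh = neigh[~np.isnan(neigh)]
        if len(neigh) and np.all(v > neigh):
            out.append(t)
    return np.array(out, dtype=int)


def merge_intervals(rapid_frames: np.ndarray, halo: int) -> list[tuple[int, int]]:
    """Inclusive ``[t0, t1]`` ranges covering ``+/- halo`` around each rapid
    frame, merged where they touch or overlap."""
    if len(rapid_frames) == 0:
        return []
    spans = [(int(t) - halo, int(t) + halo) for t in sorted(rapid_frames)]
    merged = [spans[0]]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged


def regime_of_frame(t: int, intervals: list[tuple[int, int]], halo: int = 0) -> str:
    """``"rapid"`` iff ``t`` lies within ``halo`` of any interval, else
    ``"stable"``.  Interval bounds are inclusive."""
    for lo, hi in intervals:
        if lo - halo <= t <= hi + halo:
            return "rapid"
    return "stable"


@dataclass
class MotionProfile:
    """Displacement series, paired-cell counts and derived rapid intervals."""

    delta: np.ndarray
    n_pairs: np.ndarray
    lam: float
    window: int
    halo: int
    rapid_frames: np.ndarray = field(default=None)
    intervals: list[tuple[int, int]] = field(default=None)

    def __post_init__(self) -> None:
        if self.rapid_frames is None:
            self.rapid_frames = rapid_motion_frames(self.delta, self.lam, self.window)
        if self.intervals is None:
            self.intervals = merge_intervals(self.rapid_frames, self.halo)

    def regime(self, t: int) -> str:
        return regime_of_frame(t, self.intervals)


def motion_profile(
    dets_by_frame: dict[int, list[Detection]],
    n_frames: int | None = None,
    pair_cap: float | None = None,
    lam: float = 0.5,
    window: int = 5,
    halo: int = 10,
) -> MotionProfile:
    """Build the motion profile of a detection stream.

    ``delta[t]`` is the mean mutual-NN displacement between frames ``t`` and
    ``t+1`` (NaN when undefined); the last entry is always NaN.  The default
    ``pair_cap`` is four times the median detection radius.
    """
    if n_frames is None:
        n_frames = max(dets_by_frame) + 1 if dets_by_frame else 0
    if pair_cap is None:
        radii = [d.r for dets in dets_by_frame.values() for d in dets]
        pair_cap = 4.0 * float(np.median(radii)) if radii else 24.0
    delta = np.full(n_frames, np.nan)
    n_pairs = np.zeros(n_frames, dtype=int)
    for t in range(n_frames - 1):
        a = dets_by_frame.get(t, [])
        b = dets_by_frame.get(t + 1, [])
        if a and b:
            delta[t], n_pairs[t] = frame_displacement(a, b, pair_cap)
    return MotionProfile(delta=delta, n_pairs=n_pairs, lam=lam, window=window, halo=halo)
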