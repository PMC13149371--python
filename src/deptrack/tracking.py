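"""Motion-aware adaptive-ROI trajectory reconstruction.

One track is opened per first-frame detection (later entrants are ignored
by design: identities are fixed at t0).  Frame-to-frame association is
nearest-neighbour within a regime-dependent search radius: during rapid
DEP-induced motion intervals the ROI and displacement gates widen and the
circle-IoU acceptance threshold relaxes; during stable intervals gates
tighten to limit identity ambiguity.  Association failures trigger a
multi-frame candidate search (up to ``max_gap`` subsequent frames) and the
bridged gap is filled by linear interpolation.  Post-hoc validation flags
tracks that are temporally incomplete or leave the FoV mask, and re-checks
identities of track pairs that overlap for several consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from deptrack.detection import Detection
from deptrack.fovmask import FoVMask, contains_many
from deptrack.motion import regime_of_frame

__all__ = [
    "TrackerConfig",
    "Track",
    "TrackState",
    "circle_iou",
    "associate",
    "recover_gap",
    "interpolate_gap",
    "track_sequence",
    "out_of_range_filter",
    "overlap_identity_check",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Association gates per motion regime.

    Radii and displacement gates are expressed as multiples of the track's
    current radius when ``gates_in_radii`` is True (the default), otherwise
    in pixels.  Rapid-regime gates must be at least as permissive as stable
    ones.
    """

    roi_stable: float = 3.0
    roi_rapid: float = 6.0
    dist_stable: float = 3.0
    dist_rapid: float = 6.0
    iou_stable: float = 0.2
    iou_rapid: float = 0.05
    max_gap: int = 10
    first_frame_only: bool = True
    gates_in_radii: bool = True
    best_feasible: bool = False  # if True, pick nearest candidate passing all gates

    def __post_init__(self) -> None:
        if self.roi_rapid < self.roi_stable:
            raise ValueError("roi_rapid must be >= roi_stable")
        if self.iou_rapid > self.iou_stable:
            raise ValueError("iou_rapid must be <= iou_stable")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")

    def gates(self, regime: str, r: float) -> tuple[float, float, float]:
        """(roi_radius, dist_gate, iou_threshold) for a track of radius r."""
        scale = r if self.gates_in_radii else 1.0
        if regime == "rapid":
            return self.roi_rapid * scale, self.dist_rapid * scale, self.iou_rapid
        return self.roi_stable * scale, self.dist_stable * scale, self.iou_stable


@dataclass(frozen=True)
class TrackState:
    x: float
    y: float
    r: float
    source: str  # "detected" | "interpolated"


@dataclass
class Track:
    """One cell identity with contiguous per-frame states from frame 0."""

    cell_id: int
    states: list[TrackState] = field(default_factory=list)
    status: str = "active"  # active | out_of_range | merged

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def last_frame(self) -> int:
        return len(self.states) - 1

    @property
    def last(self) -> TrackState:
        return self.states[-1]

    def positions(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.states], dtype=float)

    def sources(self) -> list[str]:
        return [s.source for s in self.states]

    def last_detected_frame(self) -> int:
        for t in range(len(self.states) - 1, -1, -1):
            if self.states[t].source == "detected":
                return t
        return -1


# ---- geometry -------------------------------------------------------------


def _lens_area(d: np.ndarray, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Intersection area of two discs at centre distance d (vectorized)."""
    d = np.asarray(d, dtype=float)
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), d.shape).copy()
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), d.shape).copy()
    area = np.zeros_like(d)
    disjoint = d >= r1 + r2
    rmin = np.minimum(r1, r2)
    contained = d <= np.abs(r1 - r2)
    area[contained] = np.pi * rmin[contained] ** 2
    mid = ~disjoint & ~contained
    if np.any(mid):
        dm, a, b = d[mid], r1[mid], r2[mid]
        alpha = np.arccos(np.clip((dm**2 + a**2 - b**2) / (2 * dm * a), -1, 1))
        beta = np.arccos(np.clip((dm**2 + b**2 - a**2) / (2 * dm * b), -1, 1))
        kernel = (-dm + a + b) * (dm + a - b) * (dm - a + b) * (dm + a + b)
        area[mid] = a**2 * alpha + b**2 * beta - 0.5 * np.sqrt(np.maximum(kernel, 0))
    return area


def circle_iou(c1, c2) -> float:
    """Exact intersection-over-union of two discs ``(x, y, r)``."""
    x1, y1, r1 = c1
    x2, y2, r2 = c2
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    d = np.hypot(x2 - x1, y2 - y1)
    inter = float(_lens_area(np.array([d]), r1, r2)[0])
    union = np.pi * (r1**2 + r2**2) - inter
    return inter / union


# ---- association ----------------------------------------------------------


def associate(
    track: Track,
    dets_t1: list[Detection],
    regime: str,
    config: TrackerConfig,
    available: np.ndarray | None = None,
) -> int | None:
    """Pick the matching detection index for ``track`` in the next frame.

    The candidate is the detection minimizing Euclidean distance from the
    track's last centroid among those inside the regime ROI (ties break to
    the lower index); it is accepted only if its distance passes the
    displacement gate and its circle-IoU with the last state passes the
    regime threshold.  With ``config.best_feasible`` the nearest candidate
    satisfying *all* gates is chosen instead.  Returns None when no
    acceptable match exists (a gap).
    """
    if not dets_t1:
        return None
    last = track.last
    roi, dist_gate, tau = config.gates(regime, last.r)
    xy = np.array([[d.x, d.y] for d in dets_t1])
    dist = np.hypot(xy[:, 0] - last.x, xy[:, 1] - last.y)
    ok = dist <= roi
    if available is not None:
        ok &= available
    if not ok.any():
        return None
    order = np.nonzero(ok)[0][np.argsort(dist[ok], kind="stable")]
    candidates = order if config.best_feasible else order[:1]
    for j in candidates:
        d = dets_t1[j]
        if dist[j] <= dist_gate and circle_iou(
            (last.x, last.y, last.r), (d.x, d.y, d.r)
        ) >= tau:
            return int(j)
    return None


def recover_gap(
    track: Track,
    detections_by_frame: dict[int, list[Detection]],
    t_gap: int,
    config: TrackerConfig,
    used: dict[int, set[int]] | None = None,
    regime: str = "rapid",
) -> tuple[int, int] | None:
    """Multi-frame candidate search after a failed association at ``t_gap``.

    Scans frames ``t_gap+1 .. t_gap+max_gap``; the first frame holding any
    unclaimed detection inside the ROI centred on the last known centroid
    yields its nearest such detection (ties to the lower index).  Returns
    ``(frame, detection_index)`` or None.  The relaxed (rapid) ROI is used
    by default since a gap already signals association trouble.
    """
    last = track.last
    roi, _, _ = config.gates(regime, last.r)
    for t in range(t_gap + 1, t_gap + config.max_gap + 1):
        dets = detections_by_frame.get(t, [])
        if not dets:
            continue
        xy = np.array([[d.x, d.y] for d in dets])
        dist = np.hypot(xy[:, 0] - last.x, xy[:, 1] - last.y)
        ok = dist <= roi
        if used is not None and t in used:
            claimed = np.zeros(len(dets), dtype=bool)
            claimed[list(used[t])] = True
            ok &= ~claimed
        if ok.any():
            j = int(np.nonzero(ok)[0][np.argmin(dist[ok])])
            return t, j
    return None


def interpolate_gap(
    start_state: TrackState, end_state: TrackState, t_start: int, t_end: int
) -> list[TrackState]:
    """States for frames ``t_start+1 .. t_end-1``, linear in x, y and r."""
    n = t_end - t_start
    out = []
    for k in range(1, n):
        frac = k / n
        out.append(
            TrackState(
                x=start_state.x + frac * (end_state.x - start_state.x),
                y=start_state.y + frac * (end_state.y - start_state.y),
                r=start_state.r + frac * (end_state.r - start_state.r),
                source="interpolated",
            )
        )
    return out


# ---- sequence tracking ----------------------------------------------------


def track_sequence(
    detections_by_frame: dict[int, list[Detection]],
    rapid_intervals: list[tuple[int, int]],
    mask: FoVMask | None,
    config: TrackerConfig = TrackerConfig(),
    n_frames: int | None = None,
) -> tuple[list[Track], list[dict]]:
    """Reconstruct one track per first-frame detection.

    Per frame, tracks are processed in ascending id; a detection claimed by
    one track is unavailable to later ones (conflicts are logged).  On
    association failure the multi-frame recovery scan runs and recovered
    gaps are filled by interpolation; otherwise the track terminates at its
    last known state.  Returns ``(tracks, conflict_log)``.
    """
    if n_frames is None:
        n_frames = max(detections_by_frame) + 1 if detections_by_frame else 0
    first = detections_by_frame.get(0, [])
    if mask is not None and first:
        pts = np.array([[d.x, d.y] for d in first])
        first = [d for d, k in zip(first, contains_many(mask, pts)) if k]
    if not first:
        raise ValueError("no detections in the first frame")
    tracks = [
        Track(cell_id=i, states=[TrackState(d.x, d.y, d.r, "detected")])
        for i, d in enumerate(first)
    ]
    used: dict[int, set[int]] = {}
    next_frame = {tr.cell_id: 1 for tr in tracks}
    active = {tr.cell_id: True for tr in tracks}
    conflicts: list[dict] = []

    for t in range(1, n_frames):
        dets = detections_by_frame.get(t, [])
        claimed = used.setdefault(t, set())
        for tr in tracks:
            q = tr.cell_id
            if not active[q] or next_frame[q] != t:
                continue
            regime = regime_of_frame(t, rapid_intervals)
            avail = None
            if dets:
                avail = np.ones(len(dets), dtype=bool)
                if claimed:
                    avail[list(claimed)] = False
            j = associate(tr, dets, regime, config, available=avail)
            if j is None and dets and claimed:
                # log when the unrestricted choice was already claimed
                j_any = associate(tr, dets, regime, config)
                if j_any is not None:
                    conflicts.append({"frame": t, "track": q, "detection": j_any})
            if j is not None:
                d = dets[j]
                tr.states.append(TrackState(d.x, d.y, d.r, "detected"))
                claimed.add(j)
                next_frame[q] = t + 1
                continue
            found = recover_gap(tr, detections_by_frame, t, config, used=used)
            if found is None:
                active[q] = False
                continue
            tf, jf = found
            d = detections_by_frame[tf][jf]
            end_state = TrackState(d.x, d.y, d.r, "detected")
            tr.states.extend(
                interpolate_gap(tr.last, end_state, t - 1, tf)
            )
            tr.states.append(end_state)
            used.setdefault(tf, set()).add(jf)
            next_frame[q] = tf + 1
    return tracks, conflicts


def out_of_range_filter(
    tracks: list[Track], total_frames: int, mask: FoVMask | None
) -> tuple[list[Track], list[Track]]:
    """Partition tracks into (valid, out_of_range).

    A track is out-of-range when it is shorter than the full sequence or any
    of its centroids leaves the FoV mask; such tracks are excluded from
    crossover-frequency analysis.
    """
    valid, out = [], []
    for tr in tracks:
        in_mask = (
            bool(contains_many(mask, tr.positions()).all()) if mask is not None else True
        )
        if tr.length >= total_frames and in_mask:
            valid.append(tr)
        else:
            tr.status = "out_of_range"
            out.append(tr)
    return valid, out


def overlap_identity_check(
    tracks: list[Track],
    tau_overlap: float = 0.5,
    min_consecutive: int = 3,
) -> list[dict]:
    """Re-evaluate identities of track pairs in prolonged spatial overlap.

    For every pair whose circle-IoU exceeds ``tau_overlap`` on at least
    ``min_consecutive`` consecutive frames, the two possible identity
    assignments of the post-event tails are compared by the displacement
    across the event boundary; if swapping the tails reduces it, the swap is
    applied in place.  Pairs that remain overlapped to the end of both
    tracks cannot be disambiguated and are flagged merged.  Returns the
    event report.
    """
    events: list[dict] = []
    pos = {tr.cell_id: tr.positions() for tr in tracks}
    for a_i in range(len(tracks)):
        for b_i in range(a_i + 1, len(tracks)):
            ta, tb = tracks[a_i], tracks[b_i]
            n = min(ta.length, tb.length)
            if n < min_consecutive:
                continue
            pa, pb = pos[ta.cell_id][:n], pos[tb.cell_id][:n]
            d = np.hypot(*(pa - pb).T)
            ra = np.array([s.r for s in ta.states[:n]])
            rb = np.array([s.r for s in tb.states[:n]])
            inter = _lens_area(d, ra, rb)
            iou = inter / (np.pi * (ra**2 + rb**2) - inter)
            over = iou > tau_overlap
            if not over.any():
                continue
            # scan runs of consecutive overlap
            t0 = None
            for t in range(n + 1):
                if t < n and over[t]:
                    if t0 is None:
                        t0 = t
                    continue
                if t0 is not None and t - t0 >= min_consecutive:
                    e = t - 1  # last overlapping frame
                    if e + 1 >= ta.length or e + 1 >= tb.length:
                        ta.status = tb.status = "merged"
                        events.append(
                            {"kind": "merged", "tracks": (ta.cell_id, tb.cell_id),
                             "start": t0, "end": e}
                        )
                    else:
                        a_e, b_e = pa[e], pb[e]
                        a_n = np.array([ta.states[e + 1].x, ta.states[e + 1].y])
                        b_n = np.array([tb.states[e + 1].x, tb.states[e + 1].y])
                        keep = np.hypot(*(a_n - a_e)) + np.hypot(*(b_n - b_e))
                        swap = np.hypot(*(b_n - a_e)) + np.hypot(*(a_n - b_e))
                        if swap < keep:
                            tail_a = ta.states[e + 1 :]
                            ta.states[e + 1 :] = tb.states[e + 1 :]
                            tb.states[e + 1 :] = tail_a
                            pos[ta.cell_id] = ta.positions()
                            pos[tb.cell_id] = tb.positions()
                            # overlap flags are swap-invariant; only the
                            # per-track coordinates need refreshing
                            pa = pos[ta.cell_id][:n]
                            pb = pos[tb.cell_id][:n]
                            events.append(
                                {"kind": "swapped", "tracks": (ta.cell_id, tb.cell_id),
                                 "start": t0, "end": e,
                                 "cost_before": float(keep), "cost_after": float(swap)}
                            )
                t0 = None
    return events
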