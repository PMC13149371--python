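"""Tracking evaluation: MOTA and trajectory retention.

MOTA = 1 - (FN + FP + IDsw) / sum_t G_t, accumulated per frame over
one-to-one centroid matches between predicted and ground-truth states.
Ground-truth cells outside the FoV mask are excluded from G_t (and from
misses), mirroring the FoV-exit exclusion used when annotating real chips.
Identity switches follow the CLEAR-MOT convention: one switch per
ground-truth identity whenever its assigned track id changes between
consecutive matched frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from deptrack.fovmask import FoVMask, contains_many
from deptrack.simulate import GroundTruthTrack
from deptrack.tracking import Track

__all__ = ["MotaResult", "RetentionCurve", "mota", "retention_curve"]


@dataclass(frozen=True)
class MotaResult:
    fn: int
    fp: int
    id_switches: int
    gt_total: int
    mota: float  # may be negative

    @property
    def mota_pct(self) -> float:
        return 100.0 * self.mota

    @classmethod
    def from_counts(cls, fn: int, fp: int, id_switches: int, gt_total: int) -> "MotaResult":
        return cls(fn, fp, id_switches, gt_total,
                   1.0 - (fn + fp + id_switches) / gt_total)


@dataclass
class RetentionCurve:
    """Fraction of initial tracks still successfully maintained per frame."""

    fraction: np.ndarray

    @property
    def final_pct(self) -> float:
        return 100.0 * float(self.fraction[-1])


def _greedy_match(
    gt_xy: np.ndarray, pred_xy: np.ndarray, tol: np.ndarray
) -> list[tuple[int, int]]:
    """One-to-one matches (gt_idx, pred_idx) by ascending distance, with a
    per-ground-truth distance tolerance."""
    if len(gt_xy) == 0 or len(pred_xy) == 0:
        return []
    dist = np.hypot(
        gt_xy[:, 0:1] - pred_xy[None, :, 0], gt_xy[:, 1:2] - pred_xy[None, :, 1]
    )
    gi, pi = np.nonzero(dist <= tol[:, None])
    order = np.argsort(dist[gi, pi], kind="stable")
    used_g, used_p, matches = set(), set(), []
    for k in order:
        g, p = int(gi[k]), int(pi[k])
        if g in used_g or p in used_p:
            continue
        used_g.add(g)
        used_p.add(p)
        matches.append((g, p))
    return matches


def mota(
    gt_tracks: list[GroundTruthTrack],
    pred_tracks: list[Track],
    match_tol: float | None = None,
    mask: FoVMask | None = None,
) -> MotaResult:
    """Multiple Object Tracking Accuracy over the shared frame axis.

    ``match_tol`` defaults to each ground-truth cell's radius (scale-aware).
    Raises ``ValueError`` on empty ground truth.
    """
    if not gt_tracks:
        raise ValueError("empty ground truth")
    n_frames = gt_tracks[0].n_frames
    gt_pos = np.stack([tr.states for tr in gt_tracks], axis=1)  # (T, n_gt, 2)
    gt_r = np.array(
        [tr.r_cell if match_tol is None else match_tol for tr in gt_tracks]
    )
    if mask is not None:
        in_mask = np.stack(
            [contains_many(mask, tr.states) for tr in gt_tracks], axis=1
        )  # (T, n_gt)
    else:
        in_mask = np.ones((n_frames, len(gt_tracks)), dtype=bool)

    fn = fp = idsw = gt_total = 0
    last_match: dict[int, int] = {}
    for t in range(n_frames):
        valid_g = np.nonzero(in_mask[t])[0]
        g_xy = gt_pos[t, valid_g]
        pred_idx = [i for i, tr in enumerate(pred_tracks) if tr.length > t]
        p_xy = np.array(
            [[pred_tracks[i].states[t].x, pred_tracks[i].states[t].y] for i in pred_idx]
        ).reshape(-1, 2)
        matches = _greedy_match(g_xy, p_xy, gt_r[valid_g])
        gt_total += len(valid_g)
        fn += len(valid_g) - len(matches)
        fp += len(p_xy) - len(matches)
        for g_local, p_local in matches:
            g = int(valid_g[g_local])
            track_id = pred_tracks[pred_idx[p_local]].cell_id
            if g in last_match and last_match[g] != track_id:
                idsw += 1
            last_match[g] = track_id
    if gt_total == 0:
        raise ValueError("no in-mask ground-truth states")
    return MotaResult.from_counts(fn, fp, idsw, gt_total)


def retention_curve(tracks: list[Track], total_frames: int) -> RetentionCurve:
    """Fraction of initial tracks whose last successfully associated
    (detected, not interpolated) frame is at least ``t``, for each frame."""
    if not tracks:
        raise ValueError("no tracks")
    last = np.array([tr.last_detected_frame() for tr in tracks])
    t = np.arange(total_frames)
    frac = (last[None, :] >= t[:, None]).mean(axis=1)
    return RetentionCurve(fraction=frac)
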