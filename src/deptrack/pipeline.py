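"""End-to-end pipeline: simulate -> mask -> detect -> events -> track ->
validate -> evaluate (-> f_co on full-protocol runs).

``run_pipeline`` drives every stage from one config mapping, writes each
stage's artifact under ``out_dir`` and is deterministic given config + seed.
A stage failure raises with the stage name; artifacts written so far are
left in place.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from deptrack import io
from deptrack.detection import blob_detect, detections_from_dataframe
from deptrack.evaluate import mota, retention_curve
from deptrack.experiments import (
    ExperimentConfig,
    benchmark_detections,
    intensity_estimates,
    make_experiment,
    tracking_schedule,
    velocity_estimates,
)
from deptrack.fco import population_summary
from deptrack.fovmask import make_fov_mask
from deptrack.motion import motion_profile
from deptrack.simulate import render_frame
from deptrack.tracking import (
    TrackerConfig,
    out_of_range_filter,
    overlap_identity_check,
    track_sequence,
)

log = logging.getLogger("deptrack.pipeline")

DEFAULT_CONFIG: dict = {
    "experiment": {
        "kind": "tracking",  # "tracking" (short benchmark) or "protocol" (full f_co run)
        "n_cells": 30,
        "p_miss": 0.0,
        "p_fp": 0.0,
        "pos_sigma": 0.0,
    },
    "detector": "stream",  # "stream" (corrupted ground truth) or "blob"
    "motion": {"lam": 0.5, "window": 5, "halo": 10},
    "tracker": {},
    "fco": True,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run_pipeline(config: dict | None, seed: int, out_dir: str | Path) -> dict:
    """Execute the configured pipeline; returns a summary dict.

    Artifacts: ``ground_truth.csv``, ``mask.png``, ``detections.csv``,
    ``events.json``, ``tracks.csv``, ``summary.json`` (plus
    ``fco_estimates.csv`` for full-protocol runs).
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "config": cfg}

    stage = "simulate"
    try:
        exp_cfg = cfg["experiment"]
        kind = exp_cfg.get("kind", "tracking")
        schedule = tracking_schedule() if kind == "tracking" else None
        exp = make_experiment(
            ExperimentConfig(n_cells=int(exp_cfg.get("n_cells", 30)), seed=seed),
            schedule=schedule,
        )
        gt_tracks = exp.run()
        n_frames = gt_tracks[0].n_frames
        io.write_ground_truth(out_dir / "ground_truth.csv", gt_tracks)

        stage = "mask"
        frame0 = render_frame(exp.layout, gt_tracks, 0, seed=seed)
        mask = make_fov_mask(frame0)
        import imageio.v3 as iio

        iio.imwrite(out_dir / "mask.png", (mask.mask * np.uint8(255)))

        stage = "detect"
        if cfg["detector"] == "blob":
            rows = []
            for t in range(n_frames):
                frame = render_frame(exp.layout, gt_tracks, t, seed=seed)
                for d in blob_detect(frame, mask, frame_index=t):
                    rows.append((t, d.x, d.y, d.w, d.h, d.score))
            import pandas as pd

            df = pd.DataFrame(rows, columns=io.DETECTION_COLUMNS)
        else:
            df = benchmark_detections(
                exp,
                p_miss=float(exp_cfg.get("p_miss", 0.0)),
                p_fp=float(exp_cfg.get("p_fp", 0.0)),
                pos_sigma=float(exp_cfg.get("pos_sigma", 0.0)),
            )
        io.write_detections(out_dir / "detections.csv", df)
        dets = detections_from_dataframe(df)

        stage = "events"
        m = cfg["motion"]
        prof = motion_profile(
            dets, n_frames=n_frames, lam=m["lam"], window=m["window"], halo=m["halo"]
        )
        (out_dir / "events.json").write_text(
            json.dumps(
                {
                    "delta": [None if np.isnan(x) else float(x) for x in prof.delta],
                    "rapid_frames": prof.rapid_frames.tolist(),
                    "intervals": prof.intervals,
                },
                indent=1,
            )
        )

        stage = "track"
        tracker_cfg = TrackerConfig(**cfg["tracker"])
        ptracks, conflicts = track_sequence(
            dets, prof.intervals, mask, tracker_cfg, n_frames=n_frames
        )
        events = overlap_identity_check(ptracks)
        valid, out_of_range = out_of_range_filter(ptracks, n_frames, mask)
        io.write_tracks(out_dir / "tracks.csv", ptracks)
        summary["tracking"] = {
            "first_frame_detections": len(ptracks),
            "valid_tracks": len(valid),
            "out_of_range_tracks": len(out_of_range),
            "conflicts": len(conflicts),
            "identity_events": len(events),
        }

        stage = "evaluate"
        res = mota(gt_tracks, ptracks, mask=mask)
        ret = retention_curve(ptracks, n_frames)
        summary["evaluation"] = {
            "mota": res.mota,
            "mota_pct": res.mota_pct,
            "fn": res.fn,
            "fp": res.fp,
            "id_switches": res.id_switches,
            "gt_total": res.gt_total,
            "retention_final_pct": ret.final_pct,
        }

        if kind == "protocol" and cfg.get("fco", True):
            stage = "fco"
            vel = velocity_estimates(gt_tracks, exp.field, exp.schedule)
            inten = intensity_estimates(
                exp.layout, gt_tracks, exp.schedule, seed=seed
            )
            import pandas as pd

            pd.DataFrame(
                [
                    (e.cell_id, e.method, e.fco, e.valid)
                    for e in vel + inten
                ],
                columns=["cell_id", "method", "fco_hz", "valid"],
            ).to_csv(out_dir / "fco_estimates.csv", index=False)
            summary["fco"] = population_summary(vel + inten)
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, err) from err

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
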