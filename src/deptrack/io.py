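"""Standard file formats: frame sequences, detection / track / truth CSVs."""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from deptrack.simulate import GroundTruthTrack
from deptrack.tracking import Track, TrackState

__all__ = [
    "read_frames",
    "write_frames",
    "write_detections",
    "read_detections",
    "write_tracks",
    "read_tracks",
    "write_ground_truth",
    "read_ground_truth",
]

DETECTION_COLUMNS = ["frame", "x", "y", "w", "h", "score"]
TRACK_COLUMNS = ["track_id", "frame", "x", "y", "r", "source", "in_fov"]
TRUTH_COLUMNS = ["cell_id", "frame", "x", "y", "r", "fco_true"]

_NUM = re.compile(r"(\d+)")


def _to_uint8(img: np.ndarray, origin: str) -> np.ndarray:
    if img.dtype == np.uint8:
        return img
    if img.dtype == np.uint16:
        warnings.warn(f"{origin}: rescaling 16-bit frame to 8-bit")
        return (img / 257.0).round().astype(np.uint8)
    raise ValueError(f"{origin}: unsupported dtype {img.dtype}")


def read_frames(path: str | Path) -> np.ndarray:
    """Load a frame sequence as a (T, rows, cols) uint8 array.

    Accepts a multi-page TIFF file or a directory of numbered PNG/TIFF
    files (ordered by the number embedded in each filename).  Raises on
    mixed frame shapes or gaps in the numbering.
    """
    path = Path(path)
    if path.is_file():
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        return np.stack([_to_uint8(f, str(path)) for f in stack])
    if not path.is_dir():
        raise FileNotFoundError(path)
    files = sorted(
        [p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")],
    )
    numbered = []
    for p in files:
        m = _NUM.findall(p.stem)
        if not m:
            raise ValueError(f"cannot order frame file {p.name}: no numeric index")
        numbered.append((int(m[-1]), p))
    numbered.sort()
    indices = [i for i, _ in numbered]
    if not indices:
        raise ValueError(f"no frames found in {path}")
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise ValueError(f"missing frame indices: {missing}")
    frames = []
    shape = None
    for i, p in numbered:
        img = _to_uint8(np.asarray(iio.imread(p)), p.name)
        if img.ndim == 3:
            img = img[..., 0]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"mixed frame shapes: {shape} vs {img.shape} ({p.name})")
        frames.append(img)
    return np.stack(frames)


def write_frames(path: str | Path, frames: np.ndarray, fmt: str = "png") -> None:
    """Write frames as numbered 8-bit grayscale files into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(frames))))
    for i, f in enumerate(frames):
        iio.imwrite(path / f"frame_{i:0{width}d}.{fmt}", np.asarray(f, dtype=np.uint8))


def write_detections(path: str | Path, df: pd.DataFrame) -> None:
    df[DETECTION_COLUMNS].to_csv(path, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    if "score" not in df.columns:
        df["score"] = 1.0
    return df


def write_tracks(path: str | Path, tracks: list[Track], in_fov=None) -> None:
    rows = []
    for tr in tracks:
        for t, s in enumerate(tr.states):
            fov = True if in_fov is None else bool(in_fov(tr, t))
            rows.append((tr.cell_id, t, s.x, s.y, s.r, s.source, fov))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False, float_format="%.4f")


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        states = [
            TrackState(r.x, r.y, r.r, r.source) for r in grp.itertuples(index=False)
        ]
        tracks.append(Track(cell_id=int(tid), states=states))
    return tracks


def write_ground_truth(path: str | Path, tracks: list[GroundTruthTrack]) -> None:
    rows = []
    for tr in tracks:
        for t, (x, y) in enumerate(tr.states):
            rows.append((tr.cell_id, t, x, y, tr.r_cell, tr.fco_true))
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False, float_format="%.4f")


def read_ground_truth(path: str | Path) -> list[GroundTruthTrack]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            GroundTruthTrack(
                cell_id=int(cid),
                fco_true=float(grp.fco_true.iloc[0]),
                r_cell=float(grp.r.iloc[0]),
                states=grp[["x", "y"]].to_numpy(),
            )
        )
    return out
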