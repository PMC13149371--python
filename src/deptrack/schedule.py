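"""Frequency-modulation schedules.

A DEP experiment applies a piecewise protocol of static holds and linear
frequency sweeps.  The default three-step protocol alternates trap holds at
1 kHz (nDEP trap) and 41 kHz (pDEP trap) with +/-800 Hz/s sweeps between
1 and 41 kHz and a ladder of static test frequencies used for velocity-based
crossover-frequency measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Segment", "FrequencySchedule", "freq_at", "default_protocol"]


@dataclass(frozen=True)
class Segment:
    """One schedule segment over the half-open time interval [t_start, t_end).

    ``kind`` is ``"static"`` (constant ``f_start``) or ``"sweep"`` (linear ramp
    from ``f_start`` at ``t_start`` to ``f_end`` at ``t_end``).  ``role`` is a
    free label used by downstream analysis ("trap", "test", "sweep").
    """

    t_start: float
    t_end: float
    kind: str
    f_start: float
    f_end: float
    role: str = ""
    step: int = 0

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")
        if self.kind not in ("static", "sweep"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "static" and self.f_start != self.f_end:
            raise ValueError("static segment must have f_start == f_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def sweep_rate(self) -> float:
        """Frequency ramp rate in Hz/s (zero for static segments)."""
        return (self.f_end - self.f_start) / self.duration


@dataclass
class FrequencySchedule:
    """Ordered, contiguous, non-overlapping segments plus the acquisition rate."""

    segments: list[Segment]
    fps: float = 10.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise ValueError("segments must be contiguous and ordered")

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_frames(self) -> int:
        """Number of frames acquired over the schedule span at ``fps``."""
        return int(round(self.duration * self.fps))

    def frame_time(self, frame: int | np.ndarray) -> float | np.ndarray:
        return self.t_start + np.asarray(frame) / self.fps

    def segment_frames(self, seg: Segment) -> np.ndarray:
        """Frame indices whose timestamps fall inside ``seg`` (half-open)."""
        first = int(np.ceil((seg.t_start - self.t_start) * self.fps - 1e-9))
        last = int(np.ceil((seg.t_end - self.t_start) * self.fps - 1e-9))
        return np.arange(max(first, 0), min(last, self.n_frames))

    def segment_at(self, t: float) -> Segment:
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg
        if np.isclose(t, self.t_end):
            return self.segments[-1]
        raise ValueError(f"t={t} outside schedule span [{self.t_start}, {self.t_end}]")

    def freq_at(self, t):
        return freq_at(self, t)

    def sweeps(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "sweep"]

    def tests(self) -> list[Segment]:
        return [s for s in self.segments if s.role == "test"]


def freq_at(schedule: FrequencySchedule, t) -> float | np.ndarray:
    """Applied frequency (Hz) at time ``t`` (s).

    Static segments return their hold frequency; sweeps interpolate linearly.
    Segment boundaries belong to the later segment (half-open convention); the
    final instant of the schedule returns the last segment's end frequency.
    Raises ``ValueError`` outside the schedule span.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < schedule.t_start - 1e-9) or np.any(t_arr > schedule.t_end + 1e-9):
        raise ValueError("t outside schedule span")
    out = np.empty_like(t_arr)
    filled = np.zeros(t_arr.shape, dtype=bool)
    for seg in schedule.segments:
        sel = (~filled) & (t_arr >= seg.t_start) & (t_arr < seg.t_end)
        if seg.kind == "static":
            out[sel] = seg.f_start
        else:
            frac = (t_arr[sel] - seg.t_start) / seg.duration
            out[sel] = seg.f_start + frac * (seg.f_end - seg.f_start)
        filled |= sel
    # final instant
    last = schedule.segments[-1]
    sel = ~filled
    out[sel] = last.f_end
    return out if np.ndim(t) else float(out[0])


#: Static test frequencies (Hz) of the default protocol's second step, in the
#: order they are applied.  Each test is preceded by a trap hold at the
#: opposite polarity (1 kHz before high-frequency tests, 41 kHz before
#: low-frequency tests) so that every test segment starts from a known locus.
STEP2_TEST_FREQS_HZ = (
    20_000.0,
    1_000.0,
    30_000.0,
    1_500.0,
    40_000.0,
    2_000.0,
    50_000.0,
    2_500.0,
    60_000.0,
    3_000.0,
    70_000.0,
    3_500.0,
)

NDEP_TRAP_HZ = 1_000.0
PDEP_TRAP_HZ = 41_000.0
SWEEP_RATE_HZ_PER_S = 800.0


def default_protocol(
    fps: float = 10.0,
    trap_hold_s: float = 25.0,
    test_hold_s: float = 60.0,
    sweep_lo_hz: float = NDEP_TRAP_HZ,
    sweep_hi_hz: float = PDEP_TRAP_HZ,
    sweep_rate_hz_s: float = SWEEP_RATE_HZ_PER_S,
    test_freqs_hz: tuple[float, ...] = STEP2_TEST_FREQS_HZ,
) -> FrequencySchedule:
    """Build the default three-step stimulation protocol.

    Step 1: nDEP trap hold, +800 Hz/s sweep 1->41 kHz, pDEP trap hold,
    -800 Hz/s sweep 41->1 kHz.  Step 2: twelve trap/test pairs alternating
    1-kHz and 41-kHz traps with the static test-frequency ladder.  Step 3
    repeats step 1.  With the defaults the schedule spans 1,320 s, i.e.
    13,200 frames at 10 frames/s.
    """
    sweep_s = (sweep_hi_hz - sweep_lo_hz) / sweep_rate_hz_s
    segs: list[Segment] = []
    t = 0.0

    def add(kind: str, dur: float, f0: float, f1: float, role: str, step: int) -> None:
        nonlocal t
        segs.append(Segment(t, t + dur, kind, f0, f1, role=role, step=step))
        t += dur

    def sweep_block(step: int) -> None:
        add("static", trap_hold_s, sweep_lo_hz, sweep_lo_hz, "trap", step)
        add("sweep", sweep_s, sweep_lo_hz, sweep_hi_hz, "sweep", step)
        add("static", trap_hold_s, sweep_hi_hz, sweep_hi_hz, "trap", step)
        add("sweep", sweep_s, sweep_hi_hz, sweep_lo_hz, "sweep", step)

    sweep_block(step=1)
    for i, f_test in enumerate(test_freqs_hz):
        trap = NDEP_TRAP_HZ if i % 2 == 0 else PDEP_TRAP_HZ
        add("static", trap_hold_s, trap, trap, "trap", 2)
        add("static", test_hold_s, f_test, f_test, "test", 2)
    sweep_block(step=3)
    return FrequencySchedule(segs, fps=fps)
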