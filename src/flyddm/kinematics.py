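"""Extraction of decision events from position trajectories.

Flies walk in a 50 mm linear chamber imaged at 30 frames/s.  A 7 mm wide
central decision zone is flanked on either side by off-center zones of the
same width.  A traverse of the decision zone counts as a decision when the
fly slows to at most 10% of its entry speed inside the zone and exits
within 15 s; the dwell time is the raw reaction time, which is then
normalized for walking speed by the fly's mean transit time across the
off-center zones.

Positions are smoothed with a 10-frame moving average before any zone
logic.  Zones are half-open intervals [lo, hi) on the chamber axis, with 0
at the left end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "ChamberGeometry",
    "Trajectory",
    "DecisionEvent",
    "QCResult",
    "smooth_positions",
    "qc_trajectory",
    "extract_decisions",
    "normalize_rt",
    "process_trajectory",
]


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber layout (mm) and acquisition frame rate (frames/s)."""

    length: float = 50.0
    decision_zone_width: float = 7.0
    frame_rate: float = 30.0

    def __post_init__(self):
        if not 0 < 3 * self.decision_zone_width <= self.length:
            raise ValidationError("decision and off-center zones must fit inside the chamber")

    @property
    def zone_lo(self) -> float:
        return (self.length - self.decision_zone_width) / 2.0

    @property
    def zone_hi(self) -> float:
        return (self.length + self.decision_zone_width) / 2.0

    @property
    def left_offcenter(self) -> tuple[float, float]:
        return (self.zone_lo - self.decision_zone_width, self.zone_lo)

    @property
    def right_offcenter(self) -> tuple[float, float]:
        return (self.zone_hi, self.zone_hi + self.decision_zone_width)

    @property
    def end_width(self) -> float:
        # the end regions used for counting end-to-center runs
        return self.decision_zone_width


@dataclass
class Trajectory:
    """A position time series for one fly at one difficulty/condition.

    ``low_conc_side`` names the arm carrying the lower odor concentration
    ('left' or 'right'); exiting the decision zone into it is a correct
    choice.
    """

    positions: np.ndarray
    fly_id: str = "fly0"
    low_conc_side: str = "right"
    difficulty: float = 0.0
    light: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.low_conc_side not in ("left", "right"):
            raise ValidationError(f"low_conc_side must be 'left' or 'right', got {self.low_conc_side!r}")


@dataclass
class DecisionEvent:
    """One traverse of the decision zone and its accept/reject status."""

    entry_frame: int
    exit_frame: int
    rt_raw: float
    choice: int  # +1 correct, -1 incorrect, 0 when no exit was observed
    valid: bool
    reason: str  # 'ok', 'timeout', 'no_slowdown', 'no_exit', 'no_transit'
    rt_normalized: float | None = None


@dataclass
class QCResult:
    accepted: bool
    reason: str
    runs: int = 0


def smooth_positions(raw: Sequence[float], window: int = 10) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    Output length equals input length; a constant sequence is unchanged;
    ``window=1`` is the identity.
    """
    raw = np.asarray(raw, dtype=float)
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if raw.size < window:
        raise ValidationError(f"sequence of length {raw.size} shorter than window {window}")
    if window == 1:
        return raw.copy()
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    n = raw.size
    idx = np.arange(n)
    lo = np.maximum(idx - (window - 1) // 2, 0)
    hi = np.minimum(idx + window // 2 + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _zone_of(pos: np.ndarray, geometry: ChamberGeometry) -> np.ndarray:
    """-2 left end, -1 left corridor, 0 decision zone, +1 right corridor, +2 right end."""
    z = np.zeros(pos.shape, dtype=int)
    z[pos < geometry.zone_lo] = -1
    z[pos >= geometry.zone_hi] = 1
    z[pos < geometry.end_width] = -2
    z[pos >= geometry.length - geometry.end_width] = 2
    return z


def count_runs(positions: np.ndarray, geometry: ChamberGeometry) -> int:
    """Number of end-to-center runs: decision-zone entries for which an end
    region was visited since the previous zone exit."""
    z = _zone_of(np.asarray(positions, dtype=float), geometry)
    runs = 0
    seen_end = False
    in_zone = False
    for zi in z:
        if abs(zi) == 2:
            seen_end = True
        if zi == 0 and not in_zone:
            if seen_end:
                runs += 1
                seen_end = False
            in_zone = True
        elif zi != 0:
            in_zone = False
    return runs


def qc_trajectory(traj: Trajectory, geometry: ChamberGeometry = ChamberGeometry(),
                  grooming: bool = False) -> QCResult:
    """Accept or reject a (smoothed) trajectory.

    Rejects videos flagged for excessive grooming (caller-supplied metadata)
    or with fewer than 2 end-to-center runs.
    """
    if grooming:
        return QCResult(accepted=False, reason="grooming", runs=0)
    runs = count_runs(traj.positions, geometry)
    if runs < 2:
        return QCResult(accepted=False, reason=f"<2 end-to-center runs ({runs})", runs=runs)
    return QCResult(accepted=True, reason="ok", runs=runs)


#: frames over which entry and in-zone speeds are averaged
SPEED_WINDOW = 5
#: required fractional reduction of the entry speed inside the zone
SLOWDOWN_FRACTION = 0.9
#: maximum dwell time in the decision zone (s)
MAX_DWELL_S = 15.0


def _speeds(pos: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame speed: |p[i] - p[i-1]| * fps, with s[0] = s[1]."""
    s = np.abs(np.diff(pos)) * fps
    return np.concatenate([[s[0] if s.size else 0.0], s])


def extract_decisions(traj: Trajectory, geometry: ChamberGeometry = ChamberGeometry()) -> list[DecisionEvent]:
    """Find decision-zone traverses and apply the decision criteria.

    For every maximal in-zone interval the event records the dwell time
    (raw reaction time), the choice sign (+1 when the exit arm carries the
    lower odor concentration), and a validity flag with one reason:
    'timeout' when the dwell exceeds 15 s, 'no_slowdown' when the minimum
    5-frame average speed inside the zone stays above 10% of the 5-frame
    average entry speed, 'no_exit' when the recording ends inside the zone.
    """
    pos = np.asarray(traj.positions, dtype=float)
    fps = geometry.frame_rate
    in_zone = (pos >= geometry.zone_lo) & (pos < geometry.zone_hi)
    speeds = _speeds(pos, fps)
    events: list[DecisionEvent] = []

    i = 0
    n = pos.size
    while i < n:
        if not in_zone[i]:
            i += 1
            continue
        entry = i
        while i < n and in_zone[i]:
            i += 1
        exit_frame = i  # first frame outside, or n if the recording ended
        if exit_frame >= n:
            events.append(DecisionEvent(entry, exit_frame, (exit_frame - entry) / fps,
                                        0, False, "no_exit"))
            break
        dwell = (exit_frame - entry) / fps
        # mean speed over the SPEED_WINDOW frames preceding zone entry
        pre = speeds[max(entry - SPEED_WINDOW, 1):entry]
        entry_speed = float(np.mean(pre)) if pre.size else 0.0
        inside = speeds[entry + 1:exit_frame]
        if inside.size >= SPEED_WINDOW:
            kernel = np.ones(SPEED_WINDOW) / SPEED_WINDOW
            min_inside = float(np.min(np.convolve(inside, kernel, mode="valid")))
        elif inside.size:
            min_inside = float(np.mean(inside))
        else:
            min_inside = 0.0
        exit_side = "right" if pos[exit_frame] >= geometry.zone_hi else "left"
        choice = 1 if exit_side == traj.low_conc_side else -1
        if dwell > MAX_DWELL_S:
            events.append(DecisionEvent(entry, exit_frame, dwell, choice, False, "timeout"))
        elif entry_speed <= 0 or min_inside > (1.0 - SLOWDOWN_FRACTION) * entry_speed:
            events.append(DecisionEvent(entry, exit_frame, dwell, choice, False, "no_slowdown"))
        else:
            events.append(DecisionEvent(entry, exit_frame, dwell, choice, True, "ok"))
    return events


def offcenter_transits(traj: Trajectory, geometry: ChamberGeometry = ChamberGeometry()) -> list[float]:
    """Durations (s) of complete traverses of either off-center zone
    (entering through one boundary and leaving through the other)."""
    pos = np.asarray(traj.positions, dtype=float)
    fps = geometry.frame_rate
    transits: list[float] = []
    for lo, hi in (geometry.left_offcenter, geometry.right_offcenter):
        inside = (pos >= lo) & (pos < hi)
        i, n = 0, pos.size
        while i < n:
            if not inside[i]:
                i += 1
                continue
            start = i
            while i < n and inside[i]:
                i += 1
            if i >= n or start == 0:
                continue  # incomplete interval at a recording edge
            entered_from = "left" if pos[start - 1] < lo else "right"
            left_to = "left" if pos[i] < lo else "right"
            if entered_from != left_to:  # a full traverse, not a bounce-back
                transits.append((i - start) / fps)
    return transits


def normalize_rt(events: list[DecisionEvent], traj: Trajectory,
                 geometry: ChamberGeometry = ChamberGeometry()) -> list[DecisionEvent]:
    """Divide raw dwell times by the fly's mean off-center transit time.

    Events are returned as new objects with ``rt_normalized`` set; when no
    complete off-center transit exists, valid events are flagged
    'no_transit' and invalidated.
    """
    transits = offcenter_transits(traj, geometry)
    out = []
    for ev in events:
        if transits:
            out.append(replace(ev, rt_normalized=ev.rt_raw / float(np.mean(transits))))
        elif ev.valid:
            out.append(replace(ev, valid=False, reason="no_transit"))
        else:
            out.append(replace(ev))
    return out


def process_trajectory(traj: Trajectory, geometry: ChamberGeometry = ChamberGeometry(),
                       smooth_window: int = 10, grooming: bool = False
                       ) -> tuple[QCResult, list[DecisionEvent]]:
    """Full pipeline: smooth, quality-control, extract, speed-normalize."""
    smoothed = replace(traj, positions=smooth_positions(traj.positions, smooth_window))
    qc = qc_trajectory(smoothed, geometry, grooming=grooming)
    if not qc.accepted:
        return qc, []
    events = extract_decisions(smoothed, geometry)
    return qc, normalize_rt(events, smoothed, geometry)
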