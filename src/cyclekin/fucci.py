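"""Fucci reporter state classification and phase segmentation.

mKO2-hCdt1 marks G0/G1 (very high in quiescent cells), mAG-hGeminin marks
S/G2/M, and early G1 shows a transient double-negative (DN) gap between
mAG degradation at cytokinesis and mKO2 accumulation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FucciState",
    "FucciGate",
    "FluorescenceTrace",
    "PhaseInterval",
    "PhaseSegmentation",
    "InsufficientTraceError",
    "TraceAlignmentError",
    "classify_point",
    "classify_points",
    "segment_trace",
    "mko2_phase_duration",
]


class FucciState(str, enum.Enum):
    KO_HIGH = "KO_HIGH"      # mKO2++ mAG-  (quiescent G0)
    KO_POS = "KO_POS"        # mKO2+  mAG-  (G1)
    DOUBLE_POS = "DOUBLE_POS"
    AG_POS = "AG_POS"        # S/G2/M
    DN = "DN"                # early-G1 double-negative gap


class InsufficientTraceError(ValueError):
    pass


class TraceAlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class FucciGate:
    """Intensity thresholds (a.u.) and run smoothing for state calls.

    Thresholds are inclusive on positivity. Defaults assume the simulator's
    1000 a.u. cycling plateau (theta = 20% of plateau) and a distinct
    quiescent mKO2 plateau.
    """

    theta_ko: float = 200.0
    theta_ko_high: float = 2000.0
    theta_ag: float = 200.0
    min_dwell: float = 12.0

    def __post_init__(self) -> None:
        if not (0 < self.theta_ko < self.theta_ko_high):
            raise ValueError("require 0 < theta_ko < theta_ko_high")
        if self.theta_ag <= 0:
            raise ValueError("theta_ag must be positive")
        if self.min_dwell < 0:
            raise ValueError("min_dwell must be nonnegative")


@dataclass
class FluorescenceTrace:
    cell_id: str
    times: np.ndarray
    ko2: np.ndarray
    ag: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ko2 = np.asarray(self.ko2, dtype=float)
        self.ag = np.asarray(self.ag, dtype=float)
        if not (len(self.times) == len(self.ko2) == len(self.ag)):
            raise ValueError("channel lengths differ")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class PhaseInterval:
    start: float
    end: float
    state: FucciState

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class PhaseSegmentation:
    cell_id: str
    intervals: list[PhaseInterval]
    durations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.durations:
            d = {s: 0.0 for s in ("DN", "KO_POS", "KO_HIGH", "DOUBLE_POS", "AG_POS")}
            for iv in self.intervals:
                d[iv.state.value] += iv.length
            self.durations = d

    @property
    def d_DN(self) -> float:
        return self.durations["DN"]

    @property
    def d_KO(self) -> float:
        return self.durations["KO_POS"]

    @property
    def d_DP(self) -> float:
        return self.durations["DOUBLE_POS"]

    @property
    def d_AG(self) -> float:
        return self.durations["AG_POS"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"cell_id": self.cell_id, "start_min": iv.start,
                 "end_min": iv.end, "state": iv.state.value}
                for iv in self.intervals
            ]
        )


def classify_point(ko2: float, ag: float, gate: FucciGate = FucciGate()) -> FucciState:
    """Threshold a single (mKO2, mAG) sample into a Fucci state."""
    ag_pos = ag >= gate.theta_ag
    if ko2 >= gate.theta_ko:
        if ag_pos:
            return FucciState.DOUBLE_POS
        if ko2 >= gate.theta_ko_high:
            return FucciState.KO_HIGH
        return FucciState.KO_POS
    return FucciState.AG_POS if ag_pos else FucciState.DN


def classify_points(ko2: np.ndarray, ag: np.ndarray, gate: FucciGate) -> list[FucciState]:
    return [classify_point(float(k), float(a), gate) for k, a in zip(ko2, ag)]


def _runs(states: list[FucciState]) -> list[list]:
    """Run-length encode: [[state, n_frames], ...]."""
    runs: list[list] = []
    for s in states:
        if runs and runs[-1][0] is s:
            runs[-1][1] += 1
        else:
            runs.append([s, 1])
    return runs


def _smooth_runs(runs: list[list], min_frames: int) -> list[list]:
    """Merge runs shorter than min_frames into the longer flanking run.

    Repeatedly absorbs the shortest offending run (earliest on ties) into
    whichever neighbour is longer (earlier neighbour on ties) until every
    remaining run meets the dwell requirement or a single run is left.
    """
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        short = [(n, i) for i, (_, n) in enumerate(runs) if n < min_frames]
        if not short:
            break
        _, i = min(short)
        left = runs[i - 1][1] if i > 0 else -1
        right = runs[i + 1][1] if i < len(runs) - 1 else -1
        j = i - 1 if left >= right else i + 1
        runs[j][1] += runs[i][1]
        del runs[i]
        # re-merge identical neighbours created by the absorption
        k = 1
        while k < len(runs):
            if runs[k][0] is runs[k - 1][0]:
                runs[k - 1][1] += runs[k][1]
                del runs[k]
            else:
                k += 1
    return runs


def segment_trace(trace: FluorescenceTrace, gate: FucciGate = FucciGate()) -> PhaseSegmentation:
    """Label a fluorescence trace with Fucci-state intervals.

    Pointwise threshold calls are smoothed by a minimum-dwell rule, then
    converted to intervals whose boundaries sit on frame times; the
    intervals tile [times[0], times[-1]] exactly.
    """
    if len(trace.times) < 3:
        raise InsufficientTraceError(
            f"cell {trace.cell_id}: trace has {len(trace.times)} frames (< 3)"
        )
    states = classify_points(trace.ko2, trace.ag, gate)
    dt = float(np.median(np.diff(trace.times)))
    min_frames = max(1, int(round(gate.min_dwell / dt)))
    runs = _smooth_runs(_runs(states), min_frames)

    intervals = []
    idx = 0
    for state, n in runs:
        start = trace.times[idx]
        idx += n
        end = trace.times[idx] if idx < len(trace.times) else trace.times[-1]
        intervals.append(PhaseInterval(float(start), float(end), state))
    return PhaseSegmentation(cell_id=trace.cell_id, intervals=intervals)


def mko2_phase_duration(
    tree,
    traces: dict[str, FluorescenceTrace],
    gate: FucciGate = FucciGate(),
    *,
    alignment_tolerance_frames: float = 2.0,
) -> pd.DataFrame:
    """Per-cycle Fucci phase durations for every fully traced divided cell.

    Each trace must cover its cell's [birth_time, end_time] within the
    alignment tolerance; phase durations then sum to the cycle time up to
    boundary quantization.
    """
    from .lineage import Fate  # local import to avoid cycle

    rows = []
    for node in tree.nodes():
        if node.fate is not Fate.DIVIDED:
            continue
        trace = traces.get(node.cell_id)
        if trace is None:
            continue
        dt = float(np.median(np.diff(trace.times))) if len(trace.times) > 1 else 3.5
        tol = alignment_tolerance_frames * dt
        if abs(trace.times[0] - node.birth_time) > tol or abs(
            trace.times[-1] - node.end_time
        ) > tol:
            raise TraceAlignmentError(
                f"cell {node.cell_id}: trace [{trace.times[0]}, {trace.times[-1]}] "
                f"does not cover cycle [{node.birth_time}, {node.end_time}]"
            )
        seg = segment_trace(trace, gate)
        rows.append(
            {
                "cell_id": node.cell_id,
                "tree_id": tree.tree_id,
                "depth": node.depth,
                "cycle_time": node.cycle_time,
                "d_DN": seg.d_DN,
                "d_KO": seg.d_KO,
                "d_DP": seg.d_DP,
                "d_AG": seg.d_AG,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "tree_id", "depth", "cycle_time", "d_DN", "d_KO", "d_DP", "d_AG"],
    )
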