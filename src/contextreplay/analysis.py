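"""Replay-sequence scoring: events, direction, remote/shortcut flags, lag-CRP.

A replay *event* is the longest contiguous run of a replayed sequence that
matches consecutive ascending (forward) or descending (backward) positions of
one awake sequence, with length at or above the task's detection threshold
(five by default).  At most one event is scored per replay period.  Further
measures classify events as local/remote relative to a resting cue, flag
novel shortcut trajectories that cross between arms of a maze, and quantify
the contiguity of replay transitions by positional lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelState, retrieve_context
from .replay import ReplayTrace
from .tasks import TaskSpec

__all__ = [
    "ReplayEvent",
    "task_items_of",
    "detect_replay_event",
    "summarize_phase",
    "classify_remote",
    "detect_shortcut",
    "lag_crp",
    "sequence_match_proportion",
    "contains_contiguous",
    "nonlocal_preference",
    "compare_runs",
    "traces_to_frame",
]


@dataclass(frozen=True)
class ReplayEvent:
    """A detected contiguous replayed segment."""

    start: int  # offset into the (task-item) trace
    length: int
    sequence_id: int
    direction: str  # "forward" | "backward"


def task_items_of(trace: ReplayTrace, space_n_task: int) -> list[int]:
    """Strip non-task entries (the recorded terminal off-task item)."""
    return [i for i in trace.items if i < space_n_task]


def _labels_of(trace_items: Sequence[int], labels: Sequence[str]) -> list[str]:
    return [labels[i] for i in trace_items]


def detect_replay_event(
    trace: ReplayTrace, task: TaskSpec, min_len: Optional[int] = None
) -> Optional[ReplayEvent]:
    """Find the longest contiguous forward or backward segment of any task
    sequence within one trace; ties break to the earliest start, then to
    forward over backward.  Returns ``None`` when no run reaches the
    threshold.  Trailing non-task items are ignored.
    """
    if min_len is None:
        min_len = task.event_min_len
    space = task.item_space()
    items = _labels_of(task_items_of(trace, space.n_task), space.labels)
    if len(items) < min_len:
        return None
    best: Optional[ReplayEvent] = None
    for sid, seq in enumerate(task.match_sequences):
        pos = {lab: p for p, lab in enumerate(seq)}
        p = [pos.get(lab, -1) for lab in items]
        for direction, step in (("forward", 1), ("backward", -1)):
            run_start = 0
            k = 1
            for idx in range(1, len(p) + 1):
                ok = (
                    idx < len(p)
                    and p[idx] >= 0
                    and p[idx - 1] >= 0
                    and p[idx] - p[idx - 1] == step
                )
                if ok:
                    k += 1
                    continue
                if k >= min_len and p[run_start] >= 0:
                    cand = ReplayEvent(run_start, k, sid, direction)
                    if _better(cand, best):
                        best = cand
                run_start = idx
                k = 1
    return best


def _better(cand: ReplayEvent, best: Optional[ReplayEvent]) -> bool:
    if best is None:
        return True
    key = lambda e: (-e.length, e.start, 0 if e.direction == "forward" else 1)
    return key(cand) < key(best)


def summarize_phase(
    traces: Iterable[ReplayTrace], task: TaskSpec, min_len: Optional[int] = None
) -> dict:
    """Aggregate event statistics over the periods of one phase.

    Event rate is reported per period; direction and per-sequence proportions
    are over detected events and are NaN when no event occurred.
    """
    traces = list(traces)
    events = [detect_replay_event(t, task, min_len) for t in traces]
    events = [e for e in events if e is not None]
    n_periods = len(traces)
    n_events = len(events)
    out = {
        "n_periods": n_periods,
        "n_events": n_events,
        "event_rate": n_events / n_periods if n_periods else math.nan,
        "mean_length": (
            float(np.mean([e.length for e in events])) if n_events else math.nan
        ),
        "forward_prop": math.nan,
        "backward_prop": math.nan,
    }
    if n_events:
        fwd = sum(e.direction == "forward" for e in events)
        out["forward_prop"] = fwd / n_events
        out["backward_prop"] = 1.0 - fwd / n_events
    for sid in range(len(task.match_sequences)):
        out[f"seq{sid}_prop"] = (
            sum(e.sequence_id == sid for e in events) / n_events if n_events else math.nan
        )
        out[f"seq{sid}_rate"] = (
            sum(e.sequence_id == sid for e in events) / n_periods if n_periods else math.nan
        )
    return out


def classify_remote(event: ReplayEvent, local_sequence_id: Optional[int]) -> bool:
    """Remote iff the event's matched sequence differs from the sequence the
    agent is resting on; undefined without a local reference (uncued phase)."""
    if local_sequence_id is None:
        raise ValueError("remote classification requires a local (cued) sequence")
    return event.sequence_id != local_sequence_id


def detect_shortcut(
    trace: ReplayTrace, task: TaskSpec, min_len: Optional[int] = None
) -> bool:
    """True iff the trace contains a never-experienced shortcut trajectory.

    The window must be a contiguous run of graph-adjacent steps of length at
    or above the event threshold, include items unique to each of the two
    sequences (both arms), and not itself be a contiguous segment of a single
    trained sequence.
    """
    if min_len is None:
        min_len = task.event_min_len
    space = task.item_space()
    graph = task.graph()
    items = _labels_of(task_items_of(trace, space.n_task), space.labels)
    if len(items) < min_len:
        return False
    membership = [set(sid for sid, seq in enumerate(task.sequences) if lab in seq) for lab in items]
    # maximal graph-adjacent runs
    start = 0
    for idx in range(1, len(items) + 1):
        ok = idx < len(items) and graph.adjacent(items[idx - 1], items[idx])
        if ok:
            continue
        run = items[start:idx]
        if len(run) >= min_len and _spans_both_arms(membership[start:idx]) and not _is_segment(
            run, task
        ):
            return True
        start = idx
    return False


def _spans_both_arms(membership: list[set]) -> bool:
    uniques = [next(iter(m)) for m in membership if len(m) == 1]
    return len(set(uniques)) >= 2


def _is_segment(run: Sequence[str], task: TaskSpec) -> bool:
    for seq in task.match_sequences:
        s = list(seq)
        for cand in (list(run), list(run)[::-1]):
            for off in range(len(s) - len(cand) + 1):
                if s[off : off + len(cand)] == cand:
                    return True
    return False


def lag_crp(
    traces: Iterable[ReplayTrace],
    reference_sequence: Sequence[int],
    window: int = 4,
    conditional: bool = True,
) -> pd.Series:
    """Conditional response probability of replay transitions by positional lag.

    For each within-trace transition from a reference item, the lag to the
    next reactivated item is tallied.  With ``conditional=True`` (the standard
    convention) the denominator for lag L counts only transitions for which
    the item at position i+L existed and had not yet been reactivated.  With
    ``conditional=False`` the observed in-window lags are simply normalized
    into a histogram.  Lags with zero denominator are NaN.
    """
    ref = list(reference_sequence)
    pos = {item: p for p, item in enumerate(ref)}
    lags = [l for l in range(-window, window + 1) if l != 0]
    num = {l: 0 for l in lags}
    den = {l: 0 for l in lags}
    for trace in traces:
        seen: set[int] = set()
        items = trace.items
        for i in range(len(items) - 1):
            cur = items[i]
            seen.add(cur)
            if cur not in pos:
                continue
            p = pos[cur]
            for l in lags:
                q = p + l
                if not (0 <= q < len(ref)):
                    continue
                if conditional and ref[q] in seen:
                    continue
                den[l] += 1
            nxt = items[i + 1]
            if nxt in pos:
                actual = pos[nxt] - p
                if actual in num:
                    num[actual] += 1
    if not conditional:
        total = sum(num.values())
        den = {l: total for l in lags}
    out = pd.Series(
        {l: (num[l] / den[l] if den[l] else math.nan) for l in lags}, name="crp"
    )
    out.index.name = "lag"
    return out


def contains_contiguous(
    trace_items: Sequence[int], sequence: Sequence[int], directions: str = "forward"
) -> bool:
    """Whether ``sequence`` occurs as a contiguous run inside ``trace_items``.

    ``directions`` is ``"forward"``, ``"backward"`` or ``"both"``.
    """
    targets = []
    if directions in ("forward", "both"):
        targets.append(list(sequence))
    if directions in ("backward", "both"):
        targets.append(list(sequence)[::-1])
    t = list(trace_items)
    for target in targets:
        m = len(target)
        for off in range(len(t) - m + 1):
            if t[off : off + m] == target:
                return True
    return False


def sequence_match_proportion(
    traces: Iterable[ReplayTrace],
    sequence: Sequence[int],
    directions: str = "forward",
) -> float:
    """Fraction of replay periods whose trace contains the full target
    sequence as a contiguous run (forward by default)."""
    traces = list(traces)
    if not traces:
        return math.nan
    hits = sum(contains_contiguous(t.items, sequence, directions) for t in traces)
    return hits / len(traces)


def nonlocal_preference(
    state: ModelState,
    start_item: int,
    candidate_items: tuple[int, int],
    T_readout: float = 0.14,
) -> tuple[float, float]:
    """Softmax readout between a start item's two possible successors.

    The start item's associated context cues ``M_cf``; the two candidates'
    activations are normalized at temperature ``T_readout``.
    """
    cue = retrieve_context(state, start_item)
    acts = state.M_cf[list(candidate_items), :] @ cue
    z = (acts - acts.max()) / T_readout
    e = np.exp(z)
    p = e / e.sum()
    return float(p[0]), float(p[1])


def compare_runs(a: Sequence[float], b: Sequence[float], paired: bool = False):
    """Two-tailed t-test across model runs (reporting plumbing)."""
    if paired:
        return stats.ttest_rel(a, b)
    return stats.ttest_ind(a, b)


def traces_to_frame(traces: Iterable[ReplayTrace], labels: Sequence[str]) -> pd.DataFrame:
    """Tidy CSV-ready view: one row per reactivation."""
    rows = []
    for t in traces:
        for step, item in enumerate(t.items):
            rows.append(
                {
                    "model_id": t.model_id,
                    "phase_id": t.phase_id,
                    "period": t.period,
                    "step": step,
                    "item_label": labels[item],
                    "terminated_by": t.terminated_by,
                }
            )
    return pd.DataFrame(rows)
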