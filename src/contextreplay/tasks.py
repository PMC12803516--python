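"""Task environments: sequence layouts, salience, distractors, session schedules.

Each task is a :class:`TaskSpec`: ordered item-label sequences (spatial
trajectories or stimulus streams), reward annotations that raise encoding
rates for salient items, optional distractor drifts between items, a session
schedule interleaving encoding and replay phases, and an adjacency graph over
items used by the shortcut analysis.  Geometries (track lengths, goal sites)
are transcribed from the simulated experimental layouts and exposed as
overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import yaml

from .model import EncodingEvent, ItemSpace
from .replay import PhaseSpec

__all__ = [
    "TaskSpec",
    "SessionSpec",
    "MazeGraph",
    "build_task",
    "task_names",
    "LAST_SEQUENCE_END",
]

#: sentinel cue label: the end item of the last-presented sequence of the
#: preceding session (resolved after sequence-order randomization)
LAST_SEQUENCE_END = "__last_sequence_end__"


@dataclass(frozen=True)
class SessionSpec:
    """One wake session: which sequences to encode (optionally in random
    order) and the replay phases that follow."""

    sequence_ids: tuple[int, ...]
    randomize: bool = True
    phases: tuple[PhaseSpec, ...] = ()
    shuffle_phases: bool = False


@dataclass(frozen=True)
class MazeGraph:
    """Undirected adjacency over items from within-sequence transitions.

    Transitions separated by a distractor are event boundaries, not spatial
    steps, and are excluded.
    """

    edges: frozenset

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges


@dataclass(frozen=True)
class TaskSpec:
    name: str
    sequences: tuple[tuple[str, ...], ...]
    reward_levels: dict = field(default_factory=dict)  # label -> level
    distractors: dict = field(default_factory=dict)  # (seq_idx, pos) -> beta
    sessions: tuple[SessionSpec, ...] = ()
    salient_final_sequence_end: Optional[str] = None
    event_min_len: int = 5
    true_sequences: tuple[tuple[str, ...], ...] = ()
    #: sequences used for replay-event matching when they differ from the
    #: encoded ones (e.g. tracks without non-spatial cue items)
    analysis_sequences: tuple[tuple[str, ...], ...] = ()

    @property
    def match_sequences(self) -> tuple[tuple[str, ...], ...]:
        return self.analysis_sequences or self.sequences

    @property
    def task_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for seq in self.sequences:
            for lab in seq:
                seen.setdefault(lab)
        return tuple(seen)

    def item_space(self) -> ItemSpace:
        return ItemSpace.for_task(self.task_labels, n_distractor=len(self.distractors))

    def distractor_units(self, space: ItemSpace) -> dict:
        """Stable assignment of one orthogonal unit per distractor event."""
        keys = sorted(self.distractors)
        return {k: space.n + i for i, k in enumerate(keys)}

    def graph(self) -> MazeGraph:
        edges = set()
        for s, seq in enumerate(self.sequences):
            for j in range(len(seq) - 1):
                if (s, j) in self.distractors:
                    continue
                edges.add(frozenset((seq[j], seq[j + 1])))
        return MazeGraph(edges=frozenset(edges))

    def encoding_events(
        self,
        seq_idx: int,
        space: ItemSpace,
        end_reward_override: Optional[str] = None,
    ) -> list[EncodingEvent]:
        """Expand a sequence into encoding events, inserting distractor drifts."""
        units = self.distractor_units(space)
        seq = self.sequences[seq_idx]
        events: list[EncodingEvent] = []
        for j, lab in enumerate(seq):
            reward = self.reward_levels.get(lab, "none")
            if end_reward_override is not None and j == len(seq) - 1:
                reward = end_reward_override
            events.append(EncodingEvent(item=space.index(lab), reward=reward))
            if (seq_idx, j) in self.distractors:
                events.append(
                    EncodingEvent(
                        item=units[(seq_idx, j)],
                        beta=self.distractors[(seq_idx, j)],
                        is_distractor=True,
                    )
                )
        return events

    # -- plain-text round trip -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sequences": [list(s) for s in self.sequences],
            "reward_levels": dict(self.reward_levels),
            "distractors": {f"{s}:{j}": b for (s, j), b in self.distractors.items()},
            "sessions": [
                {
                    "sequence_ids": list(sess.sequence_ids),
                    "randomize": sess.randomize,
                    "shuffle_phases": sess.shuffle_phases,
                    "phases": [
                        {
                            "mode": p.mode,
                            "n_periods": p.n_periods,
                            "cue_items": list(p.cue_items),
                            "learn": p.learn,
                            "phase_id": p.phase_id,
                        }
                        for p in sess.phases
                    ],
                }
                for sess in self.sessions
            ],
            "salient_final_sequence_end": self.salient_final_sequence_end,
            "event_min_len": self.event_min_len,
            "true_sequences": [list(s) for s in self.true_sequences],
            "analysis_sequences": [list(s) for s in self.analysis_sequences],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        return cls(
            name=d["name"],
            sequences=tuple(tuple(s) for s in d["sequences"]),
            reward_levels=dict(d.get("reward_levels", {})),
            distractors={
                (int(k.split(":")[0]), int(k.split(":")[1])): float(b)
                for k, b in d.get("distractors", {}).items()
            },
            sessions=tuple(
                SessionSpec(
                    sequence_ids=tuple(s["sequence_ids"]),
                    randomize=s.get("randomize", True),
                    shuffle_phases=s.get("shuffle_phases", False),
                    phases=tuple(
                        PhaseSpec(
                            mode=p["mode"],
                            n_periods=p["n_periods"],
                            cue_items=tuple(p.get("cue_items", ())),
                            learn=p.get("learn"),
                            phase_id=p.get("phase_id", ""),
                        )
                        for p in s.get("phases", ())
                    ),
                )
                for s in d.get("sessions", ())
            ),
            salient_final_sequence_end=d.get("salient_final_sequence_end"),
            event_min_len=d.get("event_min_len", 5),
            true_sequences=tuple(tuple(s) for s in d.get("true_sequences", ())),
            analysis_sequences=tuple(tuple(s) for s in d.get("analysis_sequences", ())),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TaskSpec":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# builders


def _rest(cue: str, n: int, phase_id: str) -> PhaseSpec:
    return PhaseSpec(mode="rest", n_periods=n, cue_items=(cue,), phase_id=phase_id)


def _linear_track(
    n_items: int = 10,
    n_sessions: int = 8,
    n_periods: int = 500,
    reward: str = "normal",
) -> TaskSpec:
    """Unidirectional linear track: one sequence, reward at the end, awake
    rest at the track end then the track start after every session."""
    seq = tuple(f"pos{i + 1}" for i in range(n_items))
    phases = (
        _rest(seq[-1], n_periods, "post_run_rest"),
        _rest(seq[0], n_periods, "pre_run_rest"),
    )
    return TaskSpec(
        name="linear_track",
        sequences=(seq,),
        reward_levels={seq[-1]: reward},
        sessions=tuple(
            SessionSpec(sequence_ids=(0,), randomize=False, phases=phases)
            for _ in range(n_sessions)
        ),
    )


def _liu2021_six(n_mid: int = 3, n_periods: int = 5000) -> TaskSpec:
    """Six sequences from three start items to two end items via unique paths.

    The end item of the last-presented sequence is encoded at high-reward
    rates (resolved after order randomization); rest is cued by that item.
    """
    starts = ("startA", "startB", "startC")
    ends = ("end1", "end2")
    seqs = []
    for i, s in enumerate(starts):
        for j, e in enumerate(ends):
            mids = tuple(f"path{i}{j}_{k + 1}" for k in range(n_mid))
            seqs.append((s,) + mids + (e,))
    phase = PhaseSpec(
        mode="rest", n_periods=n_periods, cue_items=(LAST_SEQUENCE_END,), phase_id="cued_rest"
    )
    return TaskSpec(
        name="liu2021_six",
        sequences=tuple(seqs),
        sessions=(SessionSpec(sequence_ids=tuple(range(6)), phases=(phase,)),),
        salient_final_sequence_end="high",
    )


def _two_choice_tmaze(
    condition: str = "alternation",
    rest: str = "cued",
    n_periods: int = 500,
    stem_len: int = 2,
    arm_len: int = 6,
    n_pretrain: int = 2,
) -> TaskSpec:
    """Two-choice maze: shared stem to a choice point, two arms with two
    reward (feeder) sites each (mid-arm and arm end).  Two pre-training
    sessions encode both arms; the final session encodes both (alternation)
    or one (L/R-only).  Cued rest happens at the feeders of the just-explored
    arm(s): all four in alternation, the experienced arm's two in L/R-only.
    Uncued replay (away from the maze) is available as an alternative.
    """
    stem = tuple(f"stem{i + 1}" for i in range(stem_len - 1)) + ("choice",)
    left = tuple(f"left{i + 1}" for i in range(arm_len))
    right = tuple(f"right{i + 1}" for i in range(arm_len))
    seq_l = stem + left
    seq_r = stem + right
    goals_l = (left[arm_len // 2 - 1], left[-1])
    goals_r = (right[arm_len // 2 - 1], right[-1])
    goals = goals_l + goals_r
    rest_sites = {"alternation": goals, "L": goals_l, "R": goals_r}
    final_ids = {"alternation": (0, 1), "L": (0,), "R": (1,)}
    if condition not in final_ids:
        raise ValueError("condition must be 'alternation', 'L' or 'R'")
    if rest == "cued":
        phases = tuple(_rest(g, n_periods, f"rest_at_{g}") for g in rest_sites[condition])
    elif rest == "uncued":
        phases = (PhaseSpec(mode="sleep", n_periods=n_periods, phase_id="uncued"),)
    else:
        raise ValueError("rest must be 'cued' or 'uncued'")
    sessions = tuple(
        SessionSpec(sequence_ids=(0, 1)) for _ in range(n_pretrain)
    ) + (
        SessionSpec(
            sequence_ids=final_ids[condition], phases=phases, shuffle_phases=True
        ),
    )
    return TaskSpec(
        name="two_choice_tmaze",
        sequences=(seq_l, seq_r),
        reward_levels={g: "normal" for g in goals},
        sessions=sessions,
    )


def _tmaze_reward(
    stem_len: int = 3, arm_len: int = 3, n_sleep: int = 5000, n_test: int = 5000
) -> TaskSpec:
    """T-maze with one rewarded and one neutral arm end; extended sleep
    flanked by no-learning test phases."""
    stem = tuple(f"stem{i + 1}" for i in range(stem_len))
    left = stem + tuple(f"left{i + 1}" for i in range(arm_len - 1)) + ("goal_rew",)
    right = stem + tuple(f"right{i + 1}" for i in range(arm_len - 1)) + ("goal_neu",)
    phases = (
        PhaseSpec(mode="test", n_periods=n_test, phase_id="pre_sleep_test"),
        PhaseSpec(mode="sleep", n_periods=n_sleep, phase_id="sleep"),
        PhaseSpec(mode="test", n_periods=n_test, phase_id="post_sleep_test"),
    )
    return TaskSpec(
        name="tmaze_reward",
        sequences=(left, right),
        reward_levels={"goal_rew": "normal"},
        sessions=(SessionSpec(sequence_ids=(0, 1), phases=phases),),
    )


def _tmr(arm_len: int = 3, n_periods: int = 500) -> TaskSpec:
    """Targeted memory reactivation: two runs share a start item, a distinct
    cue item follows the start in each, and sleep re-presents one of the two
    cues (chosen at random) each period."""
    left = ("start", "cueL") + tuple(f"left{i + 1}" for i in range(arm_len)) + ("goalL",)
    right = ("start", "cueR") + tuple(f"right{i + 1}" for i in range(arm_len)) + ("goalR",)
    phase = PhaseSpec(
        mode="rest", n_periods=n_periods, cue_items=("cueL", "cueR"), phase_id="tmr_sleep"
    )
    # events are scored on the spatial tracks; the auditory cue items are
    # encoded but are not track locations
    tracks = tuple(tuple(l for l in seq if not l.startswith("cue")) for seq in (left, right))
    return TaskSpec(
        name="tmr",
        sequences=(left, right),
        reward_levels={"goalL": "normal", "goalR": "normal"},
        sessions=(SessionSpec(sequence_ids=(0, 1), phases=(phase,)),),
        analysis_sequences=tracks,
    )


def _linear_track_directional(
    n_items: int = 8, reward_a: str = "normal", n_periods: int = 500
) -> TaskSpec:
    """Linear track with distinct directions of travel: two disjoint item
    sequences, both reward-terminated; the first sequence's reward magnitude
    is the manipulation.  Rest at the manipulated run's end, then its start."""
    a = tuple(f"fwd{i + 1}" for i in range(n_items))
    b = tuple(f"bwd{i + 1}" for i in range(n_items))
    phases = (
        _rest(a[-1], n_periods, "post_run_rest"),
        _rest(a[0], n_periods, "pre_run_rest"),
    )
    return TaskSpec(
        name="linear_track_directional",
        sequences=(a, b),
        reward_levels={a[-1]: reward_a, b[-1]: "normal"},
        sessions=(SessionSpec(sequence_ids=(0, 1), phases=phases),),
    )


def _liu2019_scrambled(n_periods: int = 1000) -> TaskSpec:
    """Scrambled-pair sequences over eight items.

    The presented sequences interleave pairwise transitions of two latent true
    sequences X1..X4 and Y1..Y4; a distractor drifts context between every
    pair of successive items, weakly (beta 0.3) within true-sequence
    transitions and near-totally (beta 0.99) otherwise.
    """
    X = tuple(f"X{i + 1}" for i in range(4))
    Y = tuple(f"Y{i + 1}" for i in range(4))
    seqs = (
        (X[0], X[1], Y[0], Y[1]),
        (X[1], X[2], Y[1], Y[2]),
        (X[2], X[3], Y[2], Y[3]),
    )
    true_pairs = {(s[i], s[i + 1]) for s in (X, Y) for i in range(3)}
    distractors = {}
    for s, seq in enumerate(seqs):
        for j in range(len(seq) - 1):
            beta = 0.3 if (seq[j], seq[j + 1]) in true_pairs else 0.99
            distractors[(s, j)] = beta
    phase = PhaseSpec(mode="sleep", n_periods=n_periods, phase_id="uncued")
    return TaskSpec(
        name="liu2019_scrambled",
        sequences=seqs,
        distractors=distractors,
        sessions=(SessionSpec(sequence_ids=(0, 1, 2), phases=(phase,)),),
        event_min_len=4,
        true_sequences=(X, Y),
    )


def _fixed_sequence(n_items: int = 5, n_sleep: int = 5000, n_test: int = 5000) -> TaskSpec:
    """A single five-item sequence; extended sleep flanked by test phases."""
    seq = tuple(f"seq{i + 1}" for i in range(n_items))
    phases = (
        PhaseSpec(mode="test", n_periods=n_test, phase_id="pre_sleep_test"),
        PhaseSpec(mode="sleep", n_periods=n_sleep, phase_id="sleep"),
        PhaseSpec(mode="test", n_periods=n_test, phase_id="post_sleep_test"),
    )
    return TaskSpec(
        name="fixed_sequence",
        sequences=(seq,),
        sessions=(SessionSpec(sequence_ids=(0,), randomize=False, phases=phases),),
    )


_BUILDERS = {
    "linear_track": _linear_track,
    "liu2021_six": _liu2021_six,
    "two_choice_tmaze": _two_choice_tmaze,
    "tmaze_reward": _tmaze_reward,
    "tmr": _tmr,
    "linear_track_directional": _linear_track_directional,
    "liu2019_scrambled": _liu2019_scrambled,
    "fixed_sequence": _fixed_sequence,
}


def task_names() -> tuple[str, ...]:
    return tuple(sorted(_BUILDERS))


def build_task(name: str, **overrides) -> TaskSpec:
    """Build a named task environment; ``overrides`` adjust lengths, session
    counts and phase sizes."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown task {name!r}; valid names: {', '.join(task_names())}"
        ) from None
    return builder(**overrides)
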