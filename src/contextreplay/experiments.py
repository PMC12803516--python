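"""Experiment registry: seeded multi-model simulations of the task protocols.

Every experiment spawns ``n_models`` independent model instances (the paper
protocols use 100), runs the task's session/phase schedule, applies the
replay analyses, and returns per-model records as a tidy DataFrame.  Model
``k`` of an experiment draws from a stream keyed only by the master seed,
the condition code and ``k``, so results are reproducible and stable under
changes of ``n_models``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .model import (
    EncodingEvent,
    EncodingRateSchedule,
    ItemSpace,
    ModelState,
    begin_session,
    encode_sequence,
)
from .replay import (
    PhaseSpec,
    ReplayParams,
    ReplayTrace,
    run_replay_phase,
    suppression_weights,
)
from .tasks import LAST_SEQUENCE_END, SessionSpec, TaskSpec, build_task
from .analysis import (
    classify_remote,
    contains_contiguous,
    detect_replay_event,
    detect_shortcut,
    lag_crp,
    nonlocal_preference,
    sequence_match_proportion,
    summarize_phase,
    task_items_of,
)

__all__ = [
    "ExperimentConfig",
    "ResultsBundle",
    "run_experiment",
    "experiment_names",
    "describe_experiment",
]


def _rng(seed: int, *keys: int) -> np.random.Generator:
    """Independent stream keyed by (master seed, condition, model index)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]])


# ---------------------------------------------------------------------------
# schedule runner


def _resolve_cues(phase: PhaseSpec, task: TaskSpec, space: ItemSpace, order: Sequence[int]) -> PhaseSpec:
    cues = []
    for c in phase.cue_items:
        if c == LAST_SEQUENCE_END:
            c = task.sequences[order[-1]][-1]
        cues.append(space.index(c) if isinstance(c, str) else int(c))
    return replace(phase, cue_items=tuple(cues))


def encode_wake_session(
    state: ModelState,
    task: TaskSpec,
    sess: SessionSpec,
    schedule: EncodingRateSchedule,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Encode one wake session; returns (presentation order, wake item ids)."""
    space = state.items
    order = list(sess.sequence_ids)
    if sess.randomize and len(order) > 1:
        rng.shuffle(order)
    wake_items = sorted(
        {space.index(lab) for sid in order for lab in task.sequences[sid]}
    )
    begin_session(state, wake_items)
    for k, sid in enumerate(order):
        override = (
            task.salient_final_sequence_end if k == len(order) - 1 else None
        )
        encode_sequence(state, task.encoding_events(sid, space, override), schedule)
    return order, wake_items


def salience_multipliers(
    task: TaskSpec,
    space: ItemSpace,
    schedule: EncodingRateSchedule,
    order: Sequence[int],
) -> np.ndarray:
    """Per-item salience factors scaling the replay learning rate.

    Replay learning mirrors awake encoding: a rewarded item's offline updates
    are scaled by the same reward multiplier that applied at encoding
    (including a final-sequence salience override resolved by ``order``).
    """
    mult = np.ones(space.n)
    for lab, level in task.reward_levels.items():
        mult[space.index(lab)] = schedule.reward_multipliers.get(level, 1.0)
    if task.salient_final_sequence_end is not None and order:
        end = task.sequences[order[-1]][-1]
        mult[space.index(end)] = schedule.reward_multipliers.get(
            task.salient_final_sequence_end, 1.0
        )
    return mult


def run_task_schedule(
    state: ModelState,
    task: TaskSpec,
    params: ReplayParams,
    schedule: EncodingRateSchedule,
    rng: np.random.Generator,
    model_id: Optional[int] = None,
) -> tuple[list[tuple[int, PhaseSpec, list[ReplayTrace]]], list[list[int]]]:
    """Run all sessions and phases of a task, threading model state.

    Returns phase records ``(session_idx, resolved_phase, traces)`` and the
    per-session sequence presentation orders.
    """
    records = []
    orders = []
    for s_idx, sess in enumerate(task.sessions):
        order, wake_items = encode_wake_session(state, task, sess, schedule, rng)
        orders.append(order)
        omega = suppression_weights(state, wake_items)
        mult = salience_multipliers(task, state.items, schedule, order)
        phases = list(sess.phases)
        if sess.shuffle_phases and len(phases) > 1:
            rng.shuffle(phases)
        for phase in phases:
            resolved = _resolve_cues(phase, task, state.items, order)
            traces, state = run_replay_phase(state, resolved, params, omega, rng, mult)
            for t in traces:
                t.model_id = model_id
            records.append((s_idx, resolved, traces))
    return records, orders


def _local_sequence_of(cue_item: int, task: TaskSpec, space: ItemSpace) -> Optional[int]:
    lab = space.labels[cue_item]
    owners = [sid for sid, seq in enumerate(task.sequences) if lab in seq]
    return owners[0] if len(owners) == 1 else None


# ---------------------------------------------------------------------------
# experiments


def directionality_linear_track(
    n_models: int = 100,
    seed: int = 0,
    n_sessions: int = 8,
    n_periods: int = 500,
    n_items: int = 10,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Forward/backward replay by rest position, tracked across sessions."""
    task = build_task(
        "linear_track", n_items=n_items, n_sessions=n_sessions, n_periods=n_periods
    )
    schedule = EncodingRateSchedule()
    rows = []
    for k in range(n_models):
        state = ModelState.fresh(task.item_space())
        records, _ = run_task_schedule(state, task, params, schedule, _rng(seed, 0, k), k)
        for s_idx, phase, traces in records:
            row = summarize_phase(traces, task)
            row.update(model=k, session=s_idx + 1, phase=phase.phase_id)
            rows.append(row)
    return {"summary": pd.DataFrame(rows)}


def sleep_vs_rest(
    n_models: int = 100,
    seed: int = 0,
    n_periods: int = 1000,
    n_items: int = 10,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Forward-replay proportion during sleep vs. awake rest at the track end."""
    base = build_task("linear_track", n_items=n_items, n_sessions=1)
    end = base.sequences[0][-1]
    rows = []
    for code, cond in enumerate(("sleep", "rest")):
        if cond == "sleep":
            phases = (PhaseSpec(mode="sleep", n_periods=n_periods, phase_id="sleep"),)
        else:
            phases = (
                PhaseSpec(mode="rest", n_periods=n_periods, cue_items=(end,), phase_id="rest_end"),
            )
        task = replace(base, sessions=(replace(base.sessions[0], phases=phases),))
        schedule = EncodingRateSchedule()
        for k in range(n_models):
            state = ModelState.fresh(task.item_space())
            records, _ = run_task_schedule(state, task, params, schedule, _rng(seed, code, k), k)
            row = summarize_phase(records[0][2], task)
            row.update(model=k, condition=cond)
            rows.append(row)
    return {"summary": pd.DataFrame(rows)}


def tmr(
    n_models: int = 100,
    seed: int = 0,
    n_periods: int = 500,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Targeted memory reactivation: per-period random cue biases replay."""
    task = build_task("tmr", n_periods=n_periods)
    space = task.item_space()
    cue_ids = {space.index("cueL"): "L", space.index("cueR"): "R"}
    schedule = EncodingRateSchedule()
    rows = []
    for k in range(n_models):
        state = ModelState.fresh(space)
        records, _ = run_task_schedule(state, task, params, schedule, _rng(seed, 0, k), k)
        traces = records[0][2]
        for cue_code in ("L", "R"):
            sub = [t for t in traces if cue_ids.get(t.cue_item) == cue_code]
            events = [detect_replay_event(t, task) for t in sub]
            n = len(sub)
            n_l = sum(1 for e in events if e is not None and e.sequence_id == 0)
            n_r = sum(1 for e in events if e is not None and e.sequence_id == 1)
            cued = n_l if cue_code == "L" else n_r
            uncued = n_r if cue_code == "L" else n_l
            rows.append(
                {
                    "model": k,
                    "cue": cue_code,
                    "n_periods": n,
                    "cued_seq_prop": cued / n if n else np.nan,
                    "uncued_seq_prop": uncued / n if n else np.nan,
                }
            )
    return {"summary": pd.DataFrame(rows)}


def _reactivation_prop(traces: list[ReplayTrace], item: int) -> float:
    if not traces:
        return np.nan
    return sum(item in t.items for t in traces) / len(traces)


def reward_overrepresentation(
    n_models: int = 100,
    seed: int = 0,
    n_sleep: int = 5000,
    n_test: int = 5000,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Sleep reactivation of a rewarded vs. matched neutral goal item, with
    pre/post-sleep test phases quantifying the consolidation gain."""
    task = build_task("tmaze_reward", n_sleep=n_sleep, n_test=n_test)
    space = task.item_space()
    rew, neu = space.index("goal_rew"), space.index("goal_neu")
    schedule = EncodingRateSchedule()
    rows = []
    for k in range(n_models):
        state = ModelState.fresh(space)
        records, _ = run_task_schedule(state, task, params, schedule, _rng(seed, 0, k), k)
        by_phase = {phase.phase_id: traces for _, phase, traces in records}
        rows.append(
            {
                "model": k,
                "sleep_rew_prop": _reactivation_prop(by_phase["sleep"], rew),
                "sleep_neu_prop": _reactivation_prop(by_phase["sleep"], neu),
                "pre_rew_prop": _reactivation_prop(by_phase["pre_sleep_test"], rew),
                "pre_neu_prop": _reactivation_prop(by_phase["pre_sleep_test"], neu),
                "post_rew_prop": _reactivation_prop(by_phase["post_sleep_test"], rew),
                "post_neu_prop": _reactivation_prop(by_phase["post_sleep_test"], neu),
            }
        )
    df = pd.DataFrame(rows)
    df["gain_rew"] = df.post_rew_prop - df.pre_rew_prop
    df["gain_neu"] = df.post_neu_prop - df.pre_neu_prop
    return {"summary": df}


def reward_magnitude(
    n_models: int = 100,
    seed: int = 0,
    n_periods: int = 500,
    n_items: int = 8,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Forward/backward event counts for a run whose terminal reward is low,
    normal or high (the paired run's reward is always normal)."""
    schedule = EncodingRateSchedule()
    rows = []
    for code, cond in enumerate(("low", "normal", "high")):
        task = build_task(
            "linear_track_directional", reward_a=cond, n_periods=n_periods, n_items=n_items
        )
        space = task.item_space()
        for k in range(n_models):
            state = ModelState.fresh(space)
            records, _ = run_task_schedule(state, task, params, schedule, _rng(seed, code, k), k)
            n_fwd = n_bwd = 0
            for _, phase, traces in records:
                for t in traces:
                    e = detect_replay_event(t, task)
                    if e is not None and e.sequence_id == 0:
                        if e.direction == "forward":
                            n_fwd += 1
                        else:
                            n_bwd += 1
            rows.append({"model": k, "condition": cond, "n_forward": n_fwd, "n_backward": n_bwd})
    return {"summary": pd.DataFrame(rows)}


def remote_shortcut(
    n_models: int = 100,
    seed: int = 0,
    n_periods: int = 500,
    conditions: Sequence[str] = ("alternation", "L", "R"),
    include_uncued: bool = True,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Two-choice maze: remote replay of the non-local arm during cued rest,
    novel shortcut trajectories, and (uncued) over-representation of the
    non-experienced arm after single-arm experience."""
    schedule = EncodingRateSchedule()
    rows = []
    cond_codes = {"alternation": 0, "L": 1, "R": 2}
    for cond in conditions:
        task = build_task("two_choice_tmaze", condition=cond, n_periods=n_periods)
        space = task.item_space()
        for k in range(n_models):
            state = ModelState.fresh(space)
            records, _ = run_task_schedule(
                state, task, params, schedule, _rng(seed, cond_codes[cond], k), k
            )
            n_seq_events = n_remote = n_shortcut = n_events = 0
            for s_idx, phase, traces in records:
                local = _local_sequence_of(phase.cue_items[0], task, space)
                for t in traces:
                    e = detect_replay_event(t, task)
                    shortcut = detect_shortcut(t, task)
                    # a period is a replay event if it replays a trained
                    # sequence segment or a novel shortcut trajectory
                    if e is not None or shortcut:
                        n_events += 1
                    if shortcut:
                        n_shortcut += 1
                    if e is not None:
                        n_seq_events += 1
                        if classify_remote(e, local):
                            n_remote += 1
            rows.append(
                {
                    "model": k,
                    "condition": cond,
                    "n_events": n_events,
                    "remote_prop": n_remote / n_seq_events if n_seq_events else np.nan,
                    "shortcut_prop": n_shortcut / n_events if n_events else np.nan,
                }
            )
    out = {"summary": pd.DataFrame(rows)}
    if include_uncued:
        urows = []
        for cond in ("L", "R"):
            task = build_task("two_choice_tmaze", condition=cond, rest="uncued", n_periods=n_periods)
            space = task.item_space()
            for k in range(n_models):
                state = ModelState.fresh(space)
                records, _ = run_task_schedule(
                    state, task, params, schedule, _rng(seed, 10 + cond_codes[cond], k), k
                )
                row = summarize_phase(records[0][2], task)
                urows.append(
                    {
                        "model": k,
                        "condition": cond,
                        "left_prop": row["seq0_prop"],
                        "right_prop": row["seq1_prop"],
                    }
                )
        out["uncued"] = pd.DataFrame(urows)
    return out


def liu2019(
    n_models: int = 100,
    seed: int = 0,
    n_periods: int = 1000,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Replay of latent true sequences vs. the scrambled presented sequences."""
    task = build_task("liu2019_scrambled", n_periods=n_periods)
    space = task.item_space()
    true_idx = [[space.index(l) for l in s] for s in task.true_sequences]
    pres_idx = [[space.index(l) for l in s] for s in task.sequences]
    schedule = EncodingRateSchedule()
    rows = []
    for k in range(n_models):
        state = ModelState.fresh(space)
        records, _ = run_task_schedule(state, task, params, schedule, _rng(seed, 0, k), k)
        traces = records[0][2]
        true_prop = float(
            np.mean([sequence_match_proportion(traces, s, "both") for s in true_idx])
        )
        scr_prop = float(
            np.mean([sequence_match_proportion(traces, s, "both") for s in pres_idx])
        )
        rows.append({"model": k, "true_prop": true_prop, "scrambled_prop": scr_prop})
    return {"summary": pd.DataFrame(rows)}


def sequence_memory(
    n_models: int = 100,
    seed: int = 0,
    n_sleep: int = 5000,
    n_test: int = 5000,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Full-sequence replay proportion before vs. after an extended sleep."""
    task = build_task("fixed_sequence", n_sleep=n_sleep, n_test=n_test)
    space = task.item_space()
    seq = [space.index(l) for l in task.sequences[0]]
    schedule = EncodingRateSchedule()
    rows = []
    for k in range(n_models):
        state = ModelState.fresh(space)
        records, _ = run_task_schedule(state, task, params, schedule, _rng(seed, 0, k), k)
        by_phase = {phase.phase_id: traces for _, phase, traces in records}
        rows.append(
            {
                "model": k,
                "pre_match": sequence_match_proportion(by_phase["pre_sleep_test"], seq),
                "post_match": sequence_match_proportion(by_phase["post_sleep_test"], seq),
            }
        )
    return {"summary": pd.DataFrame(rows)}


def nonlocal_learning(
    n_models: int = 100,
    seed: int = 0,
    n_rest: int = 5000,
    T_readout: float = 0.14,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Preference for the reward-linked path of non-local start items,
    measured by a softmax readout before and after cued rest."""
    task = build_task("liu2021_six", n_periods=n_rest)
    space = task.item_space()
    schedule = EncodingRateSchedule()

    def preference(state: ModelState, rewarded_end: str, local_start: str) -> float:
        prefs = []
        for start in ("startA", "startB", "startC"):
            if start == local_start:
                continue
            seqs = [s for s in task.sequences if s[0] == start]
            rew_seq = next(s for s in seqs if s[-1] == rewarded_end)
            alt_seq = next(s for s in seqs if s[-1] != rewarded_end)
            p_rew, _ = nonlocal_preference(
                state,
                space.index(start),
                (space.index(rew_seq[1]), space.index(alt_seq[1])),
                T_readout,
            )
            prefs.append(p_rew)
        return float(np.mean(prefs))

    rows = []
    for k in range(n_models):
        rng = _rng(seed, 0, k)
        state = ModelState.fresh(space)
        sess = task.sessions[0]
        order, wake_items = encode_wake_session(state, task, sess, schedule, rng)
        rewarded_end = task.sequences[order[-1]][-1]
        local_start = task.sequences[order[-1]][0]
        pre = preference(state, rewarded_end, local_start)
        omega = suppression_weights(state, wake_items)
        mult = salience_multipliers(task, space, schedule, order)
        phase = _resolve_cues(sess.phases[0], task, space, order)
        _, state = run_replay_phase(state, phase, params, omega, rng, mult)
        post = preference(state, rewarded_end, local_start)
        rows.append({"model": k, "pre_pref": pre, "post_pref": post})
    return {"summary": pd.DataFrame(rows)}


def teacher_student(
    n_models: int = 100,
    seed: int = 0,
    n_sleep: int = 5000,
    n_items: int = 6,
    params: ReplayParams = ReplayParams(),
) -> dict:
    """Distillation: a student trained only on a teacher's sleep replay
    inherits the teacher's lag contiguity profile."""
    task = build_task("linear_track", n_items=n_items, n_sessions=1)
    space = task.item_space()
    seq = [space.index(l) for l in task.sequences[0]]
    schedule = EncodingRateSchedule()
    student_schedule = EncodingRateSchedule(
        gamma_fc_base=params.gamma_replay,
        gamma_cf_base=params.gamma_replay,
        reward_multipliers={"none": 1.0, "low": 1.0, "normal": 1.0, "high": 1.0},
        novelty_decay=False,
    )
    sleep = PhaseSpec(mode="sleep", n_periods=n_sleep, phase_id="sleep")
    rows = []
    for k in range(n_models):
        rng = _rng(seed, 0, k)
        teacher = ModelState.fresh(space)
        sess = task.sessions[0]
        order, wake_items = encode_wake_session(teacher, task, sess, schedule, rng)
        omega = suppression_weights(teacher, wake_items)
        mult = salience_multipliers(task, space, schedule, order)
        t_traces, teacher = run_replay_phase(teacher, sleep, params, omega, rng, mult)

        student = ModelState.fresh(space)
        trained_items: set[int] = set()
        train_seqs = [task_items_of(t, space.n_task) for t in t_traces]
        begin_session(student, {i for s in train_seqs for i in s})
        for items in train_seqs:
            if not items:
                continue
            encode_sequence(
                student, [EncodingEvent(item=i) for i in items], student_schedule
            )
            trained_items.update(items)
        s_omega = suppression_weights(student, sorted(trained_items))
        s_traces, student = run_replay_phase(student, sleep, params, s_omega, rng)

        for role, traces in (("teacher", t_traces), ("student", s_traces)):
            crp = lag_crp(traces, seq)
            for lag, p in crp.items():
                rows.append({"model": k, "role": role, "lag": int(lag), "p": p})
    return {"summary": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# registry, config, bundle

_REGISTRY: dict[str, tuple[Callable[..., dict], str]] = {
    "directionality_linear_track": (
        directionality_linear_track,
        "Forward vs. backward replay at the start/end of a linear track, across 8 sessions.",
    ),
    "sleep_vs_rest": (
        sleep_vs_rest,
        "Forward-replay proportion in sleep vs. awake rest at the track end.",
    ),
    "tmr": (tmr, "Targeted memory reactivation: sleep cues bias replay toward the cued run."),
    "reward_overrepresentation": (
        reward_overrepresentation,
        "Sleep over-representation of a rewarded vs. neutral goal, with pre/post tests.",
    ),
    "reward_magnitude": (
        reward_magnitude,
        "Reward magnitude modulates backward but not forward replay counts.",
    ),
    "remote_shortcut": (
        remote_shortcut,
        "Remote replay, shortcut sequences, and non-preferred-arm replay in a two-choice maze.",
    ),
    "liu2019": (liu2019, "Replay reorganizes scrambled inputs toward latent true sequences."),
    "sequence_memory": (
        sequence_memory,
        "Sleep strengthens full-sequence replay of a five-item sequence.",
    ),
    "nonlocal_learning": (
        nonlocal_learning,
        "Cued rest propagates reward preference to non-local sequences.",
    ),
    "teacher_student": (
        teacher_student,
        "A student model trained on a teacher's replay inherits its contiguity bias.",
    ),
}


@dataclass(frozen=True)
class ExperimentConfig:
    name: str
    n_models: int = 100
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    outdir: Optional[str] = None


@dataclass
class ResultsBundle:
    manifest: dict
    summary: pd.DataFrame
    extras: dict = field(default_factory=dict)


def experiment_names() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def describe_experiment(name: str) -> str:
    if name not in _REGISTRY:
        raise ValueError(
            f"unknown experiment {name!r}; valid names: {', '.join(experiment_names())}"
        )
    return _REGISTRY[name][1]


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Run a registered experiment and (optionally) write its bundle.

    Identical configs produce byte-identical summaries; every override is
    recorded in the run manifest.
    """
    if config.name not in _REGISTRY:
        raise ValueError(
            f"unknown experiment {config.name!r}; valid names: {', '.join(experiment_names())}"
        )
    func, _ = _REGISTRY[config.name]
    out = func(n_models=config.n_models, seed=config.seed, **config.overrides)
    summary = out.pop("summary")
    manifest = {
        "experiment": config.name,
        "n_models": config.n_models,
        "seed": config.seed,
        "overrides": {k: repr(v) for k, v in config.overrides.items()},
        "replay_params": dataclasses.asdict(ReplayParams()),
        "version": _version,
    }
    bundle = ResultsBundle(manifest=manifest, summary=summary, extras=out)
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        summary.to_csv(os.path.join(config.outdir, "summary.csv"), index=False)
        for key, df in out.items():
            df.to_csv(os.path.join(config.outdir, f"{key}.csv"), index=False)
    return bundle
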