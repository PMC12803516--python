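"""Core retrieved-context memory model: representations, context drift, Hebbian encoding.

The model maintains two associative matrices over a space of localist (one-hot)
items: an item-to-context map ``M_fc`` and a context-to-item map ``M_cf``.  A
drifting context vector ``c`` carries a recency-weighted mixture of the
associated contexts of recently presented items.  Awake encoding of a sequence
interleaves three steps per item: retrieve the item's associated context,
drift the running context toward it, and Hebbian-associate the item with the
drifted context.  Encoding rates scale with the salience (reward, novelty) of
the current item only.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ItemSpace",
    "ModelState",
    "EncodingRateSchedule",
    "DriftParams",
    "EncodingEvent",
    "DegenerateMemoryError",
    "retrieve_context",
    "retrieved_context_norm",
    "drift_context",
    "associate",
    "effective_rate",
    "begin_session",
    "encode_sequence",
    "save_state",
    "load_state",
]

#: scaling of the identity initialization of the two associative matrices
FC_INIT_SCALE = 1.0
CF_INIT_SCALE = 0.7

#: reward levels recognised by the encoding-rate schedule
REWARD_LEVELS = ("none", "low", "normal", "high")


class DegenerateMemoryError(ValueError):
    """Raised when an item's stored context has zero norm and cannot be retrieved."""


@dataclass(frozen=True)
class ItemSpace:
    """The set of units a model knows about.

    Task items (indices ``0..n_task-1``) are presented during awake learning
    and can be replayed.  Non-task items (``n_task..n-1``) never appear as wake
    inputs but compete for reactivation during replay; reactivating one
    terminates a replay period.  Distractor units (``n..dim-1``) are auxiliary
    orthogonal directions used only to drift context between items (event
    boundaries); they are never associated and never enter the replay
    competition.
    """

    n_task: int
    n_nontask: int
    n_distractor: int = 0
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_task < 1:
            raise ValueError("need at least one task item")
        if not self.labels:
            labels = tuple(
                [f"item{i}" for i in range(self.n_task)]
                + [f"offtask{i}" for i in range(self.n_nontask)]
            )
            object.__setattr__(self, "labels", labels)
        if len(self.labels) != self.n:
            raise ValueError("labels must cover task + non-task items")

    @property
    def n(self) -> int:
        """Total number of items competing during replay."""
        return self.n_task + self.n_nontask

    @property
    def dim(self) -> int:
        """Dimensionality of item/context vectors (items + distractor units)."""
        return self.n + self.n_distractor

    @classmethod
    def for_task(cls, task_labels: Sequence[str], n_distractor: int = 0) -> "ItemSpace":
        """Default construction: non-task pool is half the task pool, rounded up."""
        n_task = len(task_labels)
        n_nontask = math.ceil(n_task / 2)
        labels = tuple(list(task_labels) + [f"offtask{i}" for i in range(n_nontask)])
        return cls(n_task=n_task, n_nontask=n_nontask, n_distractor=n_distractor, labels=labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def is_task(self, item: int) -> bool:
        return 0 <= item < self.n_task

    def is_nontask(self, item: int) -> bool:
        return self.n_task <= item < self.n


@dataclass
class ModelState:
    """Entire mutable state of one agent.

    ``M_fc`` columns store each item's associated context; ``M_cf`` rows map a
    context back onto items.  Both start as scaled identities, so before any
    learning each item retrieves its own orthogonal context feature.
    ``session_counts[i]`` counts the wake sessions (including the current one)
    in which item ``i`` has appeared; it drives the novelty decay of encoding
    rates.
    """

    items: ItemSpace
    M_fc: np.ndarray
    M_cf: np.ndarray
    c: np.ndarray
    session_counts: np.ndarray
    #: per-item norm of the retrieved context at the moment the item was
    #: (first) retrieved in the current wake session, i.e. before that
    #: session's own updates; drives replay-onset suppression
    wake_norms: dict = field(default_factory=dict)

    @classmethod
    def fresh(cls, items: ItemSpace) -> "ModelState":
        d = items.dim
        return cls(
            items=items,
            M_fc=FC_INIT_SCALE * np.eye(d),
            M_cf=CF_INIT_SCALE * np.eye(d),
            c=np.zeros(d),
            session_counts=np.zeros(d, dtype=np.int64),
        )

    def copy(self) -> "ModelState":
        return ModelState(
            items=self.items,
            M_fc=self.M_fc.copy(),
            M_cf=self.M_cf.copy(),
            c=self.c.copy(),
            session_counts=self.session_counts.copy(),
            wake_norms=dict(self.wake_norms),
        )

    def reset_context(self) -> None:
        """Zero the drifting context (event boundary between sequences)."""
        self.c = np.zeros(self.items.dim)


@dataclass(frozen=True)
class EncodingRateSchedule:
    """Encoding rates and their modulation by reward salience and novelty.

    ``reward_multipliers`` maps a reward level to the rate used for that item;
    repetition across sessions divides an item's rate by its session count when
    ``novelty_decay`` is on, which keeps weights from growing linearly and
    replay from becoming deterministic.
    """

    gamma_fc_base: float = 1.0
    gamma_cf_base: float = 1.0
    reward_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"none": 1.0, "low": 1.0, "normal": 1.5, "high": 2.0}
    )
    novelty_decay: bool = True

    def __post_init__(self):
        if self.gamma_fc_base <= 0 or self.gamma_cf_base <= 0:
            raise ValueError("base encoding rates must be positive")
        if any(v <= 0 for v in self.reward_multipliers.values()):
            raise ValueError("reward multipliers must be positive")


@dataclass(frozen=True)
class DriftParams:
    """Context-drift rates.  ``beta`` applies to ordinary item steps; the two
    distractor rates apply to boundary drifts in the scrambled-sequence task
    (small drift within a true-sequence transition, near-total drift across
    unrelated transitions)."""

    beta: float = 0.75
    beta_distractor_true: float = 0.3
    beta_distractor_scrambled: float = 0.99
    #: optional sensitivity switch: renormalize the context to unit length
    #: after the first drift following a zero reset.  The default applies the
    #: drift recurrence literally, which leaves the first post-reset context
    #: at norm beta and sequence-initial items comparatively under-suppressed
    #: at replay onset.
    normalize_first_drift: bool = False

    def __post_init__(self):
        for b in (self.beta, self.beta_distractor_true, self.beta_distractor_scrambled):
            if not (0.0 < b <= 1.0):
                raise ValueError("drift rates must lie in (0, 1]")


@dataclass(frozen=True)
class EncodingEvent:
    """One step of a wake sequence: an item presentation or a distractor drift.

    ``item`` indexes an item for presentations, or a distractor unit
    (``>= items.n``) when ``is_distractor``.  ``beta`` overrides the default
    drift rate for this step.  ``reward`` names the salience level of the item.
    """

    item: int
    reward: str = "none"
    beta: Optional[float] = None
    is_distractor: bool = False


def retrieve_context(state: ModelState, item: int) -> np.ndarray:
    """Retrieve an item's associated context (unit-normalized ``M_fc`` column)."""
    col = state.M_fc[:, item]
    norm = float(np.linalg.norm(col))
    if norm <= 0.0:
        raise DegenerateMemoryError(f"item {item} has a zero-norm stored context")
    return col / norm


def retrieved_context_norm(state: ModelState, item: int) -> float:
    """Euclidean norm of the *unnormalized* retrieved context ``M_fc f``.

    This magnitude tracks how much context activity an item accrued during
    learning; the replay-onset suppression weight is ``exp(-norm)``.
    """
    return float(np.linalg.norm(state.M_fc[:, item]))


def drift_context(c_prev: np.ndarray, c_in: np.ndarray, beta: float) -> np.ndarray:
    """Drift context toward an incoming (unit) context at rate ``beta``.

    Returns ``rho * c_prev + beta * c_in`` where ``rho`` is chosen so that a
    unit-norm ``c_prev`` yields a unit-norm result.  Applied literally from a
    zero context (after a reset), the result has norm ``beta``.
    """
    dot = float(c_prev @ c_in)
    rho = math.sqrt(1.0 + beta * beta * (dot * dot - 1.0)) - beta * dot
    return rho * c_prev + beta * c_in


def associate(
    state: ModelState,
    item: int,
    c: np.ndarray,
    gamma_fc: float,
    gamma_cf: float,
) -> None:
    """Hebbian update: add outer products of the item and context to both maps.

    With a one-hot item this touches exactly one column of ``M_fc`` and one row
    of ``M_cf``.  Mutates ``state`` in place.
    """
    if gamma_fc < 0 or gamma_cf < 0:
        raise ValueError("encoding rates must be nonnegative")
    state.M_fc[:, item] += gamma_fc * c
    state.M_cf[item, :] += gamma_cf * c


def effective_rate(
    schedule: EncodingRateSchedule, reward_level: str, session_index: int
) -> tuple[float, float]:
    """Encoding rates for an item at a given reward level and session count.

    ``session_index`` is the number of wake sessions (including the current
    one) in which the item has appeared; novelty decay divides the rate by it.
    """
    if session_index < 1:
        raise ValueError("session_index must be >= 1")
    if reward_level not in REWARD_LEVELS:
        raise ValueError(f"unknown reward level {reward_level!r}")
    mult = schedule.reward_multipliers.get(reward_level, 1.0)
    g_fc = schedule.gamma_fc_base * mult
    g_cf = schedule.gamma_cf_base * mult
    if schedule.novelty_decay:
        g_fc /= session_index
        g_cf /= session_index
    return g_fc, g_cf


def begin_session(state: ModelState, items: Iterable[int]) -> None:
    """Mark the start of a wake session: bump session counts of presented
    items and clear the previous session's retrieved-context norms."""
    state.wake_norms = {}
    for i in set(items):
        state.session_counts[i] += 1


def encode_sequence(
    state: ModelState,
    events: Sequence[EncodingEvent],
    schedule: EncodingRateSchedule,
    drift: DriftParams = DriftParams(),
) -> ModelState:
    """Encode one wake sequence, mutating and returning ``state``.

    Context is reset to zero first (sequence boundaries are event boundaries).
    Item events retrieve, drift, then associate at the item's effective rate;
    distractor events only drift context toward the distractor's own orthogonal
    unit, with no Hebbian update.  Deterministic.
    """
    state.reset_context()
    first = True
    for ev in events:
        beta = ev.beta if ev.beta is not None else drift.beta
        if ev.is_distractor:
            c_in = np.zeros(state.items.dim)
            c_in[ev.item] = 1.0
            state.c = drift_context(state.c, c_in, beta)
            first = False
            continue
        if not state.items.is_task(ev.item):
            raise ValueError(f"cannot encode non-task item {ev.item}")
        if ev.item not in state.wake_norms:
            state.wake_norms[ev.item] = retrieved_context_norm(state, ev.item)
        c_in = retrieve_context(state, ev.item)
        state.c = drift_context(state.c, c_in, beta)
        if first and drift.normalize_first_drift:
            norm = float(np.linalg.norm(state.c))
            if norm > 0:
                state.c = state.c / norm
        first = False
        sess = max(int(state.session_counts[ev.item]), 1)
        g_fc, g_cf = effective_rate(schedule, ev.reward, sess)
        associate(state, ev.item, state.c, g_fc, g_cf)
    return state


# ---------------------------------------------------------------------------
# plain-text serialization: JSON header + CSV matrix payloads (diffable)

def save_state(state: ModelState, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    header = {
        "n_task": state.items.n_task,
        "n_nontask": state.items.n_nontask,
        "n_distractor": state.items.n_distractor,
        "labels": list(state.items.labels),
        "context": state.c.tolist(),
        "session_counts": state.session_counts.tolist(),
        "wake_norms": {str(k): v for k, v in state.wake_norms.items()},
    }
    with open(os.path.join(directory, "state.json"), "w") as fh:
        json.dump(header, fh, indent=1)
    np.savetxt(os.path.join(directory, "m_fc.csv"), state.M_fc, delimiter=",")
    np.savetxt(os.path.join(directory, "m_cf.csv"), state.M_cf, delimiter=",")


def load_state(directory: str) -> ModelState:
    with open(os.path.join(directory, "state.json")) as fh:
        header = json.load(fh)
    items = ItemSpace(
        n_task=header["n_task"],
        n_nontask=header["n_nontask"],
        n_distractor=header["n_distractor"],
        labels=tuple(header["labels"]),
    )
    M_fc = np.loadtxt(os.path.join(directory, "m_fc.csv"), delimiter=",", ndmin=2)
    M_cf = np.loadtxt(os.path.join(directory, "m_cf.csv"), delimiter=",", ndmin=2)
    return ModelState(
        items=items,
        M_fc=M_fc,
        M_cf=M_cf,
        c=np.asarray(header["context"], dtype=float),
        session_counts=np.asarray(header["session_counts"], dtype=np.int64),
        wake_norms={int(k): float(v) for k, v in header.get("wake_norms", {}).items()},
    )
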