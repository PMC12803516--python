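"""Autonomous replay: onset distribution, softmax reactivation cascade, suppression.

A replay period starts by sampling an item from an onset distribution built
from uniform noise, optionally biased by a cue-evoked softmax (awake rest /
targeted reactivation), and multiplicatively suppressed for items that were
active in the preceding wake session.  If the sampled item is task-related,
its associated context is reinstated and the model enters a recursive loop:
stop check, softmax over not-yet-reactivated items cued by the current
context, reinstate the winner's context, drift, and (optionally) learn at a
slow rate.  A period ends on the stop draw, on reactivating a non-task item,
or on exhausting the candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    ModelState,
    associate,
    drift_context,
    retrieve_context,
    retrieved_context_norm,
)

__all__ = [
    "ReplayParams",
    "SuppressionWeights",
    "ReplayTrace",
    "PhaseSpec",
    "suppression_weights",
    "evoked_distribution",
    "initial_distribution",
    "sample_replay_period",
    "run_replay_phase",
]


@dataclass(frozen=True)
class ReplayParams:
    """Parameters of the offline reactivation process.

    ``T0`` is the softmax temperature used for the cue-evoked component of the
    onset distribution; ``T`` governs every subsequent reactivation.
    ``lambda_cue`` weighs the cue-evoked activity against onset noise drawn
    uniformly from ``[0, noise_high]``; the evoked term is a probability
    vector, so the default 0.005 makes a cued item dominate onset without
    determinism.  ``gamma_replay`` is the slow Hebbian rate used when learning
    from replay.  ``beta`` is the context-drift rate during replay.
    """

    stop_prob: float = 0.1
    T0: float = 0.1
    T: float = 0.14
    gamma_replay: float = 0.001
    noise_high: float = 0.001
    lambda_cue: float = 0.005
    beta: float = 0.75

    def __post_init__(self):
        if not (0.0 < self.stop_prob <= 1.0):
            raise ValueError("stop_prob must lie in (0, 1]")
        if self.T0 <= 0 or self.T <= 0:
            raise ValueError("temperatures must be positive")
        if self.gamma_replay < 0:
            raise ValueError("gamma_replay must be nonnegative")
        if self.noise_high <= 0:
            raise ValueError("noise_high must be positive")


@dataclass(frozen=True)
class SuppressionWeights:
    """Per-item multiplicative onset weights ``omega`` in (0, 1].

    Items shown in the preceding wake session are down-weighted by
    ``exp(-||M_fc f||)`` (the norm of their unnormalized retrieved context,
    which grows with learning); all other items keep weight 1.
    """

    omega: np.ndarray

    def __post_init__(self):
        if np.any(self.omega <= 0) or np.any(self.omega > 1.0 + 1e-12):
            raise ValueError("omega entries must lie in (0, 1]")


@dataclass
class ReplayTrace:
    """Ordered reactivations of one replay period, with phase metadata.

    If the period ended on a non-task item, that item is the final entry; it
    is recorded for audit but excluded from sequence analyses.
    """

    items: list[int]
    terminated_by: str  # "stop_prob" | "nontask_item" | "exhausted"
    model_id: Optional[int] = None
    phase_id: Optional[str] = None
    period: Optional[int] = None
    cue_item: Optional[int] = None


@dataclass(frozen=True)
class PhaseSpec:
    """Schedule for one replay phase.

    ``mode`` is ``"rest"`` (cued, learning), ``"sleep"`` (uncued, learning) or
    ``"test"`` (uncued, no learning).  ``cue_items`` holds zero or more item
    indices/labels; with several, one is drawn at random each period (targeted
    reactivation).  ``learn`` may override the mode's default.
    """

    mode: str
    n_periods: int
    cue_items: tuple = ()
    learn: Optional[bool] = None
    phase_id: str = ""

    def __post_init__(self):
        if self.mode not in ("rest", "sleep", "test"):
            raise ValueError(f"unknown phase mode {self.mode!r}")
        if self.mode == "test" and (self.cue_items or self.learn):
            raise ValueError("test phases are uncued and non-learning")

    @property
    def learning(self) -> bool:
        if self.learn is not None:
            return self.learn
        return self.mode != "test"


def suppression_weights(
    state: ModelState, wake_items: Optional[Sequence[int]] = None
) -> SuppressionWeights:
    """Onset suppression from the just-finished wake session.

    Each wake item's weight is ``exp(-||c_f||)`` where ``||c_f||`` is the
    (unnormalized) retrieved-context norm recorded when the item was
    retrieved during that session's encoding — so an item's suppression
    reflects learning accrued in *earlier* sessions, not its own update in
    the session just ended.  Items without a recorded norm fall back to the
    current state's norm; items outside ``wake_items`` keep weight 1.
    """
    if wake_items is None:
        wake_items = list(state.wake_norms)
    omega = np.ones(state.items.n)
    for i in set(wake_items):
        norm = state.wake_norms.get(i)
        if norm is None:
            norm = retrieved_context_norm(state, i)
        omega[i] = np.exp(-norm)
    return SuppressionWeights(omega=omega)


def _softmax(support: np.ndarray, mask: np.ndarray, T: float) -> np.ndarray:
    """Numerically stable masked softmax; zero outside ``mask``."""
    out = np.zeros_like(support)
    s = support[mask] / T
    s -= s.max()
    e = np.exp(s)
    out[mask] = e / e.sum()
    return out


def evoked_distribution(
    state: ModelState,
    c_cue: np.ndarray,
    excluded: Sequence[int] | np.ndarray,
    T: float,
) -> np.ndarray:
    """Softmax over items of the context-evoked activities ``M_cf c``.

    ``excluded`` items (previously reactivated) get probability exactly zero.
    ``excluded`` may be an index sequence or a boolean mask of length ``n``.
    """
    n = state.items.n
    mask = np.ones(n, dtype=bool)
    excluded = np.asarray(excluded)
    if excluded.dtype == bool:
        mask = ~excluded
    elif excluded.size:
        mask[excluded.astype(int)] = False
    if not mask.any():
        raise RuntimeError("candidate pool exhausted")
    support = state.M_cf[:n, :] @ c_cue
    return _softmax(support, mask, T)


def initial_distribution(
    state: ModelState,
    omega: SuppressionWeights,
    cue: Optional[np.ndarray],
    params: ReplayParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Onset probability over items: noise (+ weighted cue-evoked), suppressed."""
    n = state.items.n
    a = rng.uniform(0.0, params.noise_high, size=n)
    if cue is not None:
        a = a + params.lambda_cue * evoked_distribution(state, cue, np.zeros(n, bool), params.T0)
    a = a * omega.omega
    return a / a.sum()


def _sample(p: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index from probability vector ``p`` using one uniform variate."""
    cdf = np.cumsum(p)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right").clip(0, p.size - 1))


def sample_replay_period(
    state: ModelState,
    omega: SuppressionWeights,
    cue: Optional[np.ndarray],
    params: ReplayParams,
    learn: bool,
    rng: np.random.Generator,
    learn_multipliers: Optional[np.ndarray] = None,
) -> tuple[ReplayTrace, ModelState]:
    """Generate one replay period, optionally learning from it.

    No Hebbian update accompanies the onset reactivation; learning starts with
    the first recursive step.  The stop draw precedes each new sampling
    attempt, so a period may consist of the onset item alone.  Replay learning
    mirrors awake encoding: ``learn_multipliers`` (per-item salience factors,
    1 by default) scale the slow replay rate for salient items.
    """
    n = state.items.n
    a0 = initial_distribution(state, omega, cue, params, rng)
    f0 = _sample(a0, rng)
    items = [f0]
    if not state.items.is_task(f0):
        return ReplayTrace(items=items, terminated_by="nontask_item"), state
    c = retrieve_context(state, f0)
    reactivated = np.zeros(n, dtype=bool)
    reactivated[f0] = True
    terminated = "stop_prob"
    while True:
        if rng.random() < params.stop_prob:
            terminated = "stop_prob"
            break
        if reactivated.all():
            terminated = "exhausted"
            break
        a = evoked_distribution(state, c, reactivated, params.T)
        f = _sample(a, rng)
        items.append(f)
        reactivated[f] = True
        if not state.items.is_task(f):
            terminated = "nontask_item"
            break
        c_f = retrieve_context(state, f)
        c = drift_context(c, c_f, params.beta)
        if learn:
            g = params.gamma_replay
            if learn_multipliers is not None:
                g = g * float(learn_multipliers[f])
            associate(state, f, c, g, g)
    return ReplayTrace(items=items, terminated_by=terminated), state


def run_replay_phase(
    state: ModelState,
    phase: PhaseSpec,
    params: ReplayParams,
    omega: SuppressionWeights,
    rng: np.random.Generator,
    learn_multipliers: Optional[np.ndarray] = None,
) -> tuple[list[ReplayTrace], ModelState]:
    """Run a full phase of replay periods, threading state when learning.

    Suppression weights are computed once from the preceding wake session and
    held fixed for the phase.  Cue contexts are retrieved from the *current*
    state each period, so they track slow replay learning.
    """
    learn = phase.learning
    traces: list[ReplayTrace] = []
    for period in range(phase.n_periods):
        cue_item: Optional[int] = None
        cue_ctx: Optional[np.ndarray] = None
        if phase.cue_items:
            if len(phase.cue_items) == 1:
                cue_item = int(phase.cue_items[0])
            else:
                cue_item = int(phase.cue_items[_sample(
                    np.full(len(phase.cue_items), 1.0 / len(phase.cue_items)), rng)])
            cue_ctx = retrieve_context(state, cue_item)
        trace, state = sample_replay_period(
            state, omega, cue_ctx, params, learn, rng, learn_multipliers
        )
        trace.phase_id = phase.phase_id or phase.mode
        trace.period = period
        trace.cue_item = cue_item
        traces.append(trace)
    return traces, state
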