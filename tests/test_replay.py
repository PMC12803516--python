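"""Replay engine: onset distribution, suppression, sampling, phase running."""

import math

import numpy as np
import pytest

from contextreplay.model import ItemSpace, ModelState, retrieve_context
from contextreplay.replay import (
    PhaseSpec,
    ReplayParams,
    evoked_distribution,
    initial_distribution,
    run_replay_phase,
    sample_replay_period,
    suppression_weights,
)
from conftest import encode_labels

ATOL = 1e-9


@pytest.fixture
def encoded_track():
    """A 6-item track encoded once (one wake session)."""
    space = ItemSpace(n_task=6, n_nontask=3)
    state = ModelState.fresh(space)
    encode_labels(state, list(range(6)))
    return state


# ---------------------------------------------------------------------------
# suppression


def test_suppression_unseen_items_unweighted(encoded_track):
    om = suppression_weights(encoded_track)
    for i in range(6, encoded_track.items.n):
        assert om.omega[i] == pytest.approx(1.0)


def test_suppression_first_session_is_e_minus_one(encoded_track):
    """In an item's first session the retrieved-context norm at encoding time
    is the fresh identity column's norm, exactly 1."""
    om = suppression_weights(encoded_track)
    for i in range(6):
        assert om.omega[i] == pytest.approx(math.exp(-1.0), abs=1e-12)


def test_suppression_strictly_deepens_across_sessions():
    space = ItemSpace(n_task=3, n_nontask=2)
    state = ModelState.fresh(space)
    omegas = []
    for _ in range(4):
        encode_labels(state, [0, 1, 2])
        omegas.append(suppression_weights(state).omega[0])
    assert all(b < a for a, b in zip(omegas, omegas[1:]))


# ---------------------------------------------------------------------------
# evoked distribution


def test_evoked_equal_supports_split_evenly(fresh_state):
    c = np.zeros(fresh_state.items.dim)
    p = evoked_distribution(fresh_state, c, [2], 0.14)
    assert p[0] == pytest.approx(0.5)
    assert p[1] == pytest.approx(0.5)
    assert p[2] == 0.0


def test_evoked_two_candidate_softmax_value(fresh_state):
    """Supports 0.1 vs 0.0 at T=0.14 give p = e^(0.1/0.14)/(e^(0.1/0.14)+1)."""
    fresh_state.M_cf[:] = 0.0
    fresh_state.M_cf[0, 0] = 0.1
    c = np.zeros(fresh_state.items.dim)
    c[0] = 1.0
    p = evoked_distribution(fresh_state, c, [2], 0.14)
    expected = math.exp(0.1 / 0.14) / (math.exp(0.1 / 0.14) + 1.0)
    assert p[0] == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.671348, abs=1e-6)


def test_evoked_sums_to_one_with_zeros_on_excluded(encoded_track, rng):
    c = retrieve_context(encoded_track, 3)
    p = evoked_distribution(encoded_track, c, [0, 3, 7], 0.14)
    assert p.sum() == pytest.approx(1.0, abs=ATOL)
    assert p[0] == 0.0 and p[3] == 0.0 and p[7] == 0.0


def test_evoked_exhaustion_raises(fresh_state):
    with pytest.raises(RuntimeError):
        evoked_distribution(
            fresh_state, np.zeros(fresh_state.items.dim), range(fresh_state.items.n), 0.14
        )


# ---------------------------------------------------------------------------
# onset distribution


def test_initial_distribution_normalized(encoded_track, rng):
    om = suppression_weights(encoded_track)
    a = initial_distribution(encoded_track, om, None, ReplayParams(), rng)
    assert a.sum() == pytest.approx(1.0, abs=ATOL)
    assert np.all(a >= 0)


def test_sleep_onset_uniform_in_expectation(fresh_state, rng):
    om = suppression_weights(fresh_state, [])
    n = fresh_state.items.n
    draws = np.mean(
        [initial_distribution(fresh_state, om, None, ReplayParams(), rng) for _ in range(3000)],
        axis=0,
    )
    assert np.allclose(draws, 1.0 / n, atol=0.01)


def test_cued_rest_onset_biased_to_cued_item(encoded_track, rng):
    """With the final track item's context as cue, that item is the modal
    onset reactivation."""
    om = suppression_weights(encoded_track)
    cue = retrieve_context(encoded_track, 5)
    params = ReplayParams()
    counts = np.zeros(encoded_track.items.n)
    for _ in range(2000):
        a = initial_distribution(encoded_track, om, cue, params, rng)
        counts[np.argmax(a)] += 1
    assert counts.argmax() == 5


# ---------------------------------------------------------------------------
# replay periods


def test_stop_prob_one_gives_single_item_traces(encoded_track, rng):
    om = suppression_weights(encoded_track)
    params = ReplayParams(stop_prob=1.0)
    for _ in range(50):
        trace, _ = sample_replay_period(encoded_track, om, None, params, False, rng)
        assert len(trace.items) == 1


def test_nontask_onset_ends_period_without_learning(encoded_track, rng):
    om = suppression_weights(encoded_track)
    fc = encoded_track.M_fc.copy()
    found = False
    for _ in range(200):
        trace, _ = sample_replay_period(encoded_track, om, None, ReplayParams(), True, rng)
        if trace.terminated_by == "nontask_item" and len(trace.items) == 1:
            found = True
            break
    assert found
    # onset-only non-task periods never updated the matrices at t=0
    trace, _ = sample_replay_period(
        encoded_track, om, None, ReplayParams(stop_prob=1.0), True, rng
    )
    assert np.array_equal(encoded_track.M_fc, fc)


def test_traces_never_repeat_items(encoded_track, rng):
    om = suppression_weights(encoded_track)
    for _ in range(300):
        trace, _ = sample_replay_period(encoded_track, om, None, ReplayParams(), False, rng)
        assert len(set(trace.items)) == len(trace.items)


def test_phase_reproducible_and_test_mode_pure(encoded_track):
    om = suppression_weights(encoded_track)
    phase = PhaseSpec(mode="test", n_periods=40, phase_id="t")
    results = []
    for _ in range(2):
        state = encoded_track.copy()
        rng = np.random.default_rng(777)
        traces, state_after = run_replay_phase(state, phase, ReplayParams(), om, rng)
        results.append([tuple(t.items) for t in traces])
        assert np.array_equal(state_after.M_fc, encoded_track.M_fc)
        assert np.array_equal(state_after.M_cf, encoded_track.M_cf)
    assert results[0] == results[1]


def test_learning_phase_updates_state(encoded_track):
    om = suppression_weights(encoded_track)
    phase = PhaseSpec(mode="sleep", n_periods=200, phase_id="s")
    state = encoded_track.copy()
    _, state = run_replay_phase(state, phase, ReplayParams(), om, np.random.default_rng(3))
    assert state.M_fc.sum() > encoded_track.M_fc.sum()


def test_suppression_monotonicity_of_onset():
    """More repetitions of an item never increase its onset probability."""
    space = ItemSpace(n_task=3, n_nontask=2)
    mean_p = []
    for reps in (1, 3):
        state = ModelState.fresh(space)
        for _ in range(reps):
            encode_labels(state, [0, 1, 2])
        om = suppression_weights(state)
        rng = np.random.default_rng(5)
        a = np.mean(
            [initial_distribution(state, om, None, ReplayParams(), rng) for _ in range(2000)],
            axis=0,
        )
        mean_p.append(a[0])
    assert mean_p[1] < mean_p[0]


def test_phase_rejects_cued_test():
    with pytest.raises(ValueError):
        PhaseSpec(mode="test", n_periods=10, cue_items=(1,))
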