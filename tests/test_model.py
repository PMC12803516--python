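"""Core model: context drift, Hebbian association, encoding-rate schedule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextreplay.model import (
    DegenerateMemoryError,
    DriftParams,
    EncodingEvent,
    EncodingRateSchedule,
    ItemSpace,
    ModelState,
    associate,
    begin_session,
    drift_context,
    effective_rate,
    encode_sequence,
    load_state,
    retrieve_context,
    retrieved_context_norm,
    save_state,
)
from conftest import encode_labels

ATOL = 1e-9


def unit(v):
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# drift


def test_drift_fixed_point_is_exact(rng):
    c = unit(rng.standard_normal(7))
    out = drift_context(c, c, 0.75)
    assert np.allclose(out, c, atol=ATOL)


def test_drift_orthogonal_rho():
    c_prev = np.array([1.0, 0.0])
    c_in = np.array([0.0, 1.0])
    out = drift_context(c_prev, c_in, 0.75)
    assert out[0] == pytest.approx(math.sqrt(1 - 0.75**2), abs=1e-12)
    assert out[1] == pytest.approx(0.75, abs=1e-12)
    assert np.linalg.norm(out) == pytest.approx(1.0, abs=ATOL)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    beta=st.floats(0.05, 1.0),
    dim=st.integers(2, 12),
)
def test_drift_unit_norm_closure(seed, beta, dim):
    """Drifting one unit vector toward another keeps unit length."""
    r = np.random.default_rng(seed)
    c_prev = unit(np.abs(r.standard_normal(dim)))
    c_in = unit(np.abs(r.standard_normal(dim)))
    out = drift_context(c_prev, c_in, beta)
    assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)


def test_drift_from_zero_context_has_norm_beta():
    c_in = np.array([0.0, 1.0, 0.0])
    out = drift_context(np.zeros(3), c_in, 0.75)
    assert np.allclose(out, 0.75 * c_in, atol=ATOL)


# ---------------------------------------------------------------------------
# retrieval and association


def test_retrieve_context_fresh_model_is_one_hot(fresh_state):
    c = retrieve_context(fresh_state, 1)
    expected = np.zeros(fresh_state.items.dim)
    expected[1] = 1.0
    assert np.allclose(c, expected)


def test_retrieve_context_always_unit_norm(fresh_state, rng):
    fresh_state.M_fc += np.abs(rng.standard_normal(fresh_state.M_fc.shape))
    for i in range(fresh_state.items.n):
        assert np.linalg.norm(retrieve_context(fresh_state, i)) == pytest.approx(1.0, abs=ATOL)


def test_retrieve_context_zero_column_raises(fresh_state):
    fresh_state.M_fc[:, 0] = 0.0
    with pytest.raises(DegenerateMemoryError):
        retrieve_context(fresh_state, 0)


def test_associate_unit_outer_product(fresh_state):
    c = np.zeros(fresh_state.items.dim)
    c[2] = 1.0
    before_fc = fresh_state.M_fc.copy()
    associate(fresh_state, 0, c, 1.0, 0.0)
    diff = fresh_state.M_fc - before_fc
    assert diff[2, 0] == pytest.approx(1.0)
    assert np.count_nonzero(diff) == 1


def test_associate_zero_rate_is_noop(fresh_state):
    c = np.ones(fresh_state.items.dim)
    fc, cf = fresh_state.M_fc.copy(), fresh_state.M_cf.copy()
    associate(fresh_state, 1, c, 0.0, 0.0)
    assert np.array_equal(fresh_state.M_fc, fc)
    assert np.array_equal(fresh_state.M_cf, cf)


# ---------------------------------------------------------------------------
# rate schedule


@pytest.mark.parametrize(
    "reward,session,expected",
    [("none", 1, (1.0, 1.0)), ("high", 1, (2.0, 2.0)), ("none", 2, (0.5, 0.5)),
     ("normal", 1, (1.5, 1.5)), ("normal", 3, (0.5, 0.5))],
)
def test_effective_rate(reward, session, expected):
    g = effective_rate(EncodingRateSchedule(), reward, session)
    assert g == pytest.approx(expected)


def test_effective_rate_rejects_bad_session():
    with pytest.raises(ValueError):
        effective_rate(EncodingRateSchedule(), "none", 0)


def test_effective_rate_without_novelty_decay():
    sched = EncodingRateSchedule(novelty_decay=False)
    assert effective_rate(sched, "none", 5) == pytest.approx((1.0, 1.0))


# ---------------------------------------------------------------------------
# hand-computed two-item walkthrough (literal zero-reset drift)


def test_two_item_walkthrough_literal(fresh_state, literal_drift):
    """Encode A then B from scratch and check every touched weight by hand.

    Context resets to zero; the first drift leaves c1 = 0.75 e_A, so
    M_fc[A,A] = 1 + 0.75 and M_cf[A,A] = 0.7 + 0.75.  The second drift mixes
    rho*c1 with 0.75 e_B where rho = sqrt(1 - 0.75^2).
    """
    A, B = 0, 1
    begin_session(fresh_state, [A, B])
    encode_sequence(
        fresh_state,
        [EncodingEvent(item=A), EncodingEvent(item=B)],
        EncodingRateSchedule(),
        literal_drift,
    )
    rho = math.sqrt(1 - 0.75**2)
    cross = rho * 0.75  # A-component of B's encoding context
    assert fresh_state.M_fc[A, A] == pytest.approx(1.75, abs=ATOL)
    assert fresh_state.M_cf[A, A] == pytest.approx(1.45, abs=ATOL)
    assert fresh_state.M_fc[B, B] == pytest.approx(1.75, abs=ATOL)
    assert fresh_state.M_cf[B, B] == pytest.approx(1.45, abs=ATOL)
    assert fresh_state.M_fc[A, B] == pytest.approx(cross, abs=ATOL)
    assert fresh_state.M_cf[B, A] == pytest.approx(cross, abs=ATOL)
    # A's stored context is still collinear with e_A
    cA = retrieve_context(fresh_state, A)
    assert cA[A] == pytest.approx(1.0, abs=ATOL)


def test_single_item_normalized_reset(fresh_state):
    """With the normalization switch, the first context is e_A itself."""
    begin_session(fresh_state, [0])
    encode_sequence(
        fresh_state,
        [EncodingEvent(item=0)],
        EncodingRateSchedule(),
        DriftParams(normalize_first_drift=True),
    )
    assert fresh_state.M_fc[0, 0] == pytest.approx(2.0, abs=ATOL)
    assert fresh_state.M_cf[0, 0] == pytest.approx(1.7, abs=ATOL)


# ---------------------------------------------------------------------------
# invariants over arbitrary encoding


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 5_000), n_task=st.integers(3, 6), length=st.integers(1, 10))
def test_encoding_nonnegative_and_monotone(seed, n_task, length):
    r = np.random.default_rng(seed)
    space = ItemSpace(n_task=n_task, n_nontask=2)
    state = ModelState.fresh(space)
    prev_fc = state.M_fc.copy()
    prev_cf = state.M_cf.copy()
    for _ in range(3):
        items = r.integers(0, n_task, size=length).tolist()
        encode_labels(state, items)
        assert np.all(state.M_fc >= prev_fc - ATOL)
        assert np.all(state.M_cf >= prev_cf - ATOL)
        assert np.all(state.c >= -ATOL)
        prev_fc, prev_cf = state.M_fc.copy(), state.M_cf.copy()


def test_forward_asymmetry_after_single_pass():
    """For each interior item, the encoded state evokes the successor more
    strongly than the predecessor."""
    space = ItemSpace(n_task=5, n_nontask=3)
    state = ModelState.fresh(space)
    encode_labels(state, [0, 1, 2, 3, 4])
    for i in (1, 2, 3):
        cue = retrieve_context(state, i)
        acts = state.M_cf[: space.n, :] @ cue
        assert acts[i + 1] > acts[i - 1]


def test_encoding_is_deterministic():
    space = ItemSpace(n_task=4, n_nontask=2)
    s1, s2 = ModelState.fresh(space), ModelState.fresh(space)
    for s in (s1, s2):
        encode_labels(s, [0, 1, 2, 3])
    assert np.array_equal(s1.M_fc, s2.M_fc)
    assert np.array_equal(s1.M_cf, s2.M_cf)
    assert np.array_equal(s1.c, s2.c)


def test_distractor_drifts_without_learning():
    space = ItemSpace(n_task=2, n_nontask=1, n_distractor=1)
    state = ModelState.fresh(space)
    begin_session(state, [0])
    events = [
        EncodingEvent(item=0),
        EncodingEvent(item=space.n, beta=0.99, is_distractor=True),
    ]
    encode_sequence(state, events, EncodingRateSchedule())
    # distractor column/row untouched
    assert state.M_fc[space.n, space.n] == pytest.approx(1.0)
    assert state.M_cf[space.n, space.n] == pytest.approx(0.7)
    # but context moved onto the distractor unit
    assert state.c[space.n] > 0.9


def test_item_space_default_nontask_ratio():
    for n_task, expected in [(4, 2), (5, 3), (13, 7)]:
        space = ItemSpace.for_task([f"x{i}" for i in range(n_task)])
        assert space.n_nontask == expected
        assert space.n == n_task + expected


def test_state_round_trip(tmp_path, fresh_state):
    encode_labels(fresh_state, [0, 1])
    save_state(fresh_state, str(tmp_path / "state"))
    loaded = load_state(str(tmp_path / "state"))
    assert np.allclose(loaded.M_fc, fresh_state.M_fc)
    assert np.allclose(loaded.M_cf, fresh_state.M_cf)
    assert np.allclose(loaded.c, fresh_state.c)
    assert loaded.items.labels == fresh_state.items.labels
    assert loaded.wake_norms == fresh_state.wake_norms
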