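import numpy as np
import pytest

from contextreplay.model import (
    DriftParams,
    EncodingEvent,
    EncodingRateSchedule,
    ItemSpace,
    ModelState,
    begin_session,
    encode_sequence,
)


@pytest.fixture
def two_item_space():
    return ItemSpace(n_task=2, n_nontask=1)


@pytest.fixture
def fresh_state(two_item_space):
    return ModelState.fresh(two_item_space)


@pytest.fixture
def literal_drift():
    """Drift parameters applying the post-reset recurrence literally."""
    return DriftParams(normalize_first_drift=False)


def encode_labels(state, items, schedule=None, drift=None, new_session=True):
    """Encode a list of item indices as one wake sequence."""
    if schedule is None:
        schedule = EncodingRateSchedule()
    if drift is None:
        drift = DriftParams()
    if new_session:
        begin_session(state, items)
    events = [EncodingEvent(item=i) for i in items]
    return encode_sequence(state, events, schedule, drift)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
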