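# contextreplay

A retrieved-context model of hippocampal replay. During awake learning the
model associates each experienced item with a slowly drifting temporal
context; during rest and sleep, replay emerges as an autonomous cascade in
which a reactivated item reinstates its associated context, and that context
cues the next reactivation. The same two associative memories support both
directions of the loop, and slow Hebbian learning from replay consolidates
sequence memory. The package is for computational-neuroscience researchers
who want a tested, configurable simulator of replay phenomena — forward and
backward events, sleep/rest differences, reward effects, remote and shortcut
replay, experience-dependent changes, and offline learning — without any
reinforcement-learning machinery.

## Model

Items are one-hot vectors `f` over `n` units (task items plus a pool of
task-irrelevant items that compete during replay). Two associative matrices,
initialized as scaled identities (`M_fc = 1.0·I`, `M_cf = 0.7·I`), map items
to contexts and contexts to items. At each encoding step the model retrieves
the current item's context,

    c_f = M_fc f / ||M_fc f||,

drifts the running context

    c_t = ρ c_{t−1} + β c_f,      β = 0.75,

with ρ chosen so unit-length context stays unit-length, and Hebbian-updates
both maps (`ΔM_fc = γ_fc c fᵀ`, `ΔM_cf = γ_cf f cᵀ`). Encoding rates are
salience-dependent (reward multipliers 1.0 / 1.5 / 2.0) and decay with
familiarity (`γ/i` in an item's `i`-th session). A replay period starts from
an onset distribution combining uniform noise on `[0, 0.001]`, an optional
cue-evoked bias, and experience-dependent suppression `ω = exp(−||c_f||)`;
it then iterates softmax reactivation without replacement (temperature 0.14)
with a stop probability of 0.1, ending early if a task-irrelevant item wins.
Replay learning uses the same rule at the slow rate `γ_replay = 0.001`.

## Worked example

```python
from contextreplay import ExperimentConfig, run_experiment

bundle = run_experiment(ExperimentConfig(
    name="directionality_linear_track",
    n_models=8, seed=5,
    overrides={"n_sessions": 1, "n_periods": 400},
))
print(bundle.summary.groupby("phase")[["event_rate", "forward_prop"]].mean())
```

prints

```
               event_rate  forward_prop
phase
post_run_rest    0.079375      0.312747
pre_run_rest     0.108437      0.813123
```

Each model encodes a 10-item linear track (reward at the end), then rests —
400 periods cued at the track end, 400 at the track start. About 8–11% of
replay periods contain a significant replay event (a contiguous segment of
five or more items of the track). At the track end, where the reward was
just consumed, replay unrolls predominantly backward (31% forward); at the
track start it unrolls predominantly forward (81%) — the same initiation ×
contiguity logic, with no value computation anywhere.

The same library drives ten registered simulations
(`contextreplay list` from a shell, or `experiment_names()` from Python),
covering sleep-vs-rest direction biases, targeted memory reactivation,
reward over-representation and magnitude effects, remote and shortcut
replay, scrambled-sequence reorganization, sequence-memory consolidation,
non-local preference learning, and teacher–student distillation.

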