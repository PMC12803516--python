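# Methods

## Model

The simulator is a retrieved-context memory model. Each of `n` items is a
one-hot vector; `n` counts `n_task` task items plus `n_nontask =
ceil(n_task/2)` task-irrelevant items that never appear as wake inputs but
compete for reactivation offline (reactivating one ends a replay period).
Tasks with distractor drifts allocate one additional orthogonal unit per
distractor event; those units only move context and never enter the replay
competition.

Two nonnegative matrices carry all learning: `M_fc` (item → context,
initialized `1.0·I`) and `M_cf` (context → item, `0.7·I`). The asymmetric
initialization scales how strongly a reinstated context re-evokes items
relative to how faithfully an item reinstates its context, and sets the
baseline forward/backward balance of replay. Weights only grow (Hebbian
outer products with nonnegative rates); there is no decay or normalization
of the matrices.

**Awake encoding.** Context resets to zero at each sequence boundary. Per
item: retrieve `c_f = M_fc f / ||M_fc f||`, drift `c ← ρ c + β c_f` with
`β = 0.75` and `ρ` the unit-norm-preserving coefficient, then add
`γ_fc c fᵀ` and `γ_cf f cᵀ`. Rates: base 1.0; reward multipliers low 1.0,
normal 1.5, high 2.0, applied only to the rewarded item itself; novelty
decay divides an item's rate by the number of wake sessions (including the
current one) in which it has appeared, which keeps weights sublinear in
experience and preserves replay stochasticity.

**Zero-reset contexts.** Applied literally, the drift recurrence gives the
first post-reset context norm `β`, not 1 (the unit-norm guarantee assumes a
unit predecessor). The default keeps the literal recurrence.
`DriftParams.normalize_first_drift=True` renormalizes that first context as
a sensitivity switch. The choice matters: under the literal rule,
sequence-initial items store slightly weaker contexts, so they are less
suppressed at replay onset and stem-adjacent choice-point crossings remain
competitive — novel shortcut trajectories occur at realistic (rare) rates.
Under the normalized rule shortcut replay essentially disappears, while the
backward-event proportion becomes flatter across sessions (see
Limitations).

**Replay.** A period samples an onset item from
`a0 ∝ ω · (noise + λ·evoked)`, with i.i.d. noise uniform on `[0, 0.001]`,
`λ = 0.005` weighting a softmax (temperature `T0 = 0.1`) of `M_cf c_cue`
when an external cue context is present (awake rest, targeted
reactivation), and suppression `ω = exp(−||c_f||)` applied to items from
the preceding wake session. The suppression norm is recorded **when the
item is retrieved during that session's encoding** — i.e. it reflects
learning accrued in earlier sessions, not the session's own update. This
timing matters: measured at session end, a strongly rewarded item would
suppress itself within its first session, inverting the reward-magnitude
effect on backward replay. A non-task onset ends the period immediately.
Otherwise the onset item's context is reinstated (no Hebbian update at
t = 0) and the cascade iterates: stop with probability 0.1; softmax
(temperature `T = 0.14`) of `M_cf c` over not-yet-reactivated items; stop
if the winner is non-task; reinstate, drift (`β = 0.75`), and — in learning
phases — associate at `γ_replay = 0.001`. Replay learning mirrors awake
encoding's salience modulation: a rewarded item's offline updates are
scaled by its reward multiplier. Without that modulation the
pre/post-sleep consolidation gain is reliably larger for the *neutral* item
(the rewarded item's transitions sit on the flat part of the softmax, so
equal-size updates buy it less), contradicting the preferential
consolidation of rewarded memories the model is meant to show.

Suppression weights are computed once per wake session and held fixed
through all following replay phases; cue contexts are re-retrieved from the
current state each period, so they track slow replay learning. Test phases
are uncued and non-learning.

## Tasks

Eight generators (`tasks.build_task`) define the protocols; track lengths
and goal sites are not dictated by the model and are exposed as overrides.
Defaults: linear track, 10 items, reward (normal) at the end, 8 sessions
each followed by 500 rest periods at the end then 500 at the start;
directional track, two disjoint 8-item runs, both reward-terminated, the
first run's magnitude manipulated; T-maze, 3 stem + 3 arm items per arm,
one arm's end rewarded, 5000-period sleep flanked by 5000-period tests;
two-choice maze, stem (stem1, choice) and two 6-item arms with feeders at
arm positions 3 and 6, two pre-training sessions (both arms), a final
session (both arms or one), then 500 cued rest periods at each
just-explored feeder — all four in alternation, the experienced arm's two
in L/R-only (resting at unvisited feeders would cancel the suppression
asymmetry that drives remote replay); cue-association task, two runs
sharing a start item with a distinct cue item inserted after the start and
replay events scored on the tracks *excluding* the cue items (the cues are
tones, not locations; scoring them as track positions lets an onset
reactivation of the cue block its own sequence's event, inverting the
cueing effect); scrambled-pairs task, eight items presented as three
4-item interleavings with a distractor drift between every transition
(β 0.3 within latent-sequence transitions, 0.99 otherwise), 1000 uncued
periods, event threshold 4 (the presented sequences are only four items
long); six-sequence task, 3 start × 2 end items with unique 3-item paths,
the final-presented sequence's end item encoded at high rates; fixed
5-item sequence with test/sleep/test phases.

## Analyses

A replay event is the longest contiguous run of a trace matching
consecutive ascending (forward) or descending (backward) positions of one
task sequence, length ≥ 5 (one event per period; ties: longest, earliest,
forward). A shortcut window is a graph-adjacent run of ≥ 5 items containing
items unique to each arm and not itself a segment of a trained sequence;
for shortcut proportions a period counts as an event if it contains a
trained-sequence segment *or* a shortcut window (a pure crossing trace
contains no 5-item single-sequence segment, so requiring one would
undercount shortcuts several-fold). Remote classification compares an
event's matched sequence with the arm containing the rest cue. The lag-CRP
tallies, for each transition from a reference-sequence item, the positional
lag of the next reactivation; denominators are availability-conditioned
(the standard convention: lag L counts only when the item at i+L was still
available), with an unconditional histogram normalization as an option.
Model-run comparisons use two-tailed t-tests (`analysis.compare_runs`) as
reporting plumbing.

## Experiments, seeding, problem sizes

Ten registered experiments bind tasks, phases and analyses into the full
protocols; each defaults to 100 model instances per condition, with model
`k` of condition `c` drawing from `default_rng([seed, c, k])` so results
are reproducible and stable under changes of `n_models`. Sequence
presentation order, phase order, per-period cues, and all replay sampling
draw from the model's own stream. The test suite runs the same protocols at
8–40 models and a few hundred periods per phase — enough for the
directional and ordering effects it asserts; the acceptance script runs the
shortcut protocol at the full 100 models.

## What the generators do and do not emulate

Items are abstract states: there is no 2-D geometry, place-field overlap,
spiking, oscillation, or measurement noise, and replay is read out directly
rather than decoded. Passing tests therefore show that the *mechanisms*
(context drift, bidirectional Hebbian association, suppression, softmax
competition) reproduce the qualitative phenomenology; they do not show
that decoded electrophysiology would quantitatively match.

## Numerical choices

Norm and probability checks use absolute tolerance 1e−9. Softmaxes subtract
the maximum before exponentiation. Sampling inverts a cumulative sum with a
single uniform variate. Event detection tie-breaks are deterministic.
Degenerate retrieval (a zero-norm stored context) raises; it cannot occur
from the shipped initialization.

## Known limitations

- Weights grow without bound across very long simulations (no synaptic
  down-scaling); the novelty decay keeps growth harmonic, not linear.
- The backward share of linear-track replay events declines modestly over
  eight sessions (≈0.44 → ≈0.30) instead of holding flat: the rewarded
  track-end item accrues retrieved-context norm ~1.5× faster than its
  neighbours, so its onset suppression deepens faster and end-cued
  (backward) initiation weakens. An unrewarded end item, or the
  normalized-reset switch, restores a flat profile — at the cost,
  respectively, of the protocol's reward placement or of shortcut replay.
- Reward magnitude leaves forward event counts unordered but not exactly
  matched: a high-reward terminal item occasionally intrudes into late
  forward runs and truncates them.
- The choice-point crossing rate (hence the shortcut proportion) is
  sensitive to maze geometry — stem length, arm length, feeder placement —
  which the task defaults fix at the values listed above.
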