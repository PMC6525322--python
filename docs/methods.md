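# Model and methods

## The model

`plastwm` simulates a small firing-rate network in which working memory is
held jointly in activity and in rapidly plastic synapses.  Two populations
are coupled all-to-all:

- **Feature units** `f` (12 canonical: 3 dimensions — color, orientation,
  location — with 4 values each).  Each unit has a fixed selectivity; units
  on the same dimension compete through subtractive lateral inhibition.
- **Freely conjunctive units** `c` (4 canonical).  They have no fixed
  selectivity: what a conjunctive unit "means" is carried entirely by two
  plastic weight matrices, `W_fc` (feature → conjunctive) and `W_cf`
  (conjunctive → feature), updated continuously by a Hebbian rule.

Rate dynamics (Euler step, one dimensionless time step; τ = 10 steps):

    drive_f = W_cf · c + i_ext − β_f · (Σ same-dimension rates) + ξ
    drive_c = W_fc · f        − β_c · (Σ other conjunctive rates) + ξ
    x ← x + (σ(g·(drive − θ)) − x)/τ,   clipped to [0, 1]

with a logistic nonlinearity σ (gain g = 8, threshold θ = 0.42) and
independent Gaussian drive noise ξ (sd 0.065 per step).  Because σ(−gθ) > 0,
the silent state is a small positive floor (~0.02), not exactly zero; all
"silent" statements in the tests mean "at the floor".

Plasticity (every step, in every epoch — delays and blanks included):

    ΔW_fc[j,i] = η · c_j · f_i      (and symmetrically for W_cf)

followed by renormalizing each **postsynaptic unit's incoming row** to norm
1.  Growth on active synapses therefore mechanically shrinks the others on
the row — the model's only forgetting mechanism; there is no explicit decay
term.  Two refinements gate this rule:

- **Postsynaptic gate** (rate > 0.5 to learn).  Rapid Hebbian plasticity
  requires genuinely coincident firing; without the gate, noise-floor rates
  plus per-step renormalization slowly re-point *silent* units' rows at
  whatever happens to be active, and probes then pattern-complete to
  never-presented features.  With the gate, a silent engram is preserved
  exactly until its unit fires again.
- **Weight floor** (0.12).  Synapses depress only down to a baseline
  connectivity.  Without it, once every row has concentrated onto some
  engram, a novel item finds no unit above the ignition threshold and
  encoding collapses; the floor guarantees any full stimulus can engage the
  competition while a genuine engram match (~0.55) still dominates it.

## Trial structure and attention events

Stimuli are discrete conjunctions (one feature per dimension) presented
strictly sequentially.  A standard trial is: inhibitory reset (30 steps at
drive −2, silencing rates but never weights), per-item stimulus epochs
(60 steps) with 10-step gaps, a delay (200 steps canonical), optional
delay events, a single-feature probe (100 steps) and a readout window
(50 steps, probe input maintained).

Three onset transients shape the competition:

- **Stimulus onset** (25 steps, conjunctive-layer inhibition at drive
  1.05): a new stimulus disrupts ongoing activity, so the conjunctive
  competition restarts on the new feature pattern instead of being held by
  the previous winner.  The drive is deliberately weak — the previous
  winner survives partially and handicaps the new item's encoding, which
  is the model's source of primacy.  The first item after a reset skips
  the transient (there is nothing to disrupt), giving it a clean encoding.
- **Cue/probe onset "quench"** (14 steps at drive −2): an abrupt display
  change interrupts ongoing activity.  It is brief, so the focused item
  retains a residual-rate head start in the retrieval competition — the
  model's source of recency — while a silent item's engram can still win
  ignition through its weights (pattern completion).
- **Readout**: the report is the report-dimension unit with the highest
  mean rate over the last 20 steps of the readout window (none if below
  0.5; "none" is scored incorrect).  The reaction-time proxy is the first
  step after probe onset at which the reported unit reaches threshold.
  A first-threshold-crossing rule over all units would degenerately report
  the focused item on every trial, since its features are already above
  threshold at probe onset.

Weights persist across the trials of a block; blocks are independent
replicates.  Cross-trial engram carry-over is deliberate — the
previous-trial benefit and the trial-lag similarity analyses depend on it,
and proactive interference from earlier trials is part of every
experiment's error statistics.

## Parameters

| name | default | meaning / why |
|---|---|---|
| `tau` | 10 | rate relaxation, steps; sets all transient timescales |
| `gain`, `threshold` | 8, 0.42 | logistic nonlinearity; θ between the floor drive of an unmatched stimulus (~0.34) and a matched engram's drive (~0.52), so ignition is selective |
| `beta_f` | 1.2 | within-dimension competition; strong enough that a driven feature silences its rivals |
| `beta_c` | 1.2 | conjunctive winner-take-all; higher values freeze the handover between items, lower values let runner-up units co-activate |
| `eta` | 0.03 | Hebbian rate; an item concentrates its winner's row within one stimulus epoch but not within the onset-handicap window |
| `hebbian_gate` | 0.5 | coincident-firing requirement (see above) |
| `w_floor` | 0.12 | baseline connectivity (see above) |
| `w_norm` | 1.0 | incoming-row norm; fixes the drive scale |
| `noise_sigma` | 0.065 | drive noise; drives stochastic retrieval, occasional delay-period focus hops (the load-dependent forgetting mechanism), and symmetry breaking |
| `stim_drive` | 1.0 | external input during stimulus/cue/probe epochs |
| `w_init_scale` | 0.03 | initial jitter; breaks ties among fresh units |

Epoch durations are config keys (`stim_steps`, `delay_steps`, …); the
pulse experiments use drive 4.0 with energy varied via duration (weak 10,
strong 25 steps): a uniform input must exceed the within-dimension
inhibition exerted by the focused item (~1.5 on this drive scale) to evoke
any response at all, so the conventional unit-strength pulse is inert here.

All canonical values were fixed by the package's calibration procedure
(`plastwm calibrate`, `plastwm.calibrate.calibrate`): a grid search scored
on the network invariants (selective persistence, winner uniqueness,
activity-silent traces, pattern completion) and the qualitative behavioral
directions (capacity decline, recency, primacy, retro-cue benefit).  The
shipped `canonical.yaml` is the winning cell; the calibration report can be
regenerated at any time.

## What the experiments emulate — and what they do not

The synthetic protocols emulate delayed-report working-memory tasks with
small discrete stimulus sets: sequential encoding, retention, incidental
retro-cues, nonspecific stimulation pulses, single-feature probes, and
stimulus-response rule instructions.  They do not emulate continuous
feature spaces (no mixture-model precision analysis; accuracy is the
probability of reporting the exact target feature, chance 1/4),
simultaneous arrays, verbal material, endogenous attention shifts, or any
mapping from model units to recorded channels.  Passing tests therefore
demonstrate the qualitative mechanism — not quantitative agreement with
any human dataset.

## Numerical choices and degenerate inputs

- Exact argmax ties in readout and winner bookkeeping resolve to the
  lowest index; they are reachable only in noiseless degenerate setups.
- A noiseless network whose initial jitter is near-symmetric can stall the
  encoding competition (no unit crosses the learning gate); this is a
  degenerate tie, observed in roughly one in eight initializations.
  Noiseless invariants are therefore asserted as the typical case over a
  few fixed seeds (majority or median), never tuned per seed.
- Weight rows are renormalized after every update; a floor-clip is applied
  inside the update, so row norms can sit a hair under `w_norm` for rows
  with many floored entries (the floor is "soft").
- Non-finite rates raise immediately, naming the offending step.
- Decoding uses a nearest-class-centroid classifier (deterministic,
  parameter-free) with stratified k-fold cross-validation; a regularized
  logistic option exists behind a flag.  Cross-decoding significance uses
  a 1000-permutation label-shuffle null.  Attended/unattended labels are
  defined by the model's own delay activity (the focused item is the more
  active one), because encoding of the last item fails on a minority of
  trials and position-based labels would mislabel those.

## Known limitations

- Conjunctive delay patterns are nearly winner-one-hot, so trial-lag
  pattern similarity is governed by winner identity.  Winner re-selection
  is strongly content-addressed (a returning stimulus tends to re-recruit
  its previous unit even after intervening items), which makes same-stimulus
  similarity persist over more trials than a freer, history-dominated
  selection would produce; the similarity gap decays steadily but remains
  statistically detectable beyond ten trials under the canonical
  parameters.  The conjunction-violation effect (intervening shared-feature
  items reduce similarity) is present but small for the same reason.
- Serial-position margins (primacy in particular) are modest: the primacy
  handicap and the recency head start trade off through the same onset
  transients, and the calibrated compromise leaves primacy a few points
  above position 2.
- Reaction times are threshold-crossing step counts; no millisecond
  calibration is attempted or implied.
- Delay-period forgetting is weaker than intended: because sub-threshold
  rates do not learn (the coincident-firing gate), unattended engrams are
  frozen during blank delays, and the noise-driven focus hops that do
  occur *refresh* unattended items rather than eroding them.  At load 3
  the attended item's advantage declines with delay while unattended
  accuracy slightly rises, leaving overall accuracy nearly flat — the
  load-by-delay interaction seen in human data does not express under the
  canonical parameters.
- Intrusion errors are dominated by the item currently in the focus of
  attention (and, in whole-sequence recall, by the item probed just
  before), not by serial neighbors: the crisp winner allocation removes
  the adjacent-item encoding overlap that neighbor transpositions would
  require.
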