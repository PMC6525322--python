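# plastwm — a plastic-attractor model of working memory

`plastwm` simulates a small firing-rate network in which visual working
memory is held in two forms at once: the currently attended item as
persistent activity, and recently attended items as *activity-silent*
traces in rapidly plastic synapses.  It is aimed at computational and
cognitive neuroscientists who want a compact, fully reproducible testbed
for attractor-plus-plasticity accounts of the focus of attention, working
memory capacity, and flexible (history-dependent) neural coding.

## The model in brief

Twelve feature-selective rate units **f** (three dimensions — color,
orientation, location — four values each) are reciprocally coupled to four
*freely conjunctive* units **c** through two plastic matrices `W_fc` and
`W_cf`.  Units follow leaky rate dynamics with a logistic nonlinearity and
subtractive lateral inhibition (within dimension for features, all-to-all
for conjunctions):

    τ ẋ = −x + σ( g·(drive − θ) ),        drive_f = W_cf·c + i_ext − β_f·Σf + ξ
                                           drive_c = W_fc·f − β_c·Σc + ξ

Every step, co-active pairs strengthen their synapses (Hebbian outer
product, rate η) and each unit's incoming weight row is renormalized to a
fixed norm — so learning one association erodes the others, which is the
model's only forgetting mechanism.  A stimulus drives one feature per
dimension; the conjunctive unit that wins the competition binds the
features into an object and holds them active (the focus of attention).
A later stimulus displaces that activity but not the synapses; probing any
single stored feature re-ignites the object's conjunction and
pattern-completes the rest — recall from an activity-silent state.

The package implements the full simulated-experiment battery over this
model — set-size capacity curves, serial position, encoding duration,
delay-by-load forgetting, incidental retro-cues, nonspecific excitatory
pulses with neural decoding, attended/unattended cross-decoding
(representational inversion), trial-lag pattern similarity, stimulus-
response task sets (Hick's law), and three ablation variants — plus linear
decoding utilities, a calibration routine, golden-trace fixtures, and a
CLI.  See `docs/methods.md` for the full account of the dynamics,
parameters, and design choices.

## Worked example

```python
from plastwm import canonical_params, exp_set_size, exp_serial_position

params = canonical_params()          # calibrated canonical configuration

tab = exp_set_size(params, n_trials=200, seed=1)
for k in (1, 2, 3, 4):
    print(f"set size {k}: accuracy {tab.mean('correct', set_size=k):.3f}")

sp = exp_serial_position(params, n_trials=200, seed=1)
print([round(sp.mean('correct', position=k), 3) for k in range(4)])
```

prints

```
set size 1: accuracy 0.975
set size 2: accuracy 0.540
set size 3: accuracy 0.380
set size 4: accuracy 0.350
[0.22, 0.13, 0.245, 0.815]
```

Accuracy is the probability of reporting the probed item's exact
orientation (chance 0.25 with four alternatives).  The capacity curve
falls monotonically with the number of stored items because items compete
for conjunctive units and overwrite one another's synapses; the serial
position curve shows the two signatures of the focus of attention —
recency (the last item is still active at probe time) and primacy (the
first item encodes without competition from ongoing activity).

The same battery is available from the shell:

```bash
plastwm run set_size --seed 1 --out runs/
plastwm report runs/
plastwm ablate --seed 1
plastwm calibrate --param eta=0.02,0.03,0.05 --out runs/
```

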