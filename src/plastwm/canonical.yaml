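# Calibrated canonical configuration (see docs/methods.md for rationale).
n_dims: 3
n_feat_per_dim: 4
n_conj: 4
variant: full

tau: 10.0
gain: 8.0
threshold: 0.42
beta_f: 1.2
beta_c: 1.2
noise_sigma: 0.065
eta: 0.03
hebbian_gate: 0.5
w_floor: 0.12
w_init_scale: 0.03
w_norm: 1.0
stim_drive: 1.0
reset_drive: 2.0
readout_threshold: 0.5
onset_quench: true
stim_onset_steps: 25
stim_onset_drive: 1.05
facil_U: 0.2
facil_tau: 150.0
facil_gain: 1.0

stim_steps: 60
gap_steps: 10
delay_steps: 200
cue_steps: 30
pulse_steps: 10
probe_steps: 100
readout_steps: 50
readout_tail: 20
reset_steps: 30
quench_steps: 14
iti_steps: 50
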