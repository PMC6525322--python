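"""Rate dynamics and rapid Hebbian plasticity of the two-population network.

The network couples fixed feature-selective units (``f``, one unit per value
per stimulus dimension) with freely conjunctive units (``c``) through two
plastic weight matrices, ``W_fc`` (feature -> conjunctive) and ``W_cf``
(conjunctive -> feature).  Units are leaky firing-rate units with a logistic
nonlinearity; within-dimension lateral inhibition makes feature values
compete, and lateral inhibition among conjunctive units enforces a
winner-take-all over conjunctions.  Every step, co-active units strengthen
the synapses between them (outer-product Hebbian rule) and each unit's
incoming weight row is renormalized to a fixed norm — so strengthening one
synapse mechanically erodes the others on the same row.  There is no
explicit weight decay.

Three ablation variants are supported alongside the full model:

- ``facilitation_only``: no Hebbian term; a per-presynaptic-unit facilitation
  variable transiently scales outgoing efficacy (not synapse-selective).
- ``no_c_to_f_plasticity``: the conjunctive-to-feature matrix is frozen at
  its initial value.
- ``no_conjunctive_layer``: no conjunctive units; feature units recur through
  a plastic feature-to-feature matrix instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ConfigurationError, ModelParams


class NumericalStabilityError(RuntimeError):
    """Raised when rates become non-finite during integration."""


@dataclass
class NetworkState:
    """Mutable simulation state: rates, plastic weights, facilitation, RNG.

    Weight matrices are stored with the postsynaptic unit on the first axis,
    so each *row* is one unit's incoming weight vector and is kept at norm
    ``w_norm`` by the plasticity rule.  ``W_fc`` and ``W_cf`` are independent
    matrices (never constrained to be transposes).  ``t`` counts steps since
    network initialization and is never reset between trials.
    """

    f: np.ndarray                 # feature rates, (n_features,)
    c: np.ndarray                 # conjunctive rates, (n_conj,)
    W_fc: np.ndarray              # (n_conj, n_features)
    W_cf: np.ndarray              # (n_features, n_conj)
    rng: np.random.Generator
    t: int = 0
    W_ff: np.ndarray | None = None      # (n_features, n_features), ablation only
    u_facil_f: np.ndarray | None = None  # per-feature facilitation variable
    u_facil_c: np.ndarray | None = None  # per-conjunction facilitation variable

    def copy(self) -> "NetworkState":
        """Deep copy, including an independent clone of the RNG state."""
        rng = np.random.Generator(self.rng.bit_generator.__class__())
        rng.bit_generator.state = self.rng.bit_generator.state
        return NetworkState(
            f=self.f.copy(),
            c=self.c.copy(),
            W_fc=self.W_fc.copy(),
            W_cf=self.W_cf.copy(),
            rng=rng,
            t=self.t,
            W_ff=None if self.W_ff is None else self.W_ff.copy(),
            u_facil_f=None if self.u_facil_f is None else self.u_facil_f.copy(),
            u_facil_c=None if self.u_facil_c is None else self.u_facil_c.copy(),
        )


@dataclass
class ActivityTrace:
    """Step-by-step record of rates over an epoch or a trial.

    ``f`` is (n_steps, n_features), ``c`` is (n_steps, n_conj); ``t0`` is the
    global step index of the first row.
    """

    f: np.ndarray
    c: np.ndarray
    t0: int = 0
    epoch_labels: list = field(default_factory=list)  # (kind, start, stop) rows

    @property
    def n_steps(self) -> int:
        return self.f.shape[0]

    @staticmethod
    def concatenate(traces: list["ActivityTrace"]) -> "ActivityTrace":
        labels = []
        for tr in traces:
            labels.extend(tr.epoch_labels)
        return ActivityTrace(
            f=np.vstack([tr.f for tr in traces]),
            c=np.vstack([tr.c for tr in traces]),
            t0=traces[0].t0,
            epoch_labels=labels,
        )

    def to_dataframe(self, run_id: str = "", trial: int = 0):
        """Tidy long-format view: (run_id, trial, step, unit_type, unit_index, rate)."""
        import pandas as pd

        n = self.n_steps
        steps = np.arange(n) + self.t0
        frames = []
        for unit_type, block in (("feature", self.f), ("conjunctive", self.c)):
            k = block.shape[1]
            frames.append(
                pd.DataFrame(
                    {
                        "run_id": run_id,
                        "trial": trial,
                        "step": np.repeat(steps, k),
                        "unit_type": unit_type,
                        "unit_index": np.tile(np.arange(k), n),
                        "rate": block.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _normalize_rows(W: np.ndarray, w_norm: float) -> None:
    """Rescale every row of W to norm ``w_norm`` in place (zero rows are left)."""
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    np.divide(W, norms / w_norm, out=W, where=norms > 0)


def _gated_hebb(W: np.ndarray, post: np.ndarray, pre: np.ndarray, params: ModelParams) -> None:
    """Hebbian outer-product increment with a postsynaptic gate.

    Rapid Hebbian plasticity requires coincident firing: a unit whose rate
    sits at the noise floor does not potentiate its inputs.  Only rows whose
    postsynaptic rate exceeds ``hebbian_gate`` are incremented (by
    ``eta * post * pre``) and renormalized; all other rows are untouched, so
    silent engrams are preserved exactly until their units fire again.
    """
    mask = post > params.hebbian_gate
    if not np.any(mask):
        return
    W[mask] += params.eta * post[mask, None] * pre[None, :]
    sub = W[mask]
    _normalize_rows(sub, params.w_norm)
    if params.w_floor > 0:
        # baseline connectivity: synapses depress only down to a floor, so
        # any full stimulus can still engage the competition
        np.maximum(sub, params.w_floor, out=sub)
        _normalize_rows(sub, params.w_norm)
    W[mask] = sub


def init_network(params: ModelParams, seed: int) -> NetworkState:
    """Build a fresh network state.

    Rates start at zero.  Weights start from a small positive uniform
    baseline plus Gaussian jitter of scale ``w_init_scale`` (the jitter
    breaks ties in the conjunctive competition), then every incoming row is
    normalized to ``w_norm``.  The same ``(params, seed)`` pair always yields
    a bit-identical state.
    """
    if seed < 0:
        raise ConfigurationError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    nf, nc = params.n_features, params.n_conj

    def jittered(shape):
        W = 0.5 + params.w_init_scale * rng.standard_normal(shape)
        np.clip(W, 1e-6, None, out=W)
        _normalize_rows(W, params.w_norm)
        return W

    W_fc = jittered((nc, nf))
    W_cf = jittered((nf, nc))
    state = NetworkState(
        f=np.zeros(nf),
        c=np.zeros(nc),
        W_fc=W_fc,
        W_cf=W_cf,
        rng=rng,
        t=0,
    )
    if params.variant == "no_conjunctive_layer":
        W_ff = jittered((nf, nf))
        np.fill_diagonal(W_ff, 0.0)  # no self-synapses
        _normalize_rows(W_ff, params.w_norm)
        state.W_ff = W_ff
    if params.variant == "facilitation_only":
        state.u_facil_f = np.zeros(nf)
        state.u_facil_c = np.zeros(nc)
    return state


def _effective_weights(state: NetworkState, params: ModelParams):
    """Synaptic efficacies seen by the dynamics (facilitation scales presynaptically)."""
    if params.variant == "facilitation_only":
        g = params.facil_gain
        W_fc = state.W_fc * (1.0 + g * state.u_facil_f)[None, :]
        W_cf = state.W_cf * (1.0 + g * state.u_facil_c)[None, :]
        return W_fc, W_cf
    return state.W_fc, state.W_cf


def step(
    state: NetworkState,
    i_ext: np.ndarray,
    params: ModelParams,
    i_ext_c: np.ndarray | None = None,
) -> NetworkState:
    """One Euler step of the leaky rate dynamics (state is updated in place).

    Feature drive = recurrent excitation + external input − within-dimension
    lateral inhibition + noise; conjunctive drive = feature input − lateral
    inhibition + noise.  Each rate relaxes toward the logistic nonlinearity
    of its drive with time constant ``tau`` and is clipped to [0, 1].
    ``i_ext_c`` optionally drives the conjunctive units directly (used by the
    inter-trial inhibitory reset).
    """
    i_ext = np.asarray(i_ext, dtype=float)
    if i_ext.shape != (params.n_features,):
        raise ValueError(
            f"i_ext has shape {i_ext.shape}, expected ({params.n_features},)"
        )
    if state.f.shape[0] != params.n_features or state.c.shape[0] != params.n_conj:
        raise ValueError("state dimensions do not match params")

    rng = state.rng
    sig = params.noise_sigma
    nd, npd = params.n_dims, params.n_feat_per_dim

    # within-dimension inhibition: each feature is suppressed by the summed
    # rates of the other features on its own dimension
    fd = state.f.reshape(nd, npd)
    inhib_f = (fd.sum(axis=1, keepdims=True) - fd).reshape(-1)

    if params.variant == "no_conjunctive_layer":
        drive_f = state.W_ff @ state.f + i_ext - params.beta_f * inhib_f
        drive_c = None
    else:
        W_fc, W_cf = _effective_weights(state, params)
        drive_f = W_cf @ state.c + i_ext - params.beta_f * inhib_f
        inhib_c = state.c.sum() - state.c
        drive_c = W_fc @ state.f - params.beta_c * inhib_c
        if i_ext_c is not None:
            drive_c = drive_c + i_ext_c
    if sig > 0:
        drive_f = drive_f + sig * rng.standard_normal(state.f.shape)
        if drive_c is not None:
            drive_c = drive_c + sig * rng.standard_normal(state.c.shape)

    gth = params.gain
    target_f = 1.0 / (1.0 + np.exp(-gth * (drive_f - params.threshold)))
    state.f += (target_f - state.f) / params.tau
    np.clip(state.f, 0.0, 1.0, out=state.f)
    if drive_c is not None:
        target_c = 1.0 / (1.0 + np.exp(-gth * (drive_c - params.threshold)))
        state.c += (target_c - state.c) / params.tau
        np.clip(state.c, 0.0, 1.0, out=state.c)

    if params.variant == "facilitation_only":
        U, tau_u = params.facil_U, params.facil_tau
        state.u_facil_f += (1.0 - state.u_facil_f) * U * state.f - state.u_facil_f / tau_u
        state.u_facil_c += (1.0 - state.u_facil_c) * U * state.c - state.u_facil_c / tau_u
        np.clip(state.u_facil_f, 0.0, 1.0, out=state.u_facil_f)
        np.clip(state.u_facil_c, 0.0, 1.0, out=state.u_facil_c)

    state.t += 1
    if not (np.all(np.isfinite(state.f)) and np.all(np.isfinite(state.c))):
        raise NumericalStabilityError(f"non-finite rates at step {state.t}")
    return state


def plasticity_update(state: NetworkState, params: ModelParams) -> NetworkState:
    """Hebbian outer-product update with per-row weight normalization.

    Runs every step, in every epoch (blanks and delays included).  The
    increment is ``eta * post_rate * pre_rate`` on both matrices, after which
    each postsynaptic unit's incoming row is renormalized to ``w_norm`` —
    growth on active synapses therefore shrinks the inactive ones on the same
    row, which is the only mechanism of forgetting (no explicit decay).
    """
    if params.eta < 0:
        raise ConfigurationError("eta must be >= 0")
    eta = params.eta
    if eta == 0 or params.variant == "facilitation_only":
        return state

    if params.variant == "no_conjunctive_layer":
        _gated_hebb(state.W_ff, state.f, state.f, params)
        np.fill_diagonal(state.W_ff, 0.0)
        _normalize_rows(state.W_ff, params.w_norm)
        return state

    _gated_hebb(state.W_fc, state.c, state.f, params)
    if params.variant != "no_c_to_f_plasticity":
        _gated_hebb(state.W_cf, state.f, state.c, params)
    return state


def run_epoch(
    state: NetworkState,
    i_ext: np.ndarray,
    n_steps: int,
    params: ModelParams,
    i_ext_c: np.ndarray | None = None,
    record: bool = True,
    label: str = "",
) -> tuple[NetworkState, ActivityTrace]:
    """Apply ``step`` + ``plasticity_update`` for ``n_steps`` with constant input.

    Returns the state and the visited rates as an :class:`ActivityTrace`
    (rates *after* each step).  Activation and learning run continuously —
    there is no epoch in which plasticity is switched off.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    t0 = state.t
    if record:
        trace_f = np.empty((n_steps, params.n_features))
        trace_c = np.empty((n_steps, params.n_conj))
    for k in range(n_steps):
        step(state, i_ext, params, i_ext_c=i_ext_c)
        plasticity_update(state, params)
        if record:
            trace_f[k] = state.f
            trace_c[k] = state.c
    if not record:
        return state, ActivityTrace(
            f=np.empty((0, params.n_features)), c=np.empty((0, params.n_conj)), t0=t0
        )
    return state, ActivityTrace(
        f=trace_f, c=trace_c, t0=t0,
        epoch_labels=[(label or "epoch", t0, t0 + n_steps)],
    )
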