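import numpy as np
import pytest

from plastwm import (
    StimulusItem,
    build_trial,
    init_network,
    plasticity_update,
    run_epoch,
    run_script,
    step,
)
from plastwm.network import NetworkState


def _state_equal(a: NetworkState, b: NetworkState) -> bool:
    return (
        np.array_equal(a.f, b.f)
        and np.array_equal(a.c, b.c)
        and np.array_equal(a.W_fc, b.W_fc)
        and np.array_equal(a.W_cf, b.W_cf)
    )


class TestInit:
    def test_same_seed_bit_identical(self, params):
        assert _state_equal(init_network(params, 0), init_network(params, 0))

    def test_zero_jitter_gives_identical_rows(self, params):
        st = init_network(params.replace(w_init_scale=0.0), 0)
        assert np.allclose(st.W_fc, st.W_fc[0])

    def test_rows_normalized(self, params):
        st = init_network(params, 3)
        assert np.allclose(np.linalg.norm(st.W_fc, axis=1), params.w_norm)
        assert np.allclose(np.linalg.norm(st.W_cf, axis=1), params.w_norm)

    def test_negative_seed_rejected(self, params):
        from plastwm import ConfigurationError

        with pytest.raises(ConfigurationError):
            init_network(params, -1)


class TestStep:
    def test_silent_state_stays_at_floor(self, quiet_params):
        """With zero weights, input and noise, rates converge to the silent
        floor of the logistic nonlinearity and stay there (no spontaneous
        activity growth)."""
        p = quiet_params
        floor = 1.0 / (1.0 + np.exp(p.gain * p.threshold))
        st = init_network(p, 0)
        st.W_fc[:] = 0.0
        st.W_cf[:] = 0.0
        for _ in range(200):
            step(st, np.zeros(p.n_features), p)
        # lateral inhibition pushes the self-consistent floor slightly below
        # the bare logistic floor
        assert np.all(st.f <= floor + 1e-9)
        assert np.all(st.c <= floor + 1e-9)
        assert st.f.std() < 1e-6  # uniform: no unit spontaneously wins

    def test_shape_mismatch_raises(self, params):
        st = init_network(params, 0)
        with pytest.raises(ValueError):
            step(st, np.zeros(params.n_features + 1), params)

    def test_equal_drive_competition_resolved_by_jitter(self, quiet_params):
        """Two conjunctive units given identical feature drive: lateral
        inhibition plus the initial weight jitter produce a single winner."""
        p = quiet_params
        st = init_network(p, 5)
        i_ext = np.zeros(p.n_features)
        i_ext[[0, p.n_feat_per_dim, 2 * p.n_feat_per_dim]] = p.stim_drive
        for _ in range(100):
            step(st, i_ext, p)
        top, second = np.sort(st.c)[-2:][::-1]
        assert top > second

    def test_boundedness_under_random_input(self, params):
        """Rates stay in [0,1] and row norms at w_norm over a long random-
        input run (the spec-level safety property of the dynamics)."""
        p = params
        st = init_network(p, 1)
        rng = np.random.default_rng(7)
        for k in range(20_000):
            if k % 50 == 0:
                i_ext = rng.uniform(-2.0, 2.0, size=p.n_features)
            step(st, i_ext, p)
            plasticity_update(st, p)
        assert st.f.min() >= 0.0 and st.f.max() <= 1.0
        assert st.c.min() >= 0.0 and st.c.max() <= 1.0
        assert np.linalg.norm(st.W_fc, axis=1).max() <= p.w_norm + 1e-9
        assert np.linalg.norm(st.W_cf, axis=1).max() <= p.w_norm + 1e-9


class TestPlasticity:
    def test_silent_network_weights_unchanged(self, params):
        st = init_network(params, 0)
        W0 = st.W_fc.copy()
        plasticity_update(st, params)
        assert np.array_equal(st.W_fc, W0)

    def test_coactive_pair_potentiates_and_erodes_row(self, params):
        """Driving one feature-conjunction pair makes that synapse the row
        maximum while the rest of the row shrinks below baseline — the
        normalization-driven erosion mechanism."""
        st = init_network(params, 0)
        base_fc = st.W_fc.copy()
        st.f[:] = 0.0
        st.c[:] = 0.0
        st.f[0] = 1.0
        st.c[0] = 1.0
        for _ in range(100):
            plasticity_update(st, params)
        row = st.W_fc[0]
        assert row[0] == row.max()
        assert np.all(row[1:] < base_fc[0, 1:])
        col_row = st.W_cf[0]
        assert col_row[0] == col_row.max()

    def test_matrices_not_constrained_to_transposes(self, params):
        st = init_network(params, 0)
        st.f[:] = 0
        st.c[:] = 0
        st.f[[0, 4, 8]] = 1.0
        st.c[1] = 1.0
        for _ in range(50):
            plasticity_update(st, params)
        assert not np.allclose(st.W_fc, st.W_cf.T)

    def test_gate_blocks_learning_at_noise_floor(self, params):
        st = init_network(params, 0)
        st.f[:] = 1.0
        st.c[:] = params.hebbian_gate / 2
        W0 = st.W_fc.copy()
        plasticity_update(st, params)
        assert np.array_equal(st.W_fc, W0)


class TestVariants:
    def test_facilitation_boost_is_presynaptic_not_synapse_specific(self, params):
        """In the facilitation-only variant the efficacy boost from an
        active presynaptic unit is the same toward every postsynaptic
        target."""
        from plastwm.network import _effective_weights

        p = params.replace(variant="facilitation_only")
        st = init_network(p, 0)
        st.u_facil_f[0] = 0.8
        W_fc, _ = _effective_weights(st, p)
        ratio = W_fc[:, 0] / st.W_fc[:, 0]
        assert np.allclose(ratio, ratio[0])
        assert ratio[0] > 1.0

    def test_facilitation_variant_skips_hebbian(self, params):
        p = params.replace(variant="facilitation_only")
        st = init_network(p, 0)
        st.f[:] = 1.0
        st.c[:] = 1.0
        W0 = st.W_fc.copy()
        plasticity_update(st, p)
        assert np.array_equal(st.W_fc, W0)

    def test_frozen_feedback_variant_keeps_W_cf(self, params):
        p = params.replace(variant="no_c_to_f_plasticity")
        st = init_network(p, 0)
        W_cf0 = st.W_cf.copy()
        st.f[:] = 1.0
        st.c[:] = 1.0
        plasticity_update(st, p)
        assert np.array_equal(st.W_cf, W_cf0)
        assert not np.array_equal(
            st.W_fc, init_network(p, 0).W_fc
        )  # feedforward side still learns

    def test_no_conjunctive_layer_has_feature_recurrence(self, params):
        p = params.replace(variant="no_conjunctive_layer")
        st = init_network(p, 0)
        assert st.W_ff is not None
        assert np.all(np.diag(st.W_ff) == 0.0)
        st.f[:] = 0
        st.f[[0, 4, 8]] = 1.0
        plasticity_update(st, p)
        assert np.all(np.diag(st.W_ff) == 0.0)
        assert st.W_ff[0, 4] > st.W_ff[0, 1]


class TestRunEpoch:
    def test_single_step_trace(self, params):
        st = init_network(params, 0)
        st, tr = run_epoch(st, np.zeros(params.n_features), 1, params)
        assert tr.n_steps == 1

    def test_epoch_requires_positive_length(self, params):
        st = init_network(params, 0)
        with pytest.raises(ValueError):
            run_epoch(st, np.zeros(params.n_features), 0, params)

    def test_identical_seeds_identical_traces(self, params):
        out = []
        for _ in range(2):
            st = init_network(params, 11)
            st, tr = run_epoch(st, np.zeros(params.n_features), 50, params)
            out.append(tr)
        assert np.array_equal(out[0].f, out[1].f)
        assert np.array_equal(out[0].c, out[1].c)


class TestAttractor:
    def test_persistent_activity_after_single_item(self, quiet_params):
        """Encoded features stay above 0.5 and all others below 0.2 for a
        500-step blank delay: the stored attractor."""
        p = quiet_params
        st = init_network(p, 0)
        item = StimulusItem((0, 1, 2))
        script = build_trial([item], p, probe_item=0, delay_steps=500)
        st, trace = run_script(st, script, p)
        t0 = p.reset_steps + p.stim_steps + p.gap_steps
        on = [p.feature_index(d, f) for d, f in enumerate(item.features)]
        off = [i for i in range(p.n_features) if i not in on]
        delay = trace.f[t0:t0 + 500]
        assert delay[:, on].mean() > 0.5
        assert delay[:, off].mean() < 0.2

    def test_silent_trace_survives_second_item(self, quiet_params):
        """After a second item takes the focus, the first item's features
        are quiet yet its winner's weight row still peaks on them."""
        p = quiet_params
        items = [StimulusItem((0, 1, 2)), StimulusItem((1, 2, 3))]
        st = init_network(p, 0)
        script = build_trial(items, p, probe_item=0)
        st, trace = run_script(st, script, p)
        enc1 = trace.c[p.reset_steps + p.stim_steps // 2: p.reset_steps + p.stim_steps]
        w1 = int(np.argmax(enc1.mean(axis=0)))
        probe_at = script.probe_onset() - p.quench_steps
        on = [p.feature_index(d, f) for d, f in enumerate(items[0].features)]
        assert trace.f[probe_at - 100:probe_at, on].mean() < 0.2
        assert set(np.argsort(st.W_fc[w1])[-3:]) == set(on)
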