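import numpy as np
import pytest

from plastwm import (
    ConfigurationError,
    StimulusItem,
    TrialScript,
    build_rule_trial,
    build_trial,
    encode_input,
    init_network,
    make_items,
    run_script,
    run_trial,
)


class TestMakeItems:
    def test_four_unique_items_use_all_feature_values(self, params, rng):
        items = make_items(4, rng, params)
        for d in range(params.n_dims):
            assert sorted(it.features[d] for it in items) == [0, 1, 2, 3]

    def test_five_unique_items_infeasible(self, params, rng):
        with pytest.raises(ConfigurationError):
            make_items(5, rng, params)

    def test_shared_feature_mode_shares_exactly_one_dimension(self, params, rng):
        for _ in range(20):
            a, b = make_items(2, rng, params, shared_feature=True)[:2]
            shared = sum(x == y for x, y in zip(a.features, b.features))
            assert shared == 1


class TestEncodeInput:
    def test_one_unit_per_dimension(self, params):
        vec = encode_input(StimulusItem((0, 0, 0)), params)
        assert list(np.nonzero(vec)[0]) == [0, 4, 8]
        assert np.count_nonzero(vec) == params.n_dims
        assert vec.max() == params.stim_drive

    def test_out_of_range_feature_rejected(self, params):
        with pytest.raises(ConfigurationError):
            encode_input(StimulusItem((0, 4, 0)), params)


class TestBuildTrial:
    def test_epoch_sequence_and_duration(self, params):
        items = [StimulusItem((0, 1, 2)), StimulusItem((1, 2, 3))]
        sc = build_trial(items, params, probe_item=0)
        kinds = [e.kind for e in sc.epochs]
        assert kinds[0] == "reset"
        assert kinds.count("probe") == 1
        assert "stimulus" in kinds and "readout" in kinds
        assert sc.total_steps == sum(e.duration for e in sc.epochs)
        assert sc.target_item == 0

    def test_pulse_epoch_is_uniform_input(self, params):
        sc = build_trial([StimulusItem((0, 1, 2))], params, probe_item=0,
                         pulse=(1.0, 12, 50), delay_steps=200)
        pulse = [e for e in sc.epochs if e.kind == "pulse"]
        assert len(pulse) == 1
        assert pulse[0].duration == 12
        assert np.all(pulse[0].i_ext == 1.0)

    def test_retrocue_drives_single_cued_feature(self, params):
        items = [StimulusItem((2, 1, 0)), StimulusItem((3, 0, 1))]
        sc = build_trial(items, params, probe_item=1, retrocue=(0, 0),
                         delay_steps=300, cue_time=100)
        cue = [e for e in sc.epochs if e.kind == "cue"][0]
        expected = np.zeros(params.n_features)
        expected[params.feature_index(0, 2)] = params.stim_drive
        assert np.array_equal(cue.i_ext, expected)

    def test_probe_must_belong_to_an_item(self, params):
        items = [StimulusItem((0, 1, 2))]
        with pytest.raises(ConfigurationError):
            build_trial(items, params, probe=(0, 3))

    def test_events_outside_delay_rejected(self, params):
        items = [StimulusItem((0, 1, 2))]
        with pytest.raises(ConfigurationError):
            build_trial(items, params, probe_item=0, delay_steps=100,
                        pulse=(1.0, 10, 95))
        with pytest.raises(ConfigurationError):
            build_trial(items, params, probe_item=0, delay_steps=100,
                        retrocue=(0, 0), cue_time=90)

    def test_script_json_roundtrip(self, params):
        items = [StimulusItem((0, 1, 2)), StimulusItem((1, 2, 3))]
        sc = build_trial(items, params, probe_item=1, retrocue=(0, 1),
                         delay_steps=300, cue_time=50)
        sc2 = TrialScript.from_json(sc.to_json())
        assert sc2.total_steps == sc.total_steps
        assert [e.kind for e in sc2.epochs] == [e.kind for e in sc.epochs]
        assert all(np.array_equal(a.i_ext, b.i_ext)
                   for a, b in zip(sc.epochs, sc2.epochs))


class TestRunTrial:
    def test_trace_length_matches_script(self, params):
        sc = build_trial([StimulusItem((0, 1, 2))], params, probe_item=0)
        st = init_network(params, 0)
        st, res = run_trial(st, sc, params)
        assert res.trace.n_steps == sc.total_steps

    def test_single_item_noiseless_recall(self, quiet_params):
        """Pattern completion: probing the item's color re-activates its
        orientation."""
        item = StimulusItem((0, 1, 2))
        st = init_network(quiet_params, 0)
        st, res = run_trial(st, build_trial([item], quiet_params, probe_item=0),
                            quiet_params)
        assert res.correct
        assert res.reported_feature == item.features[1]
        assert res.rt_steps >= 1

    def test_unstudied_probe_on_fresh_weights_reports_nothing(self, quiet_params):
        """With no stored association, a probe cannot pattern-complete."""
        p = quiet_params
        st = init_network(p, 0)
        items = [StimulusItem((3, 3, 3))]
        sc = build_trial(items, p, probe_item=0, stim_steps=0)
        st, res = run_trial(st, sc, p)
        assert res.reported_feature is None
        assert not res.correct

    def test_probe_free_script_has_no_report(self, params):
        sc = build_trial([StimulusItem((0, 1, 2))], params, probe_item=0)
        sc.epochs = [e for e in sc.epochs if e.kind not in ("quench", "probe", "readout")]
        sc.probe_dimension = None
        st = init_network(params, 0)
        st, trace = run_script(st, sc, params)
        from plastwm.protocols import read_report

        reported, rt = read_report(sc, trace, params)
        assert reported is None and rt is None

    def test_deterministic_given_seed(self, params):
        results = []
        for _ in range(2):
            st = init_network(params, 9)
            rng = np.random.default_rng(9)
            items = make_items(2, rng, params)
            st, res = run_trial(st, build_trial(items, params, probe_item=0), params)
            results.append(res)
        assert results[0].reported_feature == results[1].reported_feature
        assert results[0].rt_steps == results[1].rt_steps
        assert np.array_equal(results[0].trace.f, results[1].trace.f)


class TestRuleTrials:
    def test_rule_script_structure(self, params):
        sc = build_rule_trial([(0, 1), (2, 3)], 0, params)
        kinds = [e.kind for e in sc.epochs]
        assert kinds.count("reset") == 2          # one per rule instruction
        assert kinds.count("probe") == 1
        assert sc.report_dimension == params.n_dims - 1

    def test_single_rule_pattern_completes_to_response(self, quiet_params):
        st = init_network(quiet_params, 0)
        st, res = run_trial(st, build_rule_trial([(0, 1)], 0, quiet_params),
                            quiet_params)
        assert res.correct
        assert res.reported_feature == 1

    def test_generalization_probe_flagged(self, params):
        sc = build_rule_trial([(0, 1)], 3, params)
        assert sc.generalization_probe
        assert sc.target_item is None
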