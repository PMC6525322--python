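"""Simulated behavioral and neural-decoding experiments.

Every experiment is a parameterized, seeded protocol that runs blocks of
trials (weights persist across the trials of a block; blocks are
independent replicates with fresh networks) and emits an
:class:`ExperimentTable` of long-format measurement rows.  Aggregation is
always a derived view over the raw rows, never stored in their place.

Covered: set-size capacity curves, serial position (with transposition
tallies), encoding-duration curves, delay-by-load decay, incidental
retro-cueing, nonspecific excitatory pulses (with decoding), task sets
(Hick's law, response repetition, rule decodability), trial-lag pattern
similarity and conjunction violations, previous-trial feature-combination
benefit, ablation contracts, and a generic parameter sweep.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .analysis import DecodeDataset, cross_decode, pattern_similarity, train_linear_decoder
from .network import init_network
from .params import ConfigurationError, ModelParams
from .protocols import (
    StimulusItem,
    build_rule_trial,
    build_trial,
    build_whole_report_trial,
    make_items,
    run_script,
    run_trial,
    score_whole_report,
    shuffle_weights,
)

DEFAULT_BLOCK_LEN = 10


class ExperimentTable:
    """Long-format condition-by-measurement results of one experiment.

    Rows carry (experiment, block, trial, seed, condition fields,
    measurement, value); every row is traceable to its block seed and the
    configuration hash.
    """

    def __init__(self, experiment: str, params: ModelParams, seed: int):
        self.experiment = experiment
        self.params = params
        self.seed = int(seed)
        self.config_hash = params.config_hash()
        self._rows: list = []

    def add(self, block: int, trial, block_seed: int, measurement: str, value,
            **conditions) -> None:
        row = {
            "experiment": self.experiment,
            "block": int(block),
            "trial": -1 if trial is None else int(trial),
            "seed": int(block_seed),
            "measurement": measurement,
            "value": value,
        }
        row.update(conditions)
        self._rows.append(row)

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows)

    def values(self, measurement: str, **conditions) -> np.ndarray:
        """Raw values of one measurement under the given condition filter."""
        df = self.df
        mask = df["measurement"] == measurement
        for key, val in conditions.items():
            mask &= df[key] == val
        return df.loc[mask, "value"].to_numpy(dtype=float)

    def mean(self, measurement: str, **conditions) -> float:
        vals = self.values(measurement, **conditions)
        return float(np.mean(vals)) if len(vals) else float("nan")

    def to_csv(self, path) -> None:
        df = self.df.copy()
        df.insert(0, "config_hash", self.config_hash)
        df.insert(0, "run_seed", self.seed)
        df.to_csv(path, index=False)


def child_seeds(seed: int, n: int) -> list:
    """Counter-based child seeds: block k is reproducible in isolation."""
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _report_owner(items, reported, report_dim: int = 1):
    """Index of the presented item whose report-dimension feature was
    reported, or None (never-presented feature / no report)."""
    if reported is None:
        return None
    for i, it in enumerate(items):
        if it.features[report_dim] == reported:
            return i
    return None


# ---------------------------------------------------------------------------
# core behavioral experiments


def exp_set_size(
    params: ModelParams,
    n_trials: int = 200,
    set_sizes=(1, 2, 3, 4),
    seed: int = 0,
    block_len: int = DEFAULT_BLOCK_LEN,
    shuffled_weights: bool = False,
) -> ExperimentTable:
    """Recall accuracy as a function of the number of encoded items.

    ``shuffled_weights=True`` runs the chance control: every incoming weight
    row is randomly permuted just before the probe, destroying all stimulus
    information while preserving row norms.
    """
    if max(set_sizes) > params.n_feat_per_dim:
        raise ConfigurationError("set size exceeds features per dimension")
    tab = ExperimentTable("set_size", params, seed)
    n_blocks = max(1, int(np.ceil(n_trials / block_len)))
    for set_size in set_sizes:
        seeds = child_seeds(seed + 7919 * set_size, n_blocks)
        done = 0
        for b, bs in enumerate(seeds):
            if done >= n_trials:
                break
            state = init_network(params, bs)
            rng = np.random.default_rng(bs + 1)
            for t in range(min(block_len, n_trials - done)):
                items = make_items(set_size, rng, params)
                pos = int(rng.integers(set_size))
                script = build_trial(items, params, probe_item=pos)
                if shuffled_weights:
                    # run encoding+delay, then scramble the weights and probe
                    state, _ = run_trial(state, script, params)
                    shuffle_weights(state, rng)
                    probe_only = build_trial(items, params, probe_item=pos,
                                             stim_steps=0, delay_steps=0)
                    state, res = run_trial(state, probe_only, params)
                else:
                    state, res = run_trial(state, script, params)
                tab.add(b, done, bs, "correct", int(res.correct),
                        set_size=set_size, position=pos)
                tab.add(b, done, bs, "reported",
                        -1 if res.reported_feature is None else res.reported_feature,
                        set_size=set_size, position=pos)
                done += 1
    return tab


def exp_serial_position(
    params: ModelParams,
    n_trials: int = 200,
    set_size: int = 4,
    seed: int = 0,
    block_len: int = DEFAULT_BLOCK_LEN,
) -> ExperimentTable:
    """Accuracy by probed serial position, with transposition tallies.

    ``n_trials`` counts trials per position.  Each trial additionally
    records which presented item's report feature was produced, so
    transposition errors (reporting a neighbor's feature) can be compared
    with distant-item errors.
    """
    tab = ExperimentTable("serial_position", params, seed)
    total = n_trials * set_size
    n_blocks = max(1, int(np.ceil(total / block_len)))
    seeds = child_seeds(seed, n_blocks)
    done = 0
    for b, bs in enumerate(seeds):
        if done >= total:
            break
        state = init_network(params, bs)
        rng = np.random.default_rng(bs + 1)
        for t in range(min(block_len, total - done)):
            items = make_items(set_size, rng, params)
            pos = done % set_size
            state, res = run_trial(state, build_trial(items, params, probe_item=pos), params)
            owner = _report_owner(items, res.reported_feature)
            tab.add(b, done, bs, "correct", int(res.correct), position=pos)
            tab.add(b, done, bs, "report_owner", -1 if owner is None else owner,
                    position=pos)
            if owner is not None and owner != pos:
                tab.add(b, done, bs, "intrusion_distance", abs(owner - pos), position=pos)
            done += 1

    # whole-sequence recall (successive in-order probes) for the
    # transposition analysis: confusions between serial neighbors
    n_wr = max(1, n_trials // 2)
    n_blocks = max(1, int(np.ceil(n_wr / block_len)))
    seeds = child_seeds(seed + 777, n_blocks)
    done = 0
    for b, bs in enumerate(seeds):
        if done >= n_wr:
            break
        state = init_network(params, bs)
        rng = np.random.default_rng(bs + 1)
        for t in range(min(block_len, n_wr - done)):
            items = make_items(set_size, rng, params)
            script, windows = build_whole_report_trial(items, params)
            state, trace = run_script(state, script, params)
            for row in score_whole_report(script, windows, trace, params):
                tab.add(b, done, bs, "wr_correct", int(row["correct"]),
                        position=row["position"])
                owner = row["owner"]
                if owner is not None and owner != row["position"]:
                    tab.add(b, done, bs, "wr_intrusion_distance",
                            abs(owner - row["position"]), position=row["position"])
            done += 1
    return tab


def exp_encoding_duration(
    params: ModelParams,
    stim_grid=(0, 15, 30, 60, 120),
    set_sizes=(1, 3),
    n_trials: int = 100,
    seed: int = 0,
    block_len: int = DEFAULT_BLOCK_LEN,
) -> ExperimentTable:
    """Accuracy versus stimulus presentation duration, per set size."""
    tab = ExperimentTable("encoding_duration", params, seed)
    n_blocks = max(1, int(np.ceil(n_trials / block_len)))
    for set_size, stim in itertools.product(set_sizes, stim_grid):
        seeds = child_seeds(seed + 104729 * set_size + 31 * stim, n_blocks)
        done = 0
        for b, bs in enumerate(seeds):
            if done >= n_trials:
                break
            state = init_network(params, bs)
            rng = np.random.default_rng(bs + 1)
            for t in range(min(block_len, n_trials - done)):
                items = make_items(set_size, rng, params)
                pos = int(rng.integers(set_size))
                script = build_trial(items, params, probe_item=pos, stim_steps=stim)
                state, res = run_trial(state, script, params)
                tab.add(b, done, bs, "correct", int(res.correct),
                        set_size=set_size, stim_steps=stim, position=pos)
                done += 1
    return tab


def exp_delay_decay(
    params: ModelParams,
    delay_grid=(100, 600, 1200),
    set_sizes=(1, 3),
    n_trials: int = 150,
    seed: int = 0,
    block_len: int = DEFAULT_BLOCK_LEN,
) -> ExperimentTable:
    """Accuracy versus delay length, per set size and probed position."""
    tab = ExperimentTable("delay_decay", params, seed)
    n_blocks = max(1, int(np.ceil(n_trials / block_len)))
    for set_size, delay in itertools.product(set_sizes, delay_grid):
        seeds = child_seeds(seed + 15485863 * set_size + delay, n_blocks)
        done = 0
        for b, bs in enumerate(seeds):
            if done >= n_trials:
                break
            state = init_network(params, bs)
            rng = np.random.default_rng(bs + 1)
            for t in range(min(block_len, n_trials - done)):
                items = make_items(set_size, rng, params)
                pos = int(rng.integers(set_size))
                script = build_trial(items, params, probe_item=pos, delay_steps=delay)
                state, res = run_trial(state, script, params)
                tab.add(b, done, bs, "correct", int(res.correct),
                        set_size=set_size, delay=delay, position=pos,
                        attended=int(pos == set_size - 1))
                done += 1
    return tab


def exp_retrocue(
    params: ModelParams,
    n_trials: int = 200,
    seed: int = 0,
    delay_steps: int = 300,
    cue_time: int = 100,
    block_len: int = DEFAULT_BLOCK_LEN,
) -> ExperimentTable:
    """Two-item trials with a mid-delay incidental single-feature cue.

    Conditions: cue item 1 or item 2 (the cue drives the item's color
    feature), probe congruent (the cued item) or incongruent (the other
    item); plus no-cue controls.  Also records the post-cue shift of delay
    activity toward the cued item's features (mean cued-minus-uncued
    feature rate).
    """
    tab = ExperimentTable("retrocue", params, seed)
    conds = [("cue", 0, True), ("cue", 0, False), ("cue", 1, True), ("cue", 1, False),
             ("nocue", 0, None), ("nocue", 1, None)]
    n_blocks = max(1, int(np.ceil(n_trials * len(conds) / block_len)))
    seeds = child_seeds(seed, n_blocks)
    done = 0
    total = n_trials * len(conds)
    ci = 0
    for b, bs in enumerate(seeds):
        if done >= total:
            break
        state = init_network(params, bs)
        rng = np.random.default_rng(bs + 1)
        for t in range(min(block_len, total - done)):
            kind, target, congruent = conds[ci % len(conds)]
            ci += 1
            items = make_items(2, rng, params)
            if kind == "nocue":
                script = build_trial(items, params, probe_item=target,
                                     delay_steps=delay_steps)
            else:
                probe_item = target if congruent else 1 - target
                script = build_trial(items, params, probe_item=probe_item,
                                     delay_steps=delay_steps,
                                     retrocue=(target, 0), cue_time=cue_time)
            state, res = run_trial(state, script, params)
            cond = dict(condition=kind, cued=target if kind == "cue" else -1,
                        congruent=-1 if congruent is None else int(congruent))
            tab.add(b, done, bs, "correct", int(res.correct), **cond)
            if kind == "cue":
                # post-cue window: delay activity should sit on the cued item
                onset = script.probe_onset() - params.quench_steps
                w0 = onset - (delay_steps - cue_time - params.quench_steps
                              - params.cue_steps) + 20
                win = res.trace.f[w0:onset]
                icued = [params.feature_index(d, f)
                         for d, f in enumerate(items[target].features)]
                iunc = [params.feature_index(d, f)
                        for d, f in enumerate(items[1 - target].features)]
                tab.add(b, done, bs, "cued_shift",
                        float(win[:, icued].mean() - win[:, iunc].mean()), **cond)
            done += 1
    return tab


def exp_pulse(
    params: ModelParams,
    n_trials: int = 150,
    seed: int = 0,
    pulse_strength: float = 4.0,
    weak_steps: int = 10,
    strong_steps: int = 25,
    delay_steps: int = 300,
    pulse_time: int = 150,
    block_len: int = DEFAULT_BLOCK_LEN,
) -> ExperimentTable:
    """Nonspecific excitatory pulse to all feature units during the delay.

    Behavioral accuracy by probed item and pulse condition (none, weak,
    strong: same drive, longer duration carries more energy), plus linear
    decoding of the unattended item's orientation from feature rates in
    matched pre- and post-pulse windows of weak-pulse trials.
    """
    tab = ExperimentTable("pulse", params, seed)
    conds = [("none", 0), ("weak", weak_steps), ("strong", strong_steps)]
    n_blocks = max(1, int(np.ceil(n_trials / block_len)))
    X_pre, X_post, y_lab = [], [], []
    t0 = params.reset_steps + 2 * (params.stim_steps + params.gap_steps)
    for (cname, dur), probe_item in itertools.product(conds, (0, 1)):
        seeds = child_seeds(seed + 131 * dur + probe_item, n_blocks)
        done = 0
        for b, bs in enumerate(seeds):
            if done >= n_trials:
                break
            state = init_network(params, bs)
            rng = np.random.default_rng(bs + 1)
            for t in range(min(block_len, n_trials - done)):
                items = make_items(2, rng, params)
                kw = dict(probe_item=probe_item, delay_steps=delay_steps)
                if dur > 0:
                    kw["pulse"] = (pulse_strength, dur, pulse_time)
                state, res = run_trial(state, build_trial(items, params, **kw), params)
                tab.add(b, done, bs, "correct", int(res.correct),
                        condition=cname, probed=probe_item)
                if cname == "weak" and probe_item == 0:
                    X_pre.append(res.trace.f[t0 + pulse_time - 60:t0 + pulse_time].mean(0))
                    X_post.append(res.trace.f[t0 + pulse_time + dur:
                                              t0 + pulse_time + dur + 60].mean(0))
                    y_lab.append(items[0].features[1])
                done += 1
    for name, X in (("pre", X_pre), ("post", X_post)):
        _, rep = train_linear_decoder(DecodeDataset(np.asarray(X), np.asarray(y_lab),
                                                    unit_subset="feature"),
                                      seed=seed)
        tab.add(-1, None, seed, f"decode_unattended_{name}", rep.accuracy,
                condition="weak", probed=0)
    return tab


def exp_task_set(
    params: ModelParams,
    n_rules_grid=(2, 3, 4),
    n_blocks: int = 25,
    n_test_trials: int = 8,
    seed: int = 0,
) -> ExperimentTable:
    """Stimulus-response rules: Hick's law, repetition priming, decodability.

    Each block encodes ``n_rules`` color-response pairings once, then runs
    test trials in which a single color is shown and the response is read
    from the motor dimension.  Records RT and correctness per test trial,
    the response-repetition structure, and (for the largest rule set) the
    conjunctive activity during correct tests for rule decoding.
    """
    tab = ExperimentTable("task_set", params, seed)
    X_rule, y_rule = [], []
    for n_rules in n_rules_grid:
        seeds = child_seeds(seed + 17 * n_rules, n_blocks)
        for b, bs in enumerate(seeds):
            rng = np.random.default_rng(bs + 1)
            colors = rng.permutation(params.n_feat_per_dim)[:n_rules]
            resps = rng.permutation(params.n_feat_per_dim)[:n_rules]
            rules = list(zip(colors.tolist(), resps.tolist()))
            state = init_network(params, bs)
            state, _ = run_trial(state, build_rule_trial(rules, rules[0][0], params),
                                 params)
            prev_resp = None
            for t in range(n_test_trials):
                color, resp = rules[int(rng.integers(n_rules))]
                script = build_rule_trial(rules, color, params, encode_rules=False)
                state, res = run_trial(state, script, params)
                rep = int(resp == prev_resp) if prev_resp is not None else -1
                tab.add(b, t, bs, "correct", int(res.correct),
                        n_rules=n_rules, repeated=rep)
                if res.rt_steps is not None and res.correct:
                    tab.add(b, t, bs, "rt_steps", res.rt_steps,
                            n_rules=n_rules, repeated=rep)
                if n_rules == max(n_rules_grid) and res.correct and t >= 1:
                    onset = script.probe_onset()
                    X_rule.append(res.trace.c[onset + 40:onset + 100].mean(0))
                    y_rule.append(resp)
                prev_resp = resp
    if len(set(y_rule)) >= 2:
        _, rep = train_linear_decoder(DecodeDataset(np.asarray(X_rule),
                                                    np.asarray(y_rule),
                                                    unit_subset="conjunctive"),
                                      seed=seed)
        tab.add(-1, None, seed, "rule_decode_accuracy", rep.accuracy,
                n_rules=max(n_rules_grid), repeated=-1)
        tab.add(-1, None, seed, "rule_decode_chance", rep.chance,
                n_rules=max(n_rules_grid), repeated=-1)
    return tab


# ---------------------------------------------------------------------------
# trial-history experiments


def _history_series(params, seed, n_trials, n_varied_dims=2):
    """Run a long series of 1-item trials with continuous weights; return
    delay-window conjunctive patterns and the stimuli."""
    state = init_network(params, seed)
    rng = np.random.default_rng(seed + 1)
    pats, stims, correct = [], [], []
    for t in range(n_trials):
        feats = [int(rng.integers(params.n_feat_per_dim)) if d < n_varied_dims else 0
                 for d in range(params.n_dims)]
        item = StimulusItem(tuple(feats))
        script = build_trial([item], params, probe_item=0)
        state, res = run_trial(state, script, params)
        t0 = params.reset_steps + params.stim_steps + params.gap_steps
        pats.append(res.trace.c[t0 + params.delay_steps - 50:
                                t0 + params.delay_steps].mean(0))
        stims.append(tuple(feats[:n_varied_dims]))
        correct.append(res.correct)
    return np.asarray(pats), stims, correct


def exp_trial_history(
    params: ModelParams,
    n_trials: int = 1000,
    seed: int = 0,
    lags=tuple(range(1, 11)),
) -> ExperimentTable:
    """Trial-lag pattern similarity of conjunctive delay activity.

    Items vary on two feature dimensions (the third is fixed).  For each
    lag the Pearson similarity of delay-window conjunctive patterns is
    recorded for same-stimulus versus different-stimulus trial pairs; for
    lag 2, same-stimulus pairs are additionally split by whether the
    intervening trial's item was a conjunction violation (shares exactly
    one feature with the reference item).
    """
    tab = ExperimentTable("trial_history", params, seed)
    pats, stims, _ = _history_series(params, seed, n_trials)
    for lag in lags:
        for t in range(lag, n_trials):
            rho = pattern_similarity(pats[t], pats[t - lag])
            if np.isnan(rho):
                continue
            same = int(stims[t] == stims[t - lag])
            row = dict(lag=lag, same=same, violation=-1)
            if lag == 2 and same:
                ref, mid = stims[t], stims[t - 1]
                shared = sum(a == b for a, b in zip(ref, mid))
                row["violation"] = int(shared == 1)
            tab.add(0, t, seed, "similarity", rho, **row)
    return tab


def exp_previous_trial_benefit(
    params: ModelParams,
    n_trials: int = 300,
    seed: int = 0,
    p_repeat: float = 0.35,
    shuffled_weights: bool = False,
) -> ExperimentTable:
    """Recall benefit for the feature combination shown on the previous trial.

    A long series of probed 1-item trials; with probability ``p_repeat`` the
    item repeats the previous trial's combination exactly.  The first trial
    is excluded from the repeated/novel comparison.  The shuffled-weights
    control scrambles the weight rows between trials, removing any synaptic
    carry-over.
    """
    tab = ExperimentTable("previous_trial_benefit", params, seed)
    state = init_network(params, seed)
    rng = np.random.default_rng(seed + 1)
    prev = None
    for t in range(n_trials):
        if prev is not None and rng.random() < p_repeat:
            item, repeated = prev, 1
        else:
            item = make_items(1, rng, params)[0]
            repeated = int(prev is not None and item.features == prev.features)
        if shuffled_weights:
            shuffle_weights(state, rng)
        script = build_trial([item], params, probe_item=0)
        state, res = run_trial(state, script, params)
        if t > 0:
            tab.add(0, t, seed, "correct", int(res.correct), repeated=repeated,
                    control=int(shuffled_weights))
        prev = item
    return tab


# ---------------------------------------------------------------------------
# ablations and sweeps


def _persistence_probe(params: ModelParams, seed: int = 0, n_seeds: int = 5):
    """Noiseless single-item encode + 500-step blank; returns the median
    (over initializations) mean delay rate of the encoded vs all other
    features, conditioned on successful encoding.

    Persistence is a maintenance property, so seeds on which the noiseless
    winner competition stalls in a degenerate tie (no unit gets driven
    above 0.3 during the stimulus — nothing was encoded) are excluded
    rather than counted as maintenance failures.
    """
    q = params.replace(noise_sigma=0.0)
    item = StimulusItem(tuple([0, 1, 2][:q.n_dims]))
    on_idx = [q.feature_index(d, f) for d, f in enumerate(item.features)]
    off_idx = [i for i in range(q.n_features) if i not in on_idx]
    ons, offs = [], []
    for s in range(n_seeds):
        state = init_network(q, seed + s)
        script = build_trial([item], q, probe_item=0, delay_steps=500)
        state, trace = run_script(state, script, q)
        t0 = q.reset_steps + q.stim_steps + q.gap_steps
        if q.variant != "no_conjunctive_layer":
            enc = trace.c[t0 - q.gap_steps - q.stim_steps // 2: t0 - q.gap_steps]
            # degenerate tie: no unit ever crossed the learning gate during
            # the stimulus, so nothing was encoded
            if enc.max() < q.hebbian_gate:
                continue
        delay = trace.f[t0:t0 + 500]
        ons.append(float(delay[:, on_idx].mean()))
        offs.append(float(delay[:, off_idx].mean()))
    if not ons:
        return 0.0, 0.0
    return float(np.median(ons)), float(np.median(offs))


def exp_ablations(
    params: ModelParams,
    n_trials: int = 100,
    seed: int = 0,
    variants=("full", "facilitation_only", "no_c_to_f_plasticity", "no_conjunctive_layer"),
) -> ExperimentTable:
    """Capability matrix of the full model and its three simpler variants.

    Probes, per variant: selective persistence (encoded features sustained,
    others quiet, noiseless), single-item recall, retro-cue shifting of
    delay activity, and delay-length-dependent accuracy loss for unattended
    items in two-item trials (the delay-interference signature).
    """
    tab = ExperimentTable("ablations", params, seed)
    for variant in variants:
        p = params.replace(variant=variant)
        on, off = _persistence_probe(p, seed)
        tab.add(0, None, seed, "persist_on", on, variant=variant)
        tab.add(0, None, seed, "persist_off", off, variant=variant)
        tab.add(0, None, seed, "persistence", int(on > 0.5 and off < 0.2),
                variant=variant)

        # single-item recall, noiseless (typical case over initializations)
        q = p.replace(noise_sigma=0.0)
        item = StimulusItem(tuple([0, 1, 2][:q.n_dims]))
        recalls = []
        for s in range(5):
            state = init_network(q, seed + s)
            state, res = run_trial(state, build_trial([item], q, probe_item=0), q)
            recalls.append(int(res.correct))
        tab.add(0, None, seed, "single_recall", int(np.median(recalls)),
                variant=variant)

        # retro-cue shift of delay activity toward the cued (first) item
        shifts = []
        seeds = child_seeds(seed + 13, max(1, n_trials // DEFAULT_BLOCK_LEN))
        for bs in seeds:
            state = init_network(p, bs)
            rng = np.random.default_rng(bs + 1)
            for t in range(DEFAULT_BLOCK_LEN):
                items = make_items(2, rng, p)
                script = build_trial(items, p, probe_item=0, delay_steps=300,
                                     retrocue=(0, 0), cue_time=100)
                state, res = run_trial(state, script, p)
                onset = script.probe_onset() - p.quench_steps
                win = res.trace.f[onset - 80:onset]
                i1 = [p.feature_index(d, f) for d, f in enumerate(items[0].features)]
                i2 = [p.feature_index(d, f) for d, f in enumerate(items[1].features)]
                shifts.append(float(win[:, i1].mean() - win[:, i2].mean()))
        tab.add(0, None, seed, "retrocue_shift", float(np.mean(shifts)), variant=variant)

        # delay interference: unattended accuracy, short vs long delay
        for delay in (100, 800):
            accs = []
            seeds = child_seeds(seed + 29 + delay, max(1, n_trials // DEFAULT_BLOCK_LEN))
            for bs in seeds:
                state = init_network(p, bs)
                rng = np.random.default_rng(bs + 1)
                for t in range(DEFAULT_BLOCK_LEN):
                    items = make_items(2, rng, p)
                    script = build_trial(items, p, probe_item=0, delay_steps=delay)
                    state, res = run_trial(state, script, p)
                    accs.append(res.correct)
            tab.add(0, None, seed, "unattended_acc", float(np.mean(accs)),
                    variant=variant, delay=delay)
    return tab


EXPERIMENTS = {
    "set_size": exp_set_size,
    "serial_position": exp_serial_position,
    "encoding_duration": exp_encoding_duration,
    "delay_decay": exp_delay_decay,
    "retrocue": exp_retrocue,
    "pulse": exp_pulse,
    "task_set": exp_task_set,
    "trial_history": exp_trial_history,
    "previous_trial_benefit": exp_previous_trial_benefit,
    "ablations": exp_ablations,
}


def parameter_sweep(
    params: ModelParams,
    grid: dict,
    experiment: str,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Cross-product sweep of ModelParams fields, re-running one experiment
    per cell.  An empty grid runs the single canonical cell."""
    if experiment not in EXPERIMENTS:
        raise ConfigurationError(f"unknown experiment {experiment!r}")
    fn = EXPERIMENTS[experiment]
    keys = list(grid)
    cells = list(itertools.product(*grid.values())) if grid else [()]
    frames = []
    for values in cells:
        cell = dict(zip(keys, values))
        tab = fn(params.replace(**cell), seed=seed, **kwargs)
        df = tab.df
        for k, v in cell.items():
            df[f"sweep_{k}"] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
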