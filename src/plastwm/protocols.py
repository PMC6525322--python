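"""Stimulus construction, timed trial scripts, and behavioral readout.

A memory item is a conjunction of discrete features, one per stimulus
dimension (canonically color, orientation, location with four values each).
A trial is a timed schedule of constant-input epochs: an inhibitory reset,
sequential item presentations, a delay (optionally interrupted by an
incidental retro-cue or a nonspecific excitatory pulse), a single-feature
probe, and a readout window.  Running a script returns a
:class:`TrialResult` with the reported feature, a reaction-time proxy, the
conjunctive winner of each encoding epoch, and the full activity trace.

Weights always carry over from trial to trial; only an explicit reset epoch
(transient global inhibition) quenches the *rates* at trial onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import ActivityTrace, NetworkState, run_epoch
from .params import ConfigurationError, ModelParams


@dataclass(frozen=True)
class StimulusItem:
    """One memory item: a feature index per dimension (dimension-major order)."""

    features: tuple

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(int(v) for v in self.features))

    @property
    def color(self) -> int:
        return self.features[0]

    @property
    def orientation(self) -> int:
        return self.features[1]

    @property
    def location(self) -> int:
        return self.features[2]

    def validate(self, params: ModelParams) -> None:
        if len(self.features) != params.n_dims:
            raise ConfigurationError(
                f"item has {len(self.features)} features, expected {params.n_dims}"
            )
        if any(not (0 <= v < params.n_feat_per_dim) for v in self.features):
            raise ConfigurationError(f"feature index out of range in {self.features}")


@dataclass
class Epoch:
    kind: str                      # reset | stimulus | blank | cue | pulse | probe | readout
    i_ext: np.ndarray              # constant feature-layer input
    duration: int                  # steps
    i_ext_c: np.ndarray | None = None


@dataclass
class TrialScript:
    """Ordered epochs plus the probe/readout bookkeeping for scoring."""

    epochs: list
    items: list
    probe_dimension: int | None = None
    probe_feature: int | None = None
    target_item: int | None = None
    report_dimension: int = 1      # canonical: orientation
    generalization_probe: bool = False

    @property
    def total_steps(self) -> int:
        return sum(e.duration for e in self.epochs)

    def probe_onset(self) -> int | None:
        """Step offset (within the trial) at which the probe epoch begins."""
        t = 0
        for e in self.epochs:
            if e.kind == "probe":
                return t
            t += e.duration
        return None

    def to_json(self) -> str:
        return json.dumps(
            {
                "epochs": [
                    {
                        "kind": e.kind,
                        "duration": e.duration,
                        "i_ext": e.i_ext.tolist(),
                        "i_ext_c": None if e.i_ext_c is None else e.i_ext_c.tolist(),
                    }
                    for e in self.epochs
                ],
                "items": [list(it.features) for it in self.items],
                "probe_dimension": self.probe_dimension,
                "probe_feature": self.probe_feature,
                "target_item": self.target_item,
                "report_dimension": self.report_dimension,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrialScript":
        d = json.loads(text)
        return cls(
            epochs=[
                Epoch(
                    kind=e["kind"],
                    i_ext=np.asarray(e["i_ext"], dtype=float),
                    duration=int(e["duration"]),
                    i_ext_c=None if e["i_ext_c"] is None else np.asarray(e["i_ext_c"]),
                )
                for e in d["epochs"]
            ],
            items=[StimulusItem(tuple(v)) for v in d["items"]],
            probe_dimension=d["probe_dimension"],
            probe_feature=d["probe_feature"],
            target_item=d["target_item"],
            report_dimension=d["report_dimension"],
        )


@dataclass
class TrialResult:
    reported_feature: int | None
    correct: bool
    rt_steps: int | None
    winner_conj: list
    trace: ActivityTrace
    target_feature: int | None = None


# ---------------------------------------------------------------------------
# stimulus construction


def make_items(
    n_items: int,
    rng: np.random.Generator,
    params: ModelParams,
    unique: bool = True,
    shared_feature: bool = False,
) -> list:
    """Draw ``n_items`` stimulus items.

    By default items are unique on *every* dimension (feasible only while
    ``n_items <= n_feat_per_dim``).  In shared-feature mode the first two
    items are forced to share exactly one dimension's feature value, for
    stress tests of feature-overlap interference.
    """
    npd = params.n_feat_per_dim
    if unique and n_items > npd:
        raise ConfigurationError(
            f"cannot draw {n_items} per-dimension-unique items from {npd} features"
        )
    if shared_feature and n_items < 2:
        raise ConfigurationError("shared-feature mode needs at least 2 items")

    cols = []
    for _ in range(params.n_dims):
        if unique:
            cols.append(rng.permutation(npd)[:n_items])
        else:
            cols.append(rng.integers(0, npd, size=n_items))
    feats = np.stack(cols, axis=1)  # (n_items, n_dims)

    if shared_feature:
        shared_dim = int(rng.integers(params.n_dims))
        feats[1, shared_dim] = feats[0, shared_dim]
        # keep the other dimensions distinct between items 0 and 1
        for d in range(params.n_dims):
            if d == shared_dim:
                continue
            if feats[1, d] == feats[0, d]:
                choices = [v for v in range(npd) if v != feats[0, d]]
                feats[1, d] = int(rng.choice(choices))
    return [StimulusItem(tuple(row)) for row in feats]


def encode_input(item: StimulusItem, params: ModelParams) -> np.ndarray:
    """Input vector driving the item's one feature unit per dimension."""
    item.validate(params)
    vec = np.zeros(params.n_features)
    for d, feat in enumerate(item.features):
        vec[params.feature_index(d, int(feat))] = params.stim_drive
    return vec


def feature_input(dim: int, feat: int, params: ModelParams, drive: float | None = None) -> np.ndarray:
    """Input vector driving a single feature unit."""
    vec = np.zeros(params.n_features)
    vec[params.feature_index(dim, feat)] = params.stim_drive if drive is None else drive
    return vec


# ---------------------------------------------------------------------------
# trial scripts


def _reset_epoch(params: ModelParams) -> Epoch:
    return Epoch(
        kind="reset",
        i_ext=np.full(params.n_features, -params.reset_drive),
        duration=params.reset_steps,
        i_ext_c=np.full(params.n_conj, -params.reset_drive),
    )


def _quench_epoch(params: ModelParams) -> Epoch:
    """Brief global inhibition modelling the interruption of ongoing activity
    by an abrupt display change (cue or probe onset).  Shorter than the
    inter-trial reset, so the focused item retains a residual-rate head
    start in the retrieval competition."""
    return Epoch(
        kind="quench",
        i_ext=np.full(params.n_features, -params.reset_drive),
        duration=params.quench_steps,
        i_ext_c=np.full(params.n_conj, -params.reset_drive),
    )


def _stimulus_epochs(
    vec: np.ndarray, duration: int, params: ModelParams, first: bool = False
) -> list:
    """Stimulus presentation with feedforward onset inhibition.

    A new stimulus disrupts ongoing activity: for the first
    ``stim_onset_steps`` the conjunctive layer receives transient inhibition
    while the feature layer switches to the new input pattern; the
    conjunctive competition then restarts on the new pattern.  Synaptic
    weights are untouched.  The first stimulus after a reset (``first``)
    skips the onset transient — there is no ongoing activity to disrupt —
    which is the model's source of primacy.
    """
    if duration <= 0:
        return []
    onset = 0 if first else min(params.stim_onset_steps, duration)
    eps = []
    if onset > 0:
        eps.append(
            Epoch("stimulus_onset", vec, onset,
                  i_ext_c=np.full(params.n_conj, -params.stim_onset_drive))
        )
    if duration > onset:
        eps.append(Epoch("stimulus", vec, duration - onset))
    return eps


def build_trial(
    items: Sequence[StimulusItem],
    params: ModelParams,
    probe: tuple | None = None,
    probe_item: int | None = None,
    delay_steps: int | None = None,
    stim_steps: int | None = None,
    retrocue: tuple | None = None,       # (item index, cue dimension)
    pulse: tuple | None = None,          # (strength, duration, time within delay)
    cue_time: int | None = None,         # cue onset within the delay
    probe_extra_feature: int | None = None,  # report-dim feature added to the probe input
    report_dimension: int = 1,
) -> TrialScript:
    """Assemble a standard working-memory trial.

    Epochs: inhibitory reset, one stimulus epoch per item (each followed by a
    short blank gap), a delay — optionally interrupted by a single-feature
    incidental cue and/or a uniform excitatory pulse to all feature units —
    then a probe epoch driving a single feature, and a readout window during
    which the probe input stays on.  ``probe`` is ``(dimension, feature)``;
    alternatively pass ``probe_item`` to probe that item's color.
    """
    items = list(items)
    for it in items:
        it.validate(params)
    delay = params.delay_steps if delay_steps is None else int(delay_steps)
    stim = params.stim_steps if stim_steps is None else int(stim_steps)

    if probe is None:
        if probe_item is None:
            raise ConfigurationError("specify probe=(dim, feature) or probe_item")
        probe = (0, items[probe_item].features[0])
    probe_dim, probe_feat = int(probe[0]), int(probe[1])

    target_item = None
    for idx, it in enumerate(items):
        if it.features[probe_dim] == probe_feat:
            target_item = idx
            break
    if target_item is None:
        raise ConfigurationError("probe feature does not belong to any presented item")

    epochs = [_reset_epoch(params)]
    for j, it in enumerate(items):
        # the first item follows the silent inter-trial reset, so there is no
        # ongoing activity for its onset to disrupt
        epochs.extend(
            _stimulus_epochs(encode_input(it, params), stim, params, first=(j == 0))
        )
        epochs.append(Epoch("blank", np.zeros(params.n_features), params.gap_steps))

    # schedule optional delay events, keeping total delay length fixed
    events = []  # (time, [epochs])
    if retrocue is not None:
        cue_item, cue_dim = int(retrocue[0]), int(retrocue[1])
        t_cue = delay // 3 if cue_time is None else int(cue_time)
        cue_len = params.cue_steps + (params.quench_steps if params.onset_quench else 0)
        if not (0 <= t_cue and t_cue + cue_len <= delay):
            raise ConfigurationError("retro-cue scheduled outside the delay")
        cue_vec = feature_input(cue_dim, items[cue_item].features[cue_dim], params)
        cue_eps = [Epoch("cue", cue_vec, params.cue_steps)]
        if params.onset_quench:
            cue_eps.insert(0, _quench_epoch(params))
        events.append((t_cue, cue_eps))
    if pulse is not None:
        strength, dur, t_pulse = float(pulse[0]), int(pulse[1]), int(pulse[2])
        if not (0 <= t_pulse and t_pulse + dur <= delay):
            raise ConfigurationError("pulse scheduled outside the delay")
        events.append(
            (t_pulse, [Epoch("pulse", np.full(params.n_features, strength), dur)])
        )
    events.sort(key=lambda pair: pair[0])
    cursor = 0
    for t_ev, eps in events:
        if t_ev < cursor:
            raise ConfigurationError("overlapping delay events")
        if t_ev > cursor:
            epochs.append(Epoch("blank", np.zeros(params.n_features), t_ev - cursor))
        epochs.extend(eps)
        cursor = t_ev + sum(e.duration for e in eps)
    if delay > cursor:
        epochs.append(Epoch("blank", np.zeros(params.n_features), delay - cursor))

    probe_vec = feature_input(probe_dim, probe_feat, params)
    if probe_extra_feature is not None:
        probe_vec = probe_vec + feature_input(report_dimension, int(probe_extra_feature), params)
    if params.onset_quench:
        epochs.append(_quench_epoch(params))
    epochs.append(Epoch("probe", probe_vec, params.probe_steps))
    epochs.append(Epoch("readout", probe_vec, params.readout_steps))

    return TrialScript(
        epochs=epochs,
        items=items,
        probe_dimension=probe_dim,
        probe_feature=probe_feat,
        target_item=target_item,
        report_dimension=report_dimension,
    )


def build_whole_report_trial(
    items: Sequence[StimulusItem],
    params: ModelParams,
    probe_dimension: int = 0,
    report_dimension: int = 1,
    delay_steps: int | None = None,
) -> tuple:
    """Whole-sequence recall: probe every item in presentation order.

    One trial = reset, sequential stimuli, delay, then for each position a
    display-change quench plus probe/readout pair.  Returns ``(script,
    probe_windows)`` where each probe window is ``(position, start, stop)``
    in trial steps; reports are read per window with :func:`read_report`'s
    rule applied to that window.
    """
    items = list(items)
    base = build_trial(items, params, probe_item=0, delay_steps=delay_steps,
                       report_dimension=report_dimension)
    # strip the single probe tail (quench? + probe + readout)
    tail = 3 if params.onset_quench else 2
    epochs = base.epochs[:-tail]
    windows = []
    t = sum(e.duration for e in epochs)
    for pos, it in enumerate(items):
        probe_vec = feature_input(probe_dimension, it.features[probe_dimension], params)
        if params.onset_quench:
            epochs.append(_quench_epoch(params))
            t += params.quench_steps
        start = t
        epochs.append(Epoch("probe", probe_vec, params.probe_steps))
        epochs.append(Epoch("readout", probe_vec, params.readout_steps))
        t += params.probe_steps + params.readout_steps
        windows.append((pos, start, t))
    script = TrialScript(
        epochs=epochs,
        items=items,
        probe_dimension=probe_dimension,
        probe_feature=None,
        target_item=None,
        report_dimension=report_dimension,
    )
    return script, windows


def score_whole_report(
    script: TrialScript, windows, trace: ActivityTrace, params: ModelParams
) -> list:
    """Score each probe window of a whole-report trial.

    Returns one dict per probed position with the reported feature, the
    owning item (which presented item's report feature was produced, if
    any) and correctness.
    """
    out = []
    sl = params.dimension_slice(script.report_dimension)
    for pos, start, stop in windows:
        rates = trace.f[start:stop, sl]
        tail = rates[-params.readout_tail:, :].mean(axis=0)
        reported = int(np.argmax(tail)) if tail.max() >= params.readout_threshold else None
        target = script.items[pos].features[script.report_dimension]
        owner = None
        if reported is not None:
            for i, it in enumerate(script.items):
                if it.features[script.report_dimension] == reported:
                    owner = i
                    break
        out.append({
            "position": pos,
            "reported": reported,
            "target": target,
            "correct": reported == target,
            "owner": owner,
        })
    return out


def build_rule_trial(
    rules: Sequence[tuple],
    test_color: int,
    params: ModelParams,
    motor_dimension: int | None = None,
    encode_rules: bool = True,
) -> TrialScript:
    """Assemble a stimulus-response (task-set) trial.

    Each rule is a ``(color, response)`` pair; responses live on a feature
    dimension reused as motor plans (canonically the last dimension).  Rule
    encoding co-activates the color and response features sequentially; the
    test epoch drives only ``test_color`` and the report is read from the
    motor dimension.  With ``encode_rules=False`` only the test part is
    built (rules already in the weights from a previous script).
    """
    motor_dim = params.n_dims - 1 if motor_dimension is None else int(motor_dimension)
    rules = [(int(c), int(r)) for c, r in rules]
    if encode_rules:
        # rule instructions are deliberate, well-separated presentations:
        # every rule follows a full inhibitory reset, so each pairing is
        # encoded from silence
        epochs = []
        for color, resp in rules:
            vec = feature_input(0, color, params) + feature_input(motor_dim, resp, params)
            epochs.append(_reset_epoch(params))
            epochs.extend(_stimulus_epochs(vec, params.stim_steps, params, first=True))
            epochs.append(Epoch("blank", np.zeros(params.n_features), params.gap_steps))
    else:
        # a test trial interrupts ongoing activity like any display change;
        # residual rates from the previous response are not fully erased,
        # which is the source of response-repetition priming
        epochs = [_quench_epoch(params)]

    generalization = all(test_color != c for c, _ in rules)
    target_item = None
    items = [StimulusItem(tuple(c if d == 0 else (r if d == motor_dim else 0)
                                for d in range(params.n_dims)))
             for c, r in rules]
    if not generalization:
        target_item = [c for c, _ in rules].index(test_color)

    probe_vec = feature_input(0, int(test_color), params)
    if params.onset_quench and encode_rules:
        epochs.append(_quench_epoch(params))
    epochs.append(Epoch("probe", probe_vec, params.probe_steps))
    epochs.append(Epoch("readout", probe_vec, params.readout_steps))
    return TrialScript(
        epochs=epochs,
        items=items,
        probe_dimension=0,
        probe_feature=int(test_color),
        target_item=target_item,
        report_dimension=motor_dim,
        generalization_probe=generalization,
    )


# ---------------------------------------------------------------------------
# running trials


def run_script(
    state: NetworkState, script: TrialScript, params: ModelParams, record: bool = True
) -> tuple[NetworkState, ActivityTrace]:
    """Execute every epoch of a script; returns the concatenated trace."""
    traces = []
    for ep in script.epochs:
        state, tr = run_epoch(
            state, ep.i_ext, ep.duration, params,
            i_ext_c=ep.i_ext_c, record=record, label=ep.kind,
        )
        traces.append(tr)
    trace = ActivityTrace.concatenate(traces) if record else traces[-1]
    return state, trace


def _winner_conjunctions(script: TrialScript, trace: ActivityTrace, params: ModelParams) -> list:
    """Per stimulus presentation, the conjunctive unit with the highest mean
    rate over the presentation's second half (ties broken by lowest index).
    A presentation is a ``stimulus_onset`` epoch plus any directly following
    ``stimulus`` epoch."""
    spans = []
    t = 0
    for ep in script.epochs:
        if ep.kind == "stimulus_onset":
            spans.append([t, t + ep.duration])
        elif ep.kind == "stimulus":
            if spans and spans[-1][1] == t:
                spans[-1][1] = t + ep.duration
            else:
                spans.append([t, t + ep.duration])
        t += ep.duration
    winners = []
    for a, b in spans:
        half = trace.c[(a + b) // 2: b]
        winners.append(int(np.argmax(half.mean(axis=0))) if half.size else None)
    return winners


def read_report(
    script: TrialScript, trace: ActivityTrace, params: ModelParams
) -> tuple[int | None, int | None]:
    """Score the probe window: (reported feature, rt in steps).

    The report is the report-dimension feature unit with the highest mean
    rate over the tail of the readout window, provided that mean exceeds
    ``readout_threshold`` (otherwise no report).  The reaction-time proxy is
    the first step after probe onset at which the reported unit's rate
    reaches the threshold.
    """
    onset = script.probe_onset()
    if onset is None:
        return None, None
    window = trace.f[onset:, :]
    sl = params.dimension_slice(script.report_dimension)
    rates = window[:, sl]
    tail = rates[-params.readout_tail:, :].mean(axis=0)
    if tail.max() < params.readout_threshold:
        return None, None
    reported = int(np.argmax(tail))
    above = np.nonzero(rates[:, reported] >= params.readout_threshold)[0]
    rt = int(above[0]) + 1 if above.size else rates.shape[0]
    return reported, rt


def run_trial(
    state: NetworkState, script: TrialScript, params: ModelParams, record: bool = True
) -> tuple[NetworkState, TrialResult]:
    """Run one trial and score it.

    The state — including the plastic weights — carries over to the next
    trial; nothing is reset here beyond the script's own reset epoch.
    A trial whose script has no probe epoch never produces a report.
    """
    state, trace = run_script(state, script, params, record=record)
    if not record:
        raise ValueError("run_trial requires record=True to score the report")
    reported, rt = read_report(script, trace, params)
    target_feature = None
    if script.target_item is not None:
        target_feature = script.items[script.target_item].features[script.report_dimension]
    correct = reported is not None and target_feature is not None and reported == target_feature
    return state, TrialResult(
        reported_feature=reported,
        correct=bool(correct),
        rt_steps=rt,
        winner_conj=_winner_conjunctions(script, trace, params),
        trace=trace,
        target_feature=target_feature,
    )


def shuffle_weights(state: NetworkState, rng: np.random.Generator) -> NetworkState:
    """Control manipulation: permute each incoming weight row independently,
    destroying all stimulus information while preserving row norms."""
    for W in (state.W_fc, state.W_cf) + ((state.W_ff,) if state.W_ff is not None else ()):
        for row in W:
            rng.shuffle(row)
    return state
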