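"""Neural-readout analyses over simulated activity.

Linear decoding of stimulus identity from time-windowed population rates,
cross-decoding between attended and unattended representations (where
below-chance accuracy — "representational inversion" — is a meaningful
outcome, not an error), trial-lag pattern similarity of conjunctive delay
activity, and the bootstrap helpers the experiments use for directional
tests.

The canonical decoder is a nearest-class-centroid linear classifier: it is
deterministic, parameter-free, and linear, which makes every reported
accuracy exactly reproducible from (dataset, seed).  A regularized logistic
decoder is available behind a flag as a robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestCentroid


# ---------------------------------------------------------------------------
# bootstrap helpers


def bootstrap_ci(values, n_boot: int = 2000, level: float = 0.95, seed: int = 0):
    """Percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha))


def bootstrap_greater(a, b, n_boot: int = 2000, level: float = 0.95, seed: int = 0) -> bool:
    """True when mean(a) > mean(b) at the given one-sided bootstrap level.

    ``a`` and ``b`` are independent samples (e.g. per-trial correctness under
    two conditions); the test asks whether the bootstrap distribution of
    mean(a) − mean(b) lies above zero at the requested level.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    return float(np.quantile(diffs, 1.0 - level)) > 0.0


# ---------------------------------------------------------------------------
# datasets and reports


@dataclass
class DecodeDataset:
    """Trial-by-unit activity samples with one label per trial.

    ``samples`` is (n_trials, n_units): each row is the mean rate over a
    named time window of one trial.  ``labels`` is the stimulus identity on
    one feature dimension.  ``unit_subset`` records which units the samples
    contain ("feature", "conjunctive", "orientation", "all", ...).
    """

    samples: np.ndarray
    labels: np.ndarray
    window: tuple = (0, 0)
    unit_subset: str = "all"

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.samples.shape[0] != self.labels.shape[0]:
            raise ValueError("samples and labels disagree on trial count")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("need at least 2 label classes")

    @property
    def n_classes(self) -> int:
        return int(len(np.unique(self.labels)))

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


@dataclass
class DecoderReport:
    accuracy: float
    chance: float
    ci: tuple = (np.nan, np.nan)
    cross_accuracy: float | None = None
    null_quantiles: tuple | None = None   # (2.5th, 97.5th) of the shuffle null
    per_window: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "chance": self.chance,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "cross_accuracy": self.cross_accuracy,
            "null_low": None if self.null_quantiles is None else self.null_quantiles[0],
            "null_high": None if self.null_quantiles is None else self.null_quantiles[1],
        }


def _make_decoder(kind: str, seed: int = 0):
    if kind == "centroid":
        return NearestCentroid()
    if kind == "logistic":
        return LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
    raise ValueError(f"unknown decoder kind {kind!r}")


def train_linear_decoder(
    data: DecodeDataset,
    seed: int = 0,
    n_folds: int = 4,
    kind: str = "centroid",
):
    """Fit the canonical linear decoder and report cross-validated accuracy.

    Returns ``(fitted_decoder, DecoderReport)``.  Folds are stratified and
    shuffled with ``seed`` so the report is reproducible.
    """
    clf = _make_decoder(kind, seed)
    counts = np.unique(data.labels, return_counts=True)[1]
    folds = int(min(n_folds, counts.min()))
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = cross_val_score(clf, data.samples, data.labels, cv=cv)
        acc = float(scores.mean())
        ci = bootstrap_ci(scores, seed=seed)
    else:   # too few samples per class for CV: training accuracy, flagged by wide CI
        acc = float(np.mean(clf.fit(data.samples, data.labels).predict(data.samples)
                            == data.labels))
        ci = (np.nan, np.nan)
    clf = _make_decoder(kind, seed).fit(data.samples, data.labels)
    return clf, DecoderReport(accuracy=acc, chance=data.chance, ci=ci)


def cross_decode(
    train: DecodeDataset,
    test: DecodeDataset,
    seed: int = 0,
    n_shuffles: int = 1000,
    kind: str = "centroid",
) -> DecoderReport:
    """Train on one condition, evaluate on another.

    Below-chance cross-accuracy is a valid outcome (representational
    inversion).  The report carries a label-shuffle null distribution of the
    cross-accuracy so "below chance" can be read as "below the null's 2.5th
    percentile".
    """
    if set(np.unique(train.labels)) != set(np.unique(test.labels)):
        raise ValueError("train and test label spaces differ")
    if train.samples.shape[1] != test.samples.shape[1]:
        raise ValueError("train and test unit counts differ")
    clf = _make_decoder(kind, seed).fit(train.samples, train.labels)
    acc = float(np.mean(clf.predict(test.samples) == test.labels))
    within = float(np.mean(clf.predict(train.samples) == train.labels))

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        ys = rng.permutation(train.labels)
        null[i] = np.mean(
            _make_decoder(kind, seed).fit(train.samples, ys).predict(test.samples)
            == test.labels
        )
    return DecoderReport(
        accuracy=within,
        chance=train.chance,
        cross_accuracy=acc,
        null_quantiles=(float(np.quantile(null, 0.025)), float(np.quantile(null, 0.975))),
    )


def pattern_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two window-mean activity vectors.

    Returns NaN when either vector has (near-)zero variance — an undefined
    similarity is reported as missing rather than raising.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    if a.std() < 1e-12 or b.std() < 1e-12:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def decode_timecourse(
    traces: np.ndarray,
    labels,
    windows,
    seed: int = 0,
    kind: str = "centroid",
) -> DecoderReport:
    """Sliding-window decoding: one CV accuracy per (start, stop) window.

    ``traces`` is (n_trials, n_steps, n_units); each window is averaged over
    time before decoding.  The report's ``per_window`` lists
    ``(start, stop, accuracy)`` and ``accuracy`` is the best window's.
    """
    traces = np.asarray(traces)
    labels = np.asarray(labels)
    per_window = []
    for (start, stop) in windows:
        data = DecodeDataset(traces[:, start:stop, :].mean(axis=1), labels,
                             window=(start, stop))
        _, rep = train_linear_decoder(data, seed=seed, kind=kind)
        per_window.append((int(start), int(stop), rep.accuracy))
    best = max(per_window, key=lambda w: w[2])
    return DecoderReport(
        accuracy=best[2],
        chance=1.0 / len(np.unique(labels)),
        per_window=per_window,
    )
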