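"""Metrics, ROC/AUC, fixed-specificity protocol, cross-validation, sweeps.

The comparison protocol fixes specificity at 0.650: each model's decision
threshold is the 0.650 empirical quantile of its *negative* scores, and
sensitivity, accuracy and Matthews correlation are then read off the
resulting confusion matrix, so models are compared at a common operating
point. AUC is threshold-free and equals the Mann-Whitney pair statistic
P(score+ > score-) + 0.5 P(tie).

Metric definitions (TP/TN/FP/FN from the thresholded confusion matrix):

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

Cross-validated results are reported per fold and as mean +/- sample
standard deviation across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from scipy import stats

from . import models as _models
from .encoders import AAIndexTable, encode_windows
from .peptide_io import LabeledDataset, kfold_assign

DEFAULT_TARGET_SP = 0.650


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion matrix is empty")


@dataclass
class FoldMetrics:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    threshold: float


@dataclass
class MetricsReport:
    """Per-fold metrics plus mean +/- sample (n-1) standard deviation."""

    folds: list[FoldMetrics]

    _NAMES = ("sn", "sp", "mcc", "acc", "auc")  # Table-style column order

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(f, name) for f in self.folds]))

    def sd(self, name: str) -> float:
        vals = [getattr(f, name) for f in self.folds]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, str]:
        return {
            n: f"{self.mean(n):.3f} ± {self.sd(n):.3f}" for n in self._NAMES
        }

    def row(self, model_name: str) -> str:
        s = self.summary()
        return "\t".join([model_name] + [s[n] for n in self._NAMES])

    @staticmethod
    def header() -> str:
        return "model\tSn\tSp\tMCC\tACC\tAUC"


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Counts under the decision rule: positive iff score > threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pred = scores > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def compute_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, ACC, MCC) from a confusion matrix.

    A metric whose denominator vanishes is returned as ``nan`` after an
    explicit ``UndefinedMetricWarning``-style warning, never silently.
    """
    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning,
                          stacklevel=3)
            return float("nan")
        return num / den

    sn = _ratio(c.tp, c.tp + c.fn, "Sn")
    sp = _ratio(c.tn, c.tn + c.fp, "Sp")
    acc = (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
    denom = (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    if denom == 0:
        warnings.warn("MCC undefined: zero denominator", RuntimeWarning,
                      stacklevel=2)
        mcc = float("nan")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / sqrt(denom)
    return sn, sp, acc, mcc


def roc_auc(scores, labels) -> float:
    """AUC as the tie-aware Mann-Whitney rank statistic.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) over all
    positive/negative pairs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) pairs at every distinct threshold, for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


def threshold_for_specificity(
    neg_scores, target_sp: float = DEFAULT_TARGET_SP
) -> float:
    """Decision threshold attaining specificity ``target_sp`` on negatives.

    Returns the linear-interpolation empirical quantile of the negative
    scores at ``target_sp``; classifying positive when score > threshold then
    leaves (about) a ``target_sp`` fraction of negatives below it. With
    heavily tied negative scores the achievable specificity is quantized; a
    warning flags that degenerate case.
    """
    if not 0 < target_sp < 1:
        raise ValueError(f"target specificity must be in (0,1), got {target_sp}")
    neg_scores = np.asarray(neg_scores, dtype=np.float64)
    if neg_scores.size == 0:
        raise ValueError("no negative scores supplied")
    thr = float(np.quantile(neg_scores, target_sp))
    achieved = float(np.mean(neg_scores <= thr))
    if abs(achieved - target_sp) > max(1.0 / neg_scores.size, 1e-12):
        warnings.warn(
            f"tied scores: achieved Sp {achieved:.3f} differs from target "
            f"{target_sp:.3f} by more than 1/n",
            RuntimeWarning,
        )
    return thr


def evaluate_fixed_sp(
    scores, labels, target_sp: float = DEFAULT_TARGET_SP
) -> FoldMetrics:
    """Metrics at the fixed-specificity operating point (AUC threshold-free)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    thr = threshold_for_specificity(scores[labels == 0], target_sp)
    c = confusion_at_threshold(scores, labels, thr)
    sn, sp, acc, mcc = compute_metrics(c)
    return FoldMetrics(sn, sp, acc, mcc, roc_auc(scores, labels), thr)


# ---------------------------------------------------------------------------
# cross-validation


def _encode_dataset(dataset: LabeledDataset, encoder_spec: dict) -> np.ndarray:
    spec = dict(encoder_spec)
    scheme = spec.pop("scheme")
    return encode_windows(dataset.sequences, scheme, **spec)


def cross_validate(
    model_config: "_models.ModelConfig",
    encoder_spec: dict,
    dataset: LabeledDataset,
    k: int = 5,
    seed: int = 0,
    target_sp: float = DEFAULT_TARGET_SP,
    train_kwargs: dict | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation at the fixed-Sp operating point.

    ``encoder_spec`` is e.g. ``{"scheme": "zscale"}`` or
    ``{"scheme": "aaindex", "aaindex_table": table}``. For network models the
    held-out fold doubles as the early-stopping validation set (the reference
    protocol); pass ``train_kwargs`` to override batch size, epoch budget,
    patience or learning rate.
    """
    X = _encode_dataset(dataset, encoder_spec)
    y = dataset.labels
    if np.unique(y).size < 2:
        raise ValueError("cross-validation requires both classes")
    fold_of = kfold_assign(np.arange(len(y)), labels=y, k=k, seed=seed)
    folds = np.array([fold_of[i] for i in range(len(y))])
    train_kwargs = train_kwargs or {}

    results = []
    for fold in range(1, k + 1):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        cfg = _models.ModelConfig(
            **{**model_config.__dict__, "seed": model_config.seed + fold}
        )
        model = _models.build_model(cfg, X.shape[1:])
        if model.kind == "network":
            _models.train_network(
                model, X[train_idx], y[train_idx], X[test_idx], y[test_idx],
                **train_kwargs,
            )
        else:
            _models.fit_tree(model, X[train_idx], y[train_idx])
        scores = _models.predict_scores(model, X[test_idx])
        results.append(evaluate_fixed_sp(scores, y[test_idx], target_sp))
    return MetricsReport(results)


@dataclass
class SweepResult:
    axis: str
    settings: list
    reports: dict = field(default_factory=dict)  # setting -> MetricsReport

    def table(self) -> str:
        lines = [MetricsReport.header()]
        for s in self.settings:
            if s in self.reports:
                lines.append(self.reports[s].row(f"{self.axis}={s}"))
        return "\n".join(lines)


def _trim_window(seq: str, L: int) -> str:
    half = (len(seq) - 1) // 2
    new_half = (L - 1) // 2
    return seq[half - new_half : half + new_half + 1]


def run_sweep(
    axis: str,
    values,
    dataset: LabeledDataset,
    model_config: "_models.ModelConfig",
    encoder_spec: dict,
    k: int = 5,
    seed: int = 0,
    train_kwargs: dict | None = None,
) -> SweepResult:
    """One full cross-validation per setting, everything else held fixed.

    Axes: ``window_length`` (windows re-cut to each odd L <= the dataset's
    window length before re-encoding), ``depth`` (CNN-n for integer values,
    plus ``"rscnn"``), ``feature`` (encoding schemes), ``algorithm``. A
    single master seed is reused so settings differ only in the swept
    variable. Invalid settings are skipped with a warning.
    """
    from .peptide_io import PeptideWindow

    values = list(values)
    if not values:
        raise ValueError("sweep needs at least one setting")
    result = SweepResult(axis, values)
    for v in values:
        try:
            ds, cfg, enc = dataset, model_config, encoder_spec
            if axis == "window_length":
                L0 = len(dataset.windows[0].sequence)
                if not (isinstance(v, int) and 3 <= v <= L0 and v % 2 == 1):
                    raise ValueError(f"invalid window length {v} (dataset L={L0})")
                ds = LabeledDataset(
                    [
                        PeptideWindow(w.protein_id, w.position,
                                      _trim_window(w.sequence, v), w.label)
                        for w in dataset.windows
                    ],
                    dataset.labels,
                )
            elif axis == "depth":
                if v == "rscnn":
                    cfg = _models.ModelConfig(
                        **{**model_config.__dict__, "algorithm": "rscnn"}
                    )
                else:
                    cfg = _models.ModelConfig(
                        **{**model_config.__dict__, "algorithm": "cnn",
                           "n_conv_layers": int(v)}
                    )
            elif axis == "feature":
                enc = {**encoder_spec, "scheme": v}
            elif axis == "algorithm":
                cfg = _models.ModelConfig(
                    **{**model_config.__dict__, "algorithm": v}
                )
            else:
                raise ValueError(f"unknown sweep axis {axis!r}")
            result.reports[v] = cross_validate(
                cfg, enc, ds, k=k, seed=seed, train_kwargs=train_kwargs
            )
        except ValueError as exc:
            warnings.warn(f"sweep setting {v!r} skipped: {exc}", RuntimeWarning)
    return result


def paired_t_test(per_fold_a, per_fold_b) -> tuple[float, float]:
    """Two-sided paired Student t-test on fold-wise metric differences.

    Degenerate zero-variance differences: p = 1.0 when the mean difference
    is exactly zero; otherwise t is +/-inf with p = 0.0 and a warning.
    """
    a = np.asarray(per_fold_a, dtype=np.float64)
    b = np.asarray(per_fold_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired t-test requires equal-length fold vectors")
    if a.size < 2:
        raise ValueError("paired t-test requires at least two folds")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        warnings.warn(
            "zero-variance nonzero differences: degenerate paired t-test",
            RuntimeWarning,
        )
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
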