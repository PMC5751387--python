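"""Classifier evaluation: confusion metrics, the Idx model-selection loss,
nested SVM tuning, CCA-based SSVEP recognition, and timing analysis.

The composite model-selection loss used to pick the SVM box constraint is

    Idx = 1 - (0.3 Kappa + 0.3 (1 - FPR_max) + 0.15 ACC + 0.25 PNM_min)

(lower is better, 0 for a perfect classifier).  PNM is a per-class prediction
quality in [-1, 1] that charges both the false negatives of a class and the
false positives attracted to it:

    PNM_i = [(C_ii - sum_{j!=i} C_ij) + (C_ii - sum_{i'!=i} C_{i'i})]
            / (row_i total + column_i total)

SSVEP target recognition follows the standard CCA recipe: for every candidate
stimulus frequency, a sine/cosine reference bank at the fundamental and its
harmonics is correlated canonically with the multichannel epoch and the
candidate with the largest first canonical correlation wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

__all__ = [
    "EvalMetrics",
    "confusion_metrics",
    "idx_metric",
    "tune_and_classify",
    "cca_ssvep_classify",
    "max_canonical_corr",
    "recognition_timing",
    "TimingResult",
]

#: weights of the composite loss components [Kappa, (1 - FPR_max), ACC, PNM_min]
IDX_WEIGHTS = (0.3, 0.3, 0.15, 0.25)


@dataclass
class EvalMetrics:
    """Confusion-matrix-derived metrics for a K-class problem."""

    acc: float
    tpr: np.ndarray            # per class (recall)
    fpr: np.ndarray            # per class
    f1: np.ndarray             # per class
    kappa: float
    pnm: np.ndarray            # per class, in [-1, 1]
    pnm_min: float
    fpr_max: float
    f1_macro: float
    idx: float | None = None
    cm: np.ndarray = field(default=None, repr=False)


def confusion_metrics(cm) -> EvalMetrics:
    """Standard metrics plus PNM from a K x K confusion matrix.

    Rows are true classes, columns predictions.  Degenerate per-class rates
    (empty row or column) are reported as 0.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if cm.sum() <= 0 or np.any(cm < 0):
        raise ValueError("confusion matrix must be nonnegative with positive total")
    total = cm.sum()
    diag = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    acc = diag.sum() / total

    with np.errstate(divide="ignore", invalid="ignore"):
        tpr = np.where(row > 0, diag / row, 0.0)
        fpr = np.where(total - row > 0, (col - diag) / (total - row), 0.0)
        prec = np.where(col > 0, diag / col, 0.0)
        f1 = np.where(prec + tpr > 0, 2 * prec * tpr / (prec + tpr), 0.0)
        pe = float((row * col).sum() / total**2)
        kappa = (acc - pe) / (1.0 - pe) if pe < 1.0 else 1.0
        denom = row + col
        pnm = np.where(
            denom > 0,
            ((diag - (row - diag)) + (diag - (col - diag))) / denom,
            0.0,
        )
    return EvalMetrics(
        acc=float(acc),
        tpr=tpr,
        fpr=fpr,
        f1=f1,
        kappa=float(kappa),
        pnm=pnm,
        pnm_min=float(pnm.min()),
        fpr_max=float(fpr.max()),
        f1_macro=float(f1.mean()),
        cm=cm,
    )


def idx_metric(metrics: EvalMetrics) -> float:
    """Composite model-selection loss; lower is better, 0 when perfect."""
    w = IDX_WEIGHTS
    p = (metrics.kappa, 1.0 - metrics.fpr_max, metrics.acc, metrics.pnm_min)
    return float(1.0 - sum(wi * pi for wi, pi in zip(w, p)))


C_GRID = (0.01, 0.05, 0.1, 1.0, 5.0, 10.0)


def _make_svm(C: float, seed: int | None):
    return make_pipeline(
        StandardScaler(),
        LinearSVC(C=C, class_weight="balanced", random_state=seed, max_iter=20000),
    )


def _cm_from_labels(y_true, y_pred, classes) -> np.ndarray:
    k = len(classes)
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k))
    for t, p in zip(y_true, y_pred):
        cm[lut[t], lut[p]] += 1
    return cm


def tune_and_classify(
    X_train,
    y_train,
    X_test,
    grid=C_GRID,
    k1: int = 2,
    seed: int | None = 0,
):
    """Nested tuning of a linear-margin SVM, then prediction on the test set.

    For every box constraint C in ``grid`` an inner stratified k1-fold CV on
    the training set produces a mean Idx; the C with the smallest mean Idx
    wins (ties go to the smallest C), a fresh classifier is refit on the full
    training set and test predictions are returned.  Class weights are
    balanced so imbalanced window counts do not bias the margin.

    Returns
    -------
    (predictions, chosen_C, idx_table)
        ``idx_table`` maps C -> mean inner-CV Idx.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    classes = sorted(set(y_train.tolist()))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    skf = StratifiedKFold(n_splits=k1, shuffle=True, random_state=seed)
    idx_table: dict[float, float] = {}
    for C in grid:
        losses = []
        for tr, te in skf.split(X_train, y_train):
            clf = _make_svm(C, seed)
            clf.fit(X_train[tr], y_train[tr])
            cm = _cm_from_labels(y_train[te], clf.predict(X_train[te]), classes)
            losses.append(idx_metric(confusion_metrics(cm)))
        idx_table[C] = float(np.mean(losses))
    best = min(idx_table, key=lambda c: (round(idx_table[c], 12), c))
    clf = _make_svm(best, seed)
    clf.fit(X_train, y_train)
    return clf.predict(np.asarray(X_test, dtype=float)), best, idx_table


def max_canonical_corr(X: np.ndarray, Y: np.ndarray) -> float:
    """Largest canonical correlation between column spaces of X and Y.

    Columns are centered; the correlation is the largest singular value of
    Qx' Qy with Qx, Qy orthonormal bases of the centered matrices.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, _ = np.linalg.qr(Xc)
    qy, _ = np.linalg.qr(Yc)
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def cca_ssvep_classify(
    epoch: np.ndarray,
    candidate_freqs,
    fs: float,
    n_harmonics: int = 6,
) -> tuple[float, np.ndarray]:
    """Recognize the SSVEP stimulus frequency of a multichannel epoch.

    For each candidate f a reference bank of sines and cosines at
    f, 2f, ..., n_harmonics f (harmonics above Nyquist are dropped) is built
    and its largest canonical correlation with the epoch channels computed;
    the argmax candidate wins.  Invariant to channel scaling and DC offsets.

    Returns
    -------
    (predicted_frequency, correlations) in candidate order.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[0] < 1:
        raise ValueError("epoch must hold at least one channel")
    T = epoch.shape[1]
    t = np.arange(T) / fs
    X = epoch.T
    corrs = np.empty(len(list(candidate_freqs)))
    freqs = list(candidate_freqs)
    for i, f in enumerate(freqs):
        cols = []
        for h in range(1, n_harmonics + 1):
            if h * f >= fs / 2:
                break
            cols.append(np.sin(2 * np.pi * h * f * t))
            cols.append(np.cos(2 * np.pi * h * f * t))
        if not cols:
            corrs[i] = -np.inf
            continue
        corrs[i] = max_canonical_corr(X, np.column_stack(cols))
    return float(freqs[int(np.argmax(corrs))]), corrs


@dataclass
class TimingResult:
    """Latency and continuous-recognition summary of one prediction stream."""

    latency_ms: float | None     # None when the cycle failed
    run_min_ms: float | None     # median qualifying run length
    run_max_ms: float | None
    failed: bool
    runs_ms: list[float] = field(default_factory=list)


def recognition_timing(
    predictions,
    fs: float,
    planning_label=1,
    persist_ms: float = 88.0,
    interval_start_s: float = -1.5,
) -> TimingResult:
    """Apply the persistence rule to a per-sample prediction stream.

    A planning command is declared when the planning label persists for at
    least ``persist_ms`` (35 samples at 400 Hz).  Latency is the time, in ms
    relative to the movement onset at 0, at which the first qualifying run
    completes the persistence requirement (negative = anticipation).  The
    "minimum" and "maximum" continuous-recognition intervals are the median
    and maximum lengths of the qualifying runs; a stream with no qualifying
    run is a failed cycle.
    """
    pred = np.asarray(predictions)
    persist = int(round(persist_ms * fs / 1000.0))
    is_plan = pred == planning_label
    # run-length encode
    runs = []  # (start, length)
    start = None
    for i, v in enumerate(is_plan):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(is_plan) - start))
    qual = [(s, ln) for s, ln in runs if ln >= persist]
    if not qual:
        return TimingResult(None, None, None, True)
    ms = 1000.0 / fs
    lat = interval_start_s * 1000.0 + (qual[0][0] + persist) * ms
    lens = [ln * ms for _, ln in qual]
    return TimingResult(
        latency_ms=float(lat),
        run_min_ms=float(np.median(lens)),
        run_max_ms=float(max(lens)),
        failed=False,
        runs_ms=lens,
    )
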