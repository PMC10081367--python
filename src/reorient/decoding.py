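"""Trial-level decoding of heading and context from place-cell activity.

Three decoders mirror the session-level prediction analyses:

* rotation-sequence decoding of heading -- each cell's binary rotation
  bit on each trial is a feature; a linear max-margin classifier
  (support-vector machine, linear kernel, empirical class prior) is
  cross-validated leave-one-out to predict whether the animal dug at the
  rewarded (C) or geometrically equivalent (G) corner;
* population dot-product decoding of context -- the held-out trial's
  population maps are compared with each context's average aligned maps
  (rebuilt without the held-out trial) by mean per-pixel cosine;
* rate decoding -- per-trial mean firing rates feed the same linear SVM
  to predict context (on C/G trials only) or digging side.

All decoders are deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "TrialFeatureMatrix",
    "LOOResult",
    "RateMatrix",
    "build_rotation_features",
    "loo_linear_classifier",
    "predict_heading",
    "predict_context_dotproduct",
    "rate_difference_matrix",
    "predict_from_rates",
]


@dataclass
class TrialFeatureMatrix:
    """Trials x cells feature matrix with one binary label per trial."""

    X: np.ndarray
    y: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix has missing entries")
        if len(np.unique(self.y)) > 2:
            raise ValueError("labels must be binary")


@dataclass
class LOOResult:
    predictions: np.ndarray
    y_true: np.ndarray
    accuracy: float
    n: int
    flagged_trials: list = field(default_factory=list)
    skipped_trials: list = field(default_factory=list)


@dataclass
class RateMatrix:
    """Trials x trials absolute mean-firing-rate differences for one cell."""

    matrix: np.ndarray
    within_mean: float = float("nan")
    across_mean: float = float("nan")


def build_rotation_features(
    sequences, labels, trial_ids=None
) -> TrialFeatureMatrix:
    """Stack per-cell rotation sequences into a trials x cells matrix.

    ``sequences`` is an iterable of equal-length binary sequences (one per
    cell).  Cells whose sequence is constant contribute constant columns;
    they are retained (the classifier simply ignores them).
    """
    seqs = [np.asarray(s) for s in sequences]
    if not seqs:
        raise ValueError("need at least one cell sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all rotation sequences must have the same length")
    X = np.stack(seqs, axis=1).astype(float)
    labels = np.asarray(labels)
    if trial_ids is None:
        trial_ids = np.arange(X.shape[0])
    classes = np.unique(labels)
    if len(classes) < 1:
        raise ValueError("need at least one trial per class")
    return TrialFeatureMatrix(X=X, y=labels, trial_ids=np.asarray(trial_ids))


def _fit_predict(X_train, y_train, x_test, C: float):
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_train, y_train)
    return clf.predict(x_test[None, :])[0]


def loo_linear_classifier(features: TrialFeatureMatrix, C: float = 1.0) -> LOOResult:
    """Leave-one-out cross-validated linear SVM.

    The empirical class prior is implicit in unit per-sample weights:
    each training trial counts equally, so class influence is
    proportional to training-fold class frequency.  If a training fold
    loses a class entirely, the held-out trial is assigned the fold's
    majority class and flagged.
    """
    X, y = features.X, features.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes and at least 2 trials per class")
    preds = np.empty(len(y), dtype=y.dtype)
    flagged = []
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        y_tr = y[keep]
        tr_classes, tr_counts = np.unique(y_tr, return_counts=True)
        if len(tr_classes) < 2:
            preds[i] = tr_classes[np.argmax(tr_counts)]
            flagged.append(int(features.trial_ids[i]))
            continue
        preds[i] = _fit_predict(X[keep], y_tr, X[i], C)
    acc = float(np.mean(preds == y))
    return LOOResult(
        predictions=preds,
        y_true=y,
        accuracy=acc,
        n=len(y),
        flagged_trials=flagged,
    )


def predict_heading(
    sequences, dig_labels, trial_ids=None, C: float = 1.0
) -> LOOResult:
    """Predict C- vs G-side digs from rotation-sequence features.

    Trials with N or F digs (geometrically incorrect corners) are
    excluded; only C and G search trials train the classifier.
    """
    dig_labels = np.asarray(dig_labels)
    keep = np.isin(dig_labels, ("C", "G"))
    if not keep.any():
        raise ValueError("no C/G trials to decode heading from")
    seqs = [np.asarray(s)[keep] for s in sequences]
    ids = (
        np.asarray(trial_ids)[keep]
        if trial_ids is not None
        else np.flatnonzero(keep)
    )
    feats = build_rotation_features(seqs, dig_labels[keep], ids)
    return loo_linear_classifier(feats, C=C)


def _mean_pixel_cosine(stack_trial: np.ndarray, stack_avg: np.ndarray) -> float:
    """Mean over pixels of the across-cell cosine between a held-out
    trial's population maps and a context-average population map."""
    n_cells = stack_trial.shape[0]
    T = stack_trial.reshape(n_cells, -1)
    A = stack_avg.reshape(n_cells, -1)
    vals = []
    for p in range(T.shape[1]):
        ok = np.isfinite(T[:, p]) & np.isfinite(A[:, p])
        u, v = T[ok, p], A[ok, p]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if ok.sum() == 0 or nu == 0 or nv == 0:
            continue
        vals.append(u @ v / (nu * nv))
    return float(np.mean(vals)) if vals else float("nan")


def predict_context_dotproduct(aligned_maps: np.ndarray, contexts) -> LOOResult:
    """Leave-one-out context prediction from firing-location population maps.

    ``aligned_maps`` is ``(n_cells, n_trials, n_rows, n_cols)`` of already
    rotation-aligned trial maps.  For each held-out trial the per-cell
    context averages are rebuilt without it and the context whose average
    population maps have the higher mean per-pixel cosine with the
    held-out maps wins; exact ties go to the first context label
    (flagged).  Trials whose own context would be left with no training
    trials are skipped and counted.
    """
    aligned_maps = np.asarray(aligned_maps, float)
    contexts = np.asarray(contexts)
    n_cells, n_trials = aligned_maps.shape[:2]
    if n_trials != len(contexts):
        raise ValueError("one context label per trial required")
    ctx_order = list(dict.fromkeys(contexts.tolist()))
    if len(ctx_order) != 2:
        raise ValueError("both contexts must be represented")
    preds, truth, flagged, skipped = [], [], [], []
    for i in range(n_trials):
        keep = np.ones(n_trials, dtype=bool)
        keep[i] = False
        if np.sum(contexts[keep] == contexts[i]) == 0:
            skipped.append(i)
            continue
        scores = {}
        for ctx in ctx_order:
            sel = keep & (contexts == ctx)
            sub = aligned_maps[:, sel]
            finite = np.isfinite(sub)
            counts = finite.sum(axis=1)
            avg = np.where(
                counts > 0,
                np.where(finite, sub, 0.0).sum(axis=1) / np.maximum(counts, 1),
                np.nan,
            )
            scores[ctx] = _mean_pixel_cosine(aligned_maps[:, i], avg)
        a, b = ctx_order
        sa = scores[a] if np.isfinite(scores[a]) else -np.inf
        sb = scores[b] if np.isfinite(scores[b]) else -np.inf
        if sa == sb:
            pred = a  # deterministic tie-break, flagged
            flagged.append(i)
        else:
            pred = a if sa > sb else b
        preds.append(pred)
        truth.append(contexts[i])
    preds = np.asarray(preds)
    truth = np.asarray(truth)
    acc = float(np.mean(preds == truth)) if len(preds) else float("nan")
    return LOOResult(
        predictions=preds,
        y_true=truth,
        accuracy=acc,
        n=len(preds),
        flagged_trials=flagged,
        skipped_trials=skipped,
    )


def rate_difference_matrix(mfr_by_trial, contexts=None) -> RateMatrix:
    """Pairwise absolute mean-firing-rate differences for one cell."""
    r = np.asarray(mfr_by_trial, float)
    if r.size < 2:
        raise ValueError("need at least 2 trials")
    mat = np.abs(r[:, None] - r[None, :])
    within = across = float("nan")
    if contexts is not None:
        ctx = np.asarray(contexts)
        same = ctx[:, None] == ctx[None, :]
        triu = np.triu(np.ones_like(mat, dtype=bool), k=1)
        if np.any(triu & same):
            within = float(mat[triu & same].mean())
        if np.any(triu & ~same):
            across = float(mat[triu & ~same].mean())
    return RateMatrix(matrix=mat, within_mean=within, across_mean=across)


def predict_from_rates(
    mfr: np.ndarray,
    contexts,
    digs,
    label_type: str = "context",
    C: float = 1.0,
) -> LOOResult:
    """Linear-SVM LOO decoding from per-trial mean firing rates.

    ``label_type="context"`` predicts context A vs B using only trials in
    which the animal identified the context (C or G digs);
    ``label_type="heading-side"`` predicts C- vs G-side digs.
    """
    mfr = np.asarray(mfr, float)
    contexts = np.asarray(contexts)
    digs = np.asarray(digs)
    keep = np.isin(digs, ("C", "G"))
    if label_type == "context":
        labels = contexts[keep]
    elif label_type == "heading-side":
        labels = digs[keep]
    else:
        raise ValueError("label_type must be 'context' or 'heading-side'")
    feats = TrialFeatureMatrix(
        X=mfr[keep], y=labels, trial_ids=np.flatnonzero(keep)
    )
    return loo_linear_classifier(feats, C=C)
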