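"""Classification metrics, ROC/AUROC, and cross-validation orchestration.

AUROC is computed in the Mann-Whitney formulation — the probability that a
random positive outranks a random negative, ties counted one half — which
is exactly the area under the threshold-swept ROC curve.  Cross-validation
runs the full extractor + ELM pipeline per fold, training on the training
split only; leave-one-out pools the held-out scores into a single ROC
(the only way a ROC is defined when each test set holds one sample),
while k-fold reports per-fold metrics with mean and standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .cnn import CNNConfig, train_extractor, extract
from .elm import elm_fit, elm_score
from .pair_features import LabeledPairSet


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class CVPlan:
    """Fold assignment for LOOCV or stratified k-fold."""

    scheme: str  # {"loocv", "kfold"}
    k: int
    fold_of: np.ndarray  # sample -> fold id
    seed: int


@dataclass
class PipelineSettings:
    """Per-fold pipeline configuration: feature extractor + ELM."""

    extractor_mode: str = "identity"  # {"identity", "cnn"}
    cnn: CNNConfig | None = None
    n_hidden: int = 500
    activation: str = "sigmoid"
    # unit ridge: sigmoid random-feature H is ill-conditioned (smallest
    # singular values ~1e-4 of the largest), so the exact least-squares
    # solution amplifies sampling noise at test time
    l2: float = 1.0
    seed: int = 0
    threshold: float = 0.5


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions have different lengths")
    return ConfusionCounts(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and MCC from counts."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return {
        "acc": _safe_div(tn + tp, c.total, "accuracy"),
        "sen": _safe_div(tp, tp + fn, "sensitivity"),
        "spec": _safe_div(tn, tn + fp, "specificity"),
        "prec": _safe_div(tp, tp + fp, "precision"),
        "mcc": _safe_div(tp * tn - fp * fn, mcc_den, "MCC"),
    }


def roc_auroc(labels: np.ndarray, scores: np.ndarray):
    """ROC curve points and AUROC (Mann-Whitney, ties count 1/2).

    Returns ``(curve, auroc)`` where curve is an array of (fpr, tpr)
    points swept over the unique score thresholds, from (0,0) to (1,1).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores have different lengths")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auroc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep one point per distinct threshold (last index of each score value)
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    curve = np.column_stack([fpr, tpr])
    return curve, float(auroc)


def make_cv_plan(
    labels: np.ndarray, scheme: str = "kfold", k: int = 5, seed: int = 0
) -> CVPlan:
    """Assign samples to folds: singleton folds for LOOCV, else a
    label-stratified seeded shuffle into k folds of near-equal size."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    if scheme == "loocv":
        return CVPlan("loocv", n, np.arange(n), seed)
    if scheme != "kfold":
        raise ValueError(f"unknown CV scheme: {scheme!r}")
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n_samples], got {k}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % k
    return CVPlan("kfold", k, fold_of, seed)


def _fit_and_score(
    train: LabeledPairSet,
    test_vectors: np.ndarray,
    settings: PipelineSettings,
    fold_seed: int,
) -> np.ndarray:
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training split contains a single class")
    cnn_cfg = settings.cnn
    if settings.extractor_mode == "cnn" and cnn_cfg is not None:
        cnn_cfg = CNNConfig(
            conv_blocks=list(cnn_cfg.conv_blocks),
            dense_units=cnn_cfg.dense_units,
            epochs=cnn_cfg.epochs,
            batch_size=cnn_cfg.batch_size,
            learning_rate=cnn_cfg.learning_rate,
            seed=fold_seed,
        )
    extractor = train_extractor(train, cnn_cfg, mode=settings.extractor_mode)
    model = elm_fit(
        extract(extractor, train.vectors),
        train.labels,
        n_hidden=settings.n_hidden,
        activation=settings.activation,
        seed=fold_seed,
        l2=settings.l2,
    )
    return elm_score(model, extract(extractor, test_vectors))


def run_cv(
    dataset: LabeledPairSet, plan: CVPlan, settings: PipelineSettings | None = None
) -> dict:
    """Cross-validate the extractor + ELM pipeline under a fold plan.

    Returns a report dict: for LOOCV the pooled AUROC and pooled point
    metrics; for k-fold a per-fold table plus mean and standard deviation
    of each metric, mirroring the usual cross-validation summary.
    """
    if settings is None:
        settings = PipelineSettings()
    folds = np.unique(plan.fold_of)
    if plan.fold_of.shape[0] != dataset.n_samples:
        raise ValueError("fold plan does not cover the dataset")

    if plan.scheme == "loocv":
        pooled = np.empty(dataset.n_samples)
        for f in folds:
            test_idx = np.flatnonzero(plan.fold_of == f)
            train_idx = np.flatnonzero(plan.fold_of != f)
            scores = _fit_and_score(
                dataset.subset(train_idx),
                dataset.vectors[test_idx],
                settings,
                settings.seed + int(f),
            )
            pooled[test_idx] = scores
        _, auroc = roc_auroc(dataset.labels, pooled)
        point = metrics(
            confusion(dataset.labels, (pooled >= settings.threshold).astype(int))
        )
        return {"scheme": "loocv", "auroc": auroc, "pooled_scores": pooled, **point}

    per_fold: list[dict] = []
    for f in folds:
        test_idx = np.flatnonzero(plan.fold_of == f)
        train_idx = np.flatnonzero(plan.fold_of != f)
        scores = _fit_and_score(
            dataset.subset(train_idx),
            dataset.vectors[test_idx],
            settings,
            settings.seed + int(f),
        )
        y = dataset.labels[test_idx]
        _, auroc = roc_auroc(y, scores)
        point = metrics(confusion(y, (scores >= settings.threshold).astype(int)))
        per_fold.append({"fold": int(f), "auroc": auroc, **point})

    names = ["acc", "sen", "spec", "prec", "mcc", "auroc"]
    summary = {
        name: {
            "mean": float(np.mean([fr[name] for fr in per_fold])),
            "sd": float(np.std([fr[name] for fr in per_fold])),
        }
        for name in names
    }
    return {"scheme": "kfold", "k": plan.k, "folds": per_fold, "summary": summary}
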