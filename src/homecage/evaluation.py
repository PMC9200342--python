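"""Leakage-safe leave-one-out cross-validation and multi-class metrics.

Every observation (one bin) takes a turn as a singleton test set. For each
fold, standardisation parameters, class weights and — for the deep model —
CWT scaleograms are recomputed from the training portion only, so no
information from the held-out bin can leak into its own fold's
preprocessing. Metrics follow the usual multi-class extension: per-class
precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R), macro-averaged as
the unweighted mean over classes (0/0 ratios resolve to 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import cwt as cwt_mod
from .preprocess import (
    BinnedObservation,
    RecordFeatureSet,
    StandardizationParams,
    apply_standardizer,
    class_weights,
    fit_standardizer,
    record_features,
    sequence_features,
    smote_oversample,
    train_val_test_split,
)

N_CLASSES = 3


@dataclass
class FoldPrediction:
    """Outcome of one LOOCV fold (one held-out observation)."""

    index: int
    y_true: int
    y_pred: int | None
    proba: np.ndarray | None = None
    error: str | None = None
    standardizer: StandardizationParams | None = None
    weights: dict[int, float] | None = None

    @property
    def valid(self) -> bool:
        return self.error is None and self.y_pred is not None


@dataclass
class MetricsReport:
    """Accuracy, per-class and averaged precision/recall/F1, confusion matrix."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    confusion: np.ndarray  # (K, K) counts, rows = true, columns = predicted
    n: int


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def _stratified_fold_subset(labels: np.ndarray, max_folds: int, seed: int) -> np.ndarray:
    """Pick ``max_folds`` observation indices with class shares preserved."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    exact = counts * max_folds / labels.size
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    for c in np.argsort(-remainder)[: max_folds - alloc.sum()]:
        alloc[c] += 1
    chosen = []
    for c, n_c in zip(classes, alloc):
        idx = np.nonzero(labels == c)[0]
        chosen.append(rng.choice(idx, size=min(n_c, idx.size), replace=False))
    return np.sort(np.concatenate(chosen))


def loocv(
    observations: Sequence[BinnedObservation],
    model_factory: Callable[[int], object],
    *,
    mode: str = "record",
    target_len: int = 48,
    scales=cwt_mod.DEFAULT_SCALES,
    wavelet: str = cwt_mod.DEFAULT_WAVELET,
    seed: int = 0,
    max_folds: int | None = None,
    capture_fold_state: bool = False,
) -> list[FoldPrediction]:
    """Leave-one-out cross-validation over binned observations.

    Parameters
    ----------
    observations
        The dataset; each element takes a turn as the singleton test set.
    model_factory
        ``model_factory(fold_seed) -> classifier`` with
        ``fit(inputs, labels, class_weight)`` and ``predict``. In ``record``
        mode the classifier receives an (n, 4) feature table; in ``sequence``
        mode a ``(sequences, scaleograms)`` pair.
    max_folds
        Optional stratified subsample of fold indices for reduced-scale
        runs; each selected fold still trains on all other observations.

    A training fold that loses a class entirely is reported as an invalid
    fold (``error`` set), never silently skipped.
    """
    n = len(observations)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 observations")
    if mode not in ("record", "sequence"):
        raise ValueError("mode must be 'record' or 'sequence'")

    if mode == "record":
        feats = record_features(list(observations))
        all_x, all_y = feats.features, feats.labels
        tensor = None
    else:
        tensor = sequence_features(list(observations), target_len=target_len)
        all_x, all_y = tensor.data, tensor.labels

    fold_indices = np.arange(n)
    if max_folds is not None and max_folds < n:
        fold_indices = _stratified_fold_subset(all_y, max_folds, seed)

    predictions: list[FoldPrediction] = []
    for i in fold_indices:
        train_idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        y_train = all_y[train_idx]
        if np.unique(y_train).size < 2:
            predictions.append(
                FoldPrediction(
                    index=int(i),
                    y_true=int(all_y[i]),
                    y_pred=None,
                    error="training fold lost a class",
                )
            )
            continue
        weights = class_weights(y_train)
        if mode == "record":
            params = fit_standardizer(all_x[train_idx])
            x_train = apply_standardizer(params, all_x[train_idx])
            x_test = apply_standardizer(params, all_x[i : i + 1])
            train_inputs, test_inputs = x_train, x_test
        else:
            mask_train, mask_test = tensor.mask[train_idx], tensor.mask[i : i + 1]
            params = fit_standardizer(all_x[train_idx], mask=mask_train)
            seq_train = apply_standardizer(params, all_x[train_idx], mask=mask_train)
            seq_test = apply_standardizer(params, all_x[i : i + 1], mask=mask_test)
            scal_train = cwt_mod.batch_scaleograms(seq_train, scales, wavelet).data
            scal_test = cwt_mod.batch_scaleograms(seq_test, scales, wavelet).data
            train_inputs = (seq_train, scal_train)
            test_inputs = (seq_test, scal_test)

        model = model_factory(_fold_seed(seed, int(i)))
        model.fit(train_inputs, y_train, class_weight=weights)
        proba = None
        if hasattr(model, "predict_proba"):
            try:
                proba = np.asarray(model.predict_proba(test_inputs))[0]
            except (AttributeError, NotImplementedError):
                proba = None
        y_pred = int(np.asarray(model.predict(test_inputs))[0])
        predictions.append(
            FoldPrediction(
                index=int(i),
                y_true=int(all_y[i]),
                y_pred=y_pred,
                proba=proba,
                standardizer=params if capture_fold_state else None,
                weights=weights if capture_fold_state else None,
            )
        )
    return predictions


def fixed_split_smote_report(
    observations: Sequence[BinnedObservation],
    model_factory: Callable[[int], object],
    *,
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
    k: int = 5,
    use_smote: bool = True,
    seed: int = 0,
) -> MetricsReport:
    """Single stratified-split evaluation with optional SMOTE on the training set.

    SMOTE resamples training folds only, so it cannot be compared fairly
    under LOOCV (the resampled dataset is not the original one); this
    fixed-split report is the companion evaluation for oversampling. The
    held-out rows are never resampled or otherwise modified. Shallow
    (record-feature) models only.
    """
    feats = record_features(list(observations))
    train_idx, _, test_idx = train_val_test_split(feats.labels, ratios, seed=seed)
    params = fit_standardizer(feats.features[train_idx])
    x_train = apply_standardizer(params, feats.features[train_idx])
    y_train = feats.labels[train_idx]
    if use_smote:
        augmented = smote_oversample(
            RecordFeatureSet(features=x_train, labels=y_train), k=k, seed=seed
        )
        x_train = augmented.features.features
        y_train = augmented.features.labels
    x_test = apply_standardizer(params, feats.features[test_idx])
    model = model_factory(seed)
    model.fit(x_train, y_train, class_weight=None if use_smote else class_weights(y_train))
    y_pred = np.asarray(model.predict(x_test), dtype=int)
    preds = [
        FoldPrediction(index=int(i), y_true=int(t), y_pred=int(p))
        for i, t, p in zip(test_idx, feats.labels[test_idx], y_pred)
    ]
    return compute_metrics(preds)


def compute_metrics(
    predictions: Sequence[FoldPrediction], n_classes: int = N_CLASSES
) -> MetricsReport:
    """Confusion matrix and (macro / weighted) precision, recall, F1.

    Macro-F1 is the unweighted mean of per-class F1 values (not the harmonic
    mean of macro precision and macro recall).
    """
    if not predictions:
        raise ValueError("no predictions")
    invalid = [p for p in predictions if not p.valid]
    if invalid:
        raise ValueError(
            f"{len(invalid)} invalid fold(s), e.g. fold {invalid[0].index}: {invalid[0].error}"
        )
    y_true = np.array([p.y_true for p in predictions], dtype=int)
    y_pred = np.array([p.y_pred for p in predictions], dtype=int)
    if ((y_true < 0) | (y_true >= n_classes) | (y_pred < 0) | (y_pred >= n_classes)).any():
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (y_true, y_pred), 1)
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    support = confusion.sum(axis=1)
    w = support / support.sum()
    return MetricsReport(
        accuracy=float(tp.sum() / len(y_true)),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float((precision * w).sum()),
        weighted_recall=float((recall * w).sum()),
        weighted_f1=float((f1 * w).sum()),
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        confusion=confusion,
        n=len(y_true),
    )


def pca_embedding(
    features: RecordFeatureSet | np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred projection onto the leading principal axes.

    Returns ``(coordinates, explained_variance_fractions)``. The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA

    x = features.features if isinstance(features, RecordFeatureSet) else np.asarray(features)
    if x.shape[0] <= n_components:
        raise ValueError("need more observations than components")
    if np.allclose(x, x[0]):
        raise ValueError("constant dataset: PCA is degenerate")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(x)
    for k, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            coords[:, k] *= -1.0
    return coords, pca.explained_variance_ratio_


def evaluation_report(
    metrics_by_model: dict[str, MetricsReport],
    out_dir: str | Path | None = None,
) -> str:
    """Deterministic text table of model performance; optional plot files.

    With ``out_dir`` set, writes ``report.txt`` and one confusion-matrix PNG
    per model.
    """
    if not metrics_by_model:
        raise ValueError("no metrics to report")
    header = f"{'model':<12} {'accuracy %':>10} {'precision':>10} {'recall':>10} {'F1':>10}"
    lines = [header, "-" * len(header)]
    for name in sorted(metrics_by_model):
        m = metrics_by_model[name]
        lines.append(
            f"{name:<12} {100 * m.accuracy:>10.2f} {m.macro_precision:>10.3f} "
            f"{m.macro_recall:>10.3f} {m.macro_f1:>10.3f}"
        )
    table = "\n".join(lines) + "\n"
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.txt").write_text(table)
        for name, m in metrics_by_model.items():
            _plot_confusion(m.confusion, name, out_dir / f"confusion_{name}.png")
    return table


def _plot_confusion(confusion: np.ndarray, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(confusion, cmap="Blues")
    for (r, c), v in np.ndenumerate(confusion):
        ax.text(c, r, str(v), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_xticks(range(confusion.shape[1]), ["naive", "injured", "sham"])
    ax.set_yticks(range(confusion.shape[0]), ["naive", "injured", "sham"])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
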