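"""Dataset construction from animal-week records.

Each animal-week record (290 samples by default) is split into ``n_bins``
contiguous bins (default 6); a bin is the unit of classification. Two
dataset styles are built from bins:

* record-style — the per-channel mean of each bin, a 4-feature row, for the
  shallow classifiers (SVM, random forest, feed-forward network);
* sequence-style — the full bin content zero-padded (or tail-truncated) to a
  common length of 48 time steps, for the dual-branch deep network.

Also implemented here: training-set-only standardisation, balanced class
weights for the loss, SMOTE oversampling for record features, and a
stratified train/validation/test split utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .records import CHANNELS, CLASS_LABELS, AnimalRecord

logger = logging.getLogger(__name__)

MAX_BINS = 20


@dataclass
class BinnedObservation:
    """One bin of one animal-week: the unit of classification."""

    animal_id: str
    group: str
    week: int
    bin_index: int
    segment: np.ndarray  # (m, 4) channel samples
    label: int

    def __post_init__(self) -> None:
        self.segment = np.asarray(self.segment, dtype=float)
        if self.segment.ndim != 2 or self.segment.shape[1] != len(CHANNELS):
            raise ValueError(f"segment must have shape (m, {len(CHANNELS)})")
        if self.segment.shape[0] == 0:
            raise ValueError("segment must be non-empty")
        if self.label != CLASS_LABELS[self.group]:
            raise ValueError("label inconsistent with group")


@dataclass
class RecordFeatureSet:
    """Per-bin channel means with labels (shallow-model dataset)."""

    features: np.ndarray  # (N, 4)
    labels: np.ndarray  # (N,)
    index: list[tuple[str, int, int]] = field(default_factory=list)  # (animal, week, bin)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features/labels length mismatch")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")

    def __len__(self) -> int:
        return int(self.labels.shape[0])


@dataclass
class SequenceTensor:
    """Zero-padded per-bin sequences with labels (deep-model input 1)."""

    data: np.ndarray  # (N, target_len, 4)
    labels: np.ndarray  # (N,)
    mask: np.ndarray  # (N, target_len) True where the position holds real data

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[:2] != self.mask.shape:
            raise ValueError("data/mask shape mismatch")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("data/labels length mismatch")

    def __len__(self) -> int:
        return int(self.labels.shape[0])


def bin_observations(records: list[AnimalRecord], n_bins: int = 6) -> list[BinnedObservation]:
    """Split each record into ``n_bins`` contiguous, order-preserving bins.

    When the record length is not divisible by ``n_bins`` the remainder
    samples go one-each to the earliest bins (290 over 6 bins gives lengths
    49, 49, 48, 48, 48, 48). Concatenating the segments of a record
    reproduces the record exactly.
    """
    if not 1 <= n_bins <= MAX_BINS:
        raise ValueError(f"n_bins must be in [1, {MAX_BINS}]")
    observations: list[BinnedObservation] = []
    for rec in records:
        if rec.n_samples < n_bins:
            raise ValueError(
                f"record {rec.animal_id!r} week {rec.week} has {rec.n_samples} samples "
                f"< {n_bins} bins"
            )
        for bin_index, segment in enumerate(np.array_split(rec.values, n_bins)):
            observations.append(
                BinnedObservation(
                    animal_id=rec.animal_id,
                    group=rec.group,
                    week=rec.week,
                    bin_index=bin_index,
                    segment=segment,
                    label=CLASS_LABELS[rec.group],
                )
            )
    return observations


def record_features(observations: list[BinnedObservation]) -> RecordFeatureSet:
    """Per-bin arithmetic channel means: the record-style dataset."""
    if not observations:
        raise ValueError("no observations")
    features = np.stack([obs.segment.mean(axis=0) for obs in observations])
    labels = np.array([obs.label for obs in observations], dtype=int)
    index = [(obs.animal_id, obs.week, obs.bin_index) for obs in observations]
    return RecordFeatureSet(features=features, labels=labels, index=index)


def sequence_features(
    observations: list[BinnedObservation], target_len: int = 48
) -> SequenceTensor:
    """Sequence-style dataset: bins zero-padded / tail-truncated to ``target_len``."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    n = len(observations)
    data = np.zeros((n, target_len, len(CHANNELS)))
    mask = np.zeros((n, target_len), dtype=bool)
    labels = np.empty(n, dtype=int)
    for i, obs in enumerate(observations):
        m = min(obs.segment.shape[0], target_len)
        data[i, :m] = obs.segment[:m]
        mask[i, :m] = True
        labels[i] = obs.label
    return SequenceTensor(data=data, labels=labels, mask=mask)


# ---------------------------------------------------------------------------
# Standardisation (training subset only)
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    """Per-feature (record) or per-channel (sequence) z-score parameters."""

    mean: np.ndarray
    sd: np.ndarray
    mode: str  # "record" | "sequence"


def fit_standardizer(
    train: np.ndarray | RecordFeatureSet | SequenceTensor,
    mask: np.ndarray | None = None,
) -> StandardizationParams:
    """Estimate z-score parameters on a training subset only.

    Record mode (2-D input): one (mean, sd) per feature column. Sequence
    mode (3-D input): one (mean, sd) per channel, pooled over time but
    restricted to unpadded positions given by ``mask``. Zero-variance
    features get sd replaced by 1 (with a logged warning).
    """
    if isinstance(train, RecordFeatureSet):
        train = train.features
    elif isinstance(train, SequenceTensor):
        mask = train.mask if mask is None else mask
        train = train.data
    x = np.asarray(train, dtype=float)
    if x.size == 0:
        raise ValueError("training subset is empty")
    if x.ndim == 2:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        mode = "record"
    elif x.ndim == 3:
        if mask is None:
            mask = np.ones(x.shape[:2], dtype=bool)
        valid = x[mask]  # (n_valid_positions, channels)
        mean = valid.mean(axis=0)
        sd = valid.std(axis=0)
        mode = "sequence"
    else:
        raise ValueError("expected a 2-D feature table or 3-D sequence tensor")
    zero = sd <= 0
    if zero.any():
        logger.warning("zero-variance feature(s) %s; sd set to 1", np.nonzero(zero)[0])
        sd = np.where(zero, 1.0, sd)
    return StandardizationParams(mean=mean, sd=sd, mode=mode)


def apply_standardizer(
    params: StandardizationParams,
    data: np.ndarray | RecordFeatureSet | SequenceTensor,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the z-score transform; padded sequence positions stay exactly 0."""
    if isinstance(data, RecordFeatureSet):
        data = data.features
    elif isinstance(data, SequenceTensor):
        mask = data.mask if mask is None else mask
        data = data.data
    x = (np.asarray(data, dtype=float) - params.mean) / params.sd
    if params.mode == "sequence" and mask is not None:
        x = np.where(mask[..., None], x, 0.0)
    return x


# ---------------------------------------------------------------------------
# Class imbalance handling
# ---------------------------------------------------------------------------

def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Balanced class weights ``w_c = N / (K * n_c)`` for the training loss.

    The minority class receives the largest weight and
    ``sum_c n_c * w_c == N``.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("class weights need >= 2 distinct classes")
    n, k = labels.size, classes.size
    return {int(c): n / (k * int(nc)) for c, nc in zip(classes, counts)}


@dataclass
class SmoteResult:
    """Augmented feature set plus the provenance of each synthetic row."""

    features: RecordFeatureSet
    n_original: int
    parents: np.ndarray  # (n_synthetic, 2) indices into the original rows
    gaps: np.ndarray  # (n_synthetic,) interpolation coefficient u in [0, 1]


def smote_oversample(features: RecordFeatureSet, k: int = 5, seed: int = 0) -> SmoteResult:
    """SMOTE: balance class counts by interpolating minority samples.

    Every synthetic point is ``x_i + u * (x_j - x_i)`` with ``u ~ U[0, 1]``
    and ``x_j`` one of the ``k`` nearest same-class neighbours of ``x_i``
    (``k`` capped at class size − 1). Original rows are preserved verbatim
    and come first; classes already at the majority count are untouched.
    Intended for training data only — never for evaluation folds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x, y = features.features, features.labels
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    rng = np.random.default_rng(seed)
    new_rows, new_labels, parents, gaps = [], [], [], []
    for c, n_c in zip(classes, counts):
        deficit = int(majority - n_c)
        if deficit == 0:
            continue
        if n_c < 2:
            raise ValueError(f"class {int(c)} has {int(n_c)} sample(s); SMOTE needs >= 2")
        idx = np.nonzero(y == c)[0]
        xc = x[idx]
        k_eff = min(k, int(n_c) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(xc)
        neigh = nn.kneighbors(xc, return_distance=False)[:, 1:]  # drop self
        for _ in range(deficit):
            i = int(rng.integers(0, len(idx)))
            j = int(neigh[i][int(rng.integers(0, k_eff))])
            u = float(rng.random())
            new_rows.append(xc[i] + u * (xc[j] - xc[i]))
            new_labels.append(int(c))
            parents.append((int(idx[i]), int(idx[j])))
            gaps.append(u)
    if not new_rows:
        augmented = RecordFeatureSet(
            features=x.copy(), labels=y.copy(), index=list(features.index)
        )
        return SmoteResult(
            features=augmented,
            n_original=len(features),
            parents=np.empty((0, 2), dtype=int),
            gaps=np.empty(0),
        )
    augmented = RecordFeatureSet(
        features=np.vstack([x, np.stack(new_rows)]),
        labels=np.concatenate([y, np.array(new_labels, dtype=int)]),
        index=list(features.index) + [("synthetic", -1, -1)] * len(new_rows),
    )
    return SmoteResult(
        features=augmented,
        n_original=len(features),
        parents=np.array(parents, dtype=int),
        gaps=np.array(gaps),
    )


def train_val_test_split(
    labels: np.ndarray,
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified index split (train, validation, test).

    A provisional-evaluation utility; headline evaluation uses LOOCV.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    labels = np.asarray(labels, dtype=int)
    idx = np.arange(labels.size)
    train_idx, rest_idx = train_test_split(
        idx, test_size=ratios[1] + ratios[2], random_state=seed, stratify=labels
    )
    val_frac = ratios[1] / (ratios[1] + ratios[2])
    val_idx, test_idx = train_test_split(
        rest_idx,
        test_size=1.0 - val_frac,
        random_state=seed,
        stratify=labels[rest_idx],
    )
    return np.sort(train_idx), np.sort(val_idx), np.sort(test_idx)
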