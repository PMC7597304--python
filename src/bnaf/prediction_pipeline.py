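"""Four-class prediction from 30-point fragility-difference features.

Workflow: assemble labelled difference-curve vectors, oversample the
imbalanced training data (SMOTE or ADASYN), select hyperparameters by nested
k-fold cross-validation with inner-loop AUC, train a 1-D CNN, and evaluate
with accuracy, a row-normalized confusion matrix, precision-recall curves
and average precision against prevalence (random-classifier) baselines.

Held-out evaluation always uses the original imbalanced distribution;
oversampling only ever touches training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_curve,
    roc_auc_score,
)
from sklearn.neighbors import NearestNeighbors

from ._cnn import CNNModel, build_cnn
from .antifragility import DifferenceCurve
from .robustness_classification import CLASS_ORDER, RobustnessClass
from .rngutil import substream

__all__ = [
    "FeatureDataset",
    "HyperparameterSet",
    "EvaluationReport",
    "build_dataset",
    "oversample",
    "build_cnn",
    "default_grid",
    "train_model",
    "nested_cross_validation",
    "evaluate",
    "random_baseline_ap",
]

FEATURE_WIDTH = 30
N_CLASSES = len(CLASS_ORDER)


@dataclass(frozen=True)
class FeatureDataset:
    """Rows of 30-point difference curves with class labels and source groups.

    ``labels`` are integer class indices into
    :data:`bnaf.robustness_classification.CLASS_ORDER`.
    """

    features: np.ndarray
    labels: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 2 or (len(f) > 0 and f.shape[1] != FEATURE_WIDTH):
            raise ValueError(f"features must be (n, {FEATURE_WIDTH})")
        if not (len(f) == len(self.labels) == len(self.groups)):
            raise ValueError("features/labels/groups row counts differ")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        object.__setattr__(self, "groups", np.asarray(self.groups))

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, idx) -> "FeatureDataset":
        return FeatureDataset(self.features[idx], self.labels[idx], self.groups[idx])

    def class_counts(self) -> dict[RobustnessClass, int]:
        return {
            c: int((self.labels == i).sum()) for i, c in enumerate(CLASS_ORDER)
        }


@dataclass(frozen=True)
class HyperparameterSet:
    batch_size: int
    balancing: str
    architecture: str
    epochs: int = 128

    def __post_init__(self):
        if self.batch_size not in (32, 64, 128):
            raise ValueError("batch_size must be one of 32/64/128")
        if self.balancing not in ("SMOTE", "ADASYN"):
            raise ValueError("balancing must be SMOTE or ADASYN")
        if self.architecture not in ("simple", "complex"):
            raise ValueError("architecture must be simple or complex")


def default_grid(epochs: int = 128) -> list[HyperparameterSet]:
    """The full 12-set grid: 3 batch sizes x 2 balancers x 2 architectures."""
    return [
        HyperparameterSet(b, bal, arch, epochs)
        for bal in ("SMOTE", "ADASYN")
        for arch in ("simple", "complex")
        for b in (32, 64, 128)
    ]


@dataclass(frozen=True)
class EvaluationReport:
    accuracy: float
    confusion: np.ndarray  # 4x4, rows = actual class, row-normalized
    per_class_ap: dict[RobustnessClass, float]
    micro_ap: float
    auc: float
    pr_curves: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# dataset assembly


def build_dataset(
    comparisons: list[tuple[DifferenceCurve | np.ndarray, RobustnessClass, object]],
) -> FeatureDataset:
    """Stack (difference curve, class, network id) triples into a dataset."""
    feats, labels, groups = [], [], []
    class_index = {c: i for i, c in enumerate(CLASS_ORDER)}
    for curve, cls, gid in comparisons:
        values = curve.values if isinstance(curve, DifferenceCurve) else np.asarray(curve)
        if len(values) != FEATURE_WIDTH:
            raise ValueError(f"difference curve must have {FEATURE_WIDTH} points")
        feats.append(np.asarray(values, dtype=float))
        labels.append(class_index[cls] if isinstance(cls, RobustnessClass) else int(cls))
        groups.append(gid)
    if not feats:
        return FeatureDataset(
            np.empty((0, FEATURE_WIDTH)), np.empty(0, dtype=int), np.empty(0, dtype=object)
        )
    return FeatureDataset(np.vstack(feats), np.array(labels), np.array(groups, dtype=object))


# ---------------------------------------------------------------------------
# oversampling


def _synthesize(
    X_class: np.ndarray,
    seeds: np.ndarray,
    rng: np.random.Generator,
    k_neighbors: int,
) -> np.ndarray:
    """SMOTE-style synthesis: convex combinations with same-class neighbors."""
    k = min(k_neighbors, len(X_class) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_class)
    _, idx = nn.kneighbors(X_class)  # column 0 is the point itself
    picks = idx[seeds, 1 + rng.integers(0, k, size=len(seeds))]
    gaps = rng.random((len(seeds), 1))
    base = X_class[seeds]
    return base + gaps * (X_class[picks] - base)


def oversample(
    train: FeatureDataset, method: str = "SMOTE", seed: int = 0, k_neighbors: int = 5
) -> FeatureDataset:
    """Balance training data by synthesizing minority-class samples.

    SMOTE draws synthesis seeds uniformly within each minority class; ADASYN
    weights them by local difficulty (the fraction of other-class points among
    each sample's nearest neighbors in the full training set). Original rows
    are always retained unchanged; every synthetic row lies on a segment
    between two original same-class rows.
    """
    method = method.upper()
    if method not in ("SMOTE", "ADASYN"):
        raise ValueError("method must be SMOTE or ADASYN")
    y = train.labels
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("oversampling requires at least 2 classes")
    counts = {c: int((y == c).sum()) for c in present}
    target = max(counts.values())
    rng = substream(seed, "oversample", method)

    feats = [train.features]
    labels = [train.labels]
    groups = [train.groups]
    for c in present:
        need = target - counts[c]
        if need == 0:
            continue
        if counts[c] < 2:
            raise ValueError(
                f"class {CLASS_ORDER[c].value} has < 2 members; "
                "cannot synthesize neighbors (consider duplicating rows instead)"
            )
        Xc = train.features[y == c]
        if method == "SMOTE":
            seeds = rng.integers(0, len(Xc), size=need)
        else:
            k = min(k_neighbors, len(train) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(train.features)
            _, idx = nn.kneighbors(Xc)
            neigh_labels = y[idx[:, 1:]]
            r = (neigh_labels != c).mean(axis=1)
            p = r / r.sum() if r.sum() > 0 else np.full(len(Xc), 1.0 / len(Xc))
            seeds = rng.choice(len(Xc), size=need, p=p)
        synth = _synthesize(Xc, seeds, rng, k_neighbors)
        feats.append(synth)
        labels.append(np.full(need, c, dtype=int))
        groups.append(np.full(need, "synthetic", dtype=object))
    return FeatureDataset(
        np.vstack(feats), np.concatenate(labels), np.concatenate(groups)
    )


# ---------------------------------------------------------------------------
# training / evaluation


def train_model(
    data: FeatureDataset, hp: HyperparameterSet, seed: int = 0, lr: float = 1e-3
) -> CNNModel:
    model = build_cnn(hp.architecture, input_len=FEATURE_WIDTH, seed=seed)
    model.fit(
        data.features,
        data.labels,
        epochs=hp.epochs,
        batch_size=hp.batch_size,
        lr=lr,
        seed=seed,
    )
    return model


def evaluate(model: CNNModel, test: FeatureDataset) -> EvaluationReport:
    """Accuracy, row-normalized confusion matrix, PR curves, AP, macro-OVR AUC."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    proba = model.predict_proba(test.features)
    pred = proba.argmax(axis=1)
    y = test.labels
    accuracy = float((pred == y).mean())
    cm = confusion_matrix(y, pred, labels=range(N_CLASSES)).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        cm_norm = np.where(row_sums > 0, cm / row_sums, 0.0)

    per_class_ap: dict[RobustnessClass, float] = {}
    pr_curves: dict[RobustnessClass, tuple] = {}
    onehot = np.zeros((len(y), N_CLASSES))
    onehot[np.arange(len(y)), y] = 1.0
    for i, c in enumerate(CLASS_ORDER):
        pos = onehot[:, i]
        if pos.sum() == 0:
            per_class_ap[c] = float("nan")
            continue
        per_class_ap[c] = float(average_precision_score(pos, proba[:, i]))
        prec, rec, _ = precision_recall_curve(pos, proba[:, i])
        pr_curves[c] = (prec, rec)
    micro_ap = float(average_precision_score(onehot.ravel(), proba.ravel()))
    present = np.unique(y)
    if len(present) > 1:
        auc = float(
            roc_auc_score(y, proba[:, present] if len(present) < N_CLASSES else proba,
                          multi_class="ovr", average="macro", labels=present)
        )
    else:
        auc = float("nan")
    return EvaluationReport(accuracy, cm_norm, per_class_ap, micro_ap, auc, pr_curves)


def _inner_auc(proba: np.ndarray, y: np.ndarray) -> float:
    """Macro one-vs-rest AUC restricted to classes present in ``y``."""
    present = np.unique(y)
    if len(present) < 2:
        return float("nan")
    return float(
        roc_auc_score(y, proba[:, present] if len(present) < proba.shape[1] else proba,
                      multi_class="ovr", average="macro", labels=present)
    )


def nested_cross_validation(
    data: FeatureDataset,
    grid: list[HyperparameterSet] | None = None,
    seed: int = 0,
    k: int = 4,
    test_fraction: float = 0.25,
    inner_rows: int = 3,
    inner_val_fraction: float = 0.33,
    balance_before_inner_split: bool = True,
    lr: float = 1e-3,
) -> tuple[HyperparameterSet, list[EvaluationReport], dict]:
    """Select hyperparameters by nested k-fold CV and report per-fold test metrics.

    The data is split 75/25 into a training portion and a held-out test set;
    the training portion is partitioned into ``k`` outer folds. Per fold, the
    fold-training data is balanced and the inner loop runs ``inner_rows``
    random 67/33 splits, scoring every hyperparameter set by validation AUC.
    AUC is averaged over inner rows, then over folds, and the argmax wins.
    Finally one model per fold is retrained on that fold's balanced training
    data with the winning hyperparameters and evaluated on the untouched,
    imbalanced held-out test set.

    ``balance_before_inner_split=True`` reproduces the published protocol
    (oversample, then split 67/33, which can leak synthetic neighbors across
    the inner split); set it False to balance only the 67% portion.

    Returns ``(best_hyperparameters, per_fold_test_reports, details)`` where
    ``details`` carries the per-hyperparameter AUC table.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y = data.labels
    if len(np.unique(y)) < N_CLASSES:
        raise ValueError("dataset must contain all four classes")

    rng = substream(seed, "cv-split")
    order = rng.permutation(len(data))
    n_test = int(round(len(data) * test_fraction))
    test_idx, train_idx = order[:n_test], order[n_test:]
    if len(np.unique(y[train_idx])) < N_CLASSES:
        raise ValueError("a class is absent from the training portion")

    folds = np.array_split(rng.permutation(train_idx), k)
    balancers = sorted({hp.balancing for hp in grid})
    auc_table = {hp: [] for hp in grid}

    for f in range(k):
        fold_train_idx = np.concatenate([folds[j] for j in range(k) if j != f])
        fold_train = data.subset(fold_train_idx)
        balanced = {
            bal: oversample(fold_train, bal, seed=seed + f) for bal in balancers
        }
        row_aucs = {hp: [] for hp in grid}
        for row in range(inner_rows):
            for bal in balancers:
                bdata = balanced[bal]
                row_rng = substream(seed, "inner", f, row, bal)
                if balance_before_inner_split:
                    perm = row_rng.permutation(len(bdata))
                    n_val = int(round(len(bdata) * inner_val_fraction))
                    val, tr = perm[:n_val], perm[n_val:]
                    inner_train, inner_val = bdata.subset(tr), bdata.subset(val)
                else:
                    perm = row_rng.permutation(len(fold_train))
                    n_val = int(round(len(fold_train) * inner_val_fraction))
                    val, tr = perm[:n_val], perm[n_val:]
                    inner_train = oversample(
                        fold_train.subset(tr), bal, seed=seed + 7 * f + row
                    )
                    inner_val = fold_train.subset(val)
                for hp in grid:
                    if hp.balancing != bal:
                        continue
                    model = train_model(
                        inner_train, hp, seed=seed + 1000 * f + 10 * row, lr=lr
                    )
                    proba = model.predict_proba(inner_val.features)
                    row_aucs[hp].append(_inner_auc(proba, inner_val.labels))
        for hp in grid:
            auc_table[hp].append(float(np.nanmean(row_aucs[hp])))

    final_auc = {hp: float(np.nanmean(aucs)) for hp, aucs in auc_table.items()}
    best = max(grid, key=lambda hp: (final_auc[hp], -grid.index(hp)))

    test_set = data.subset(test_idx)
    reports = []
    for f in range(k):
        fold_train_idx = np.concatenate([folds[j] for j in range(k) if j != f])
        balanced = oversample(data.subset(fold_train_idx), best.balancing, seed=seed + f)
        model = train_model(balanced, best, seed=seed + 5000 + f, lr=lr)
        reports.append(evaluate(model, test_set))
    details = {
        "auc_final": final_auc,
        "auc_per_fold": {hp: tuple(v) for hp, v in auc_table.items()},
        "test_indices": test_idx,
        "train_indices": train_idx,
    }
    return best, reports, details


def random_baseline_ap(class_counts: dict) -> dict:
    """Prevalence baseline: a random scorer's AP per class is count / total."""
    total = sum(class_counts.values())
    if total <= 0:
        raise ValueError("class counts must have a positive total")
    return {c: n / total for c, n in class_counts.items()}
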