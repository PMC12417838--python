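"""Feature assembly and compartment classification.

The descriptor of each electrode is a 38-entry feature vector: 12 periodic
features (absolute and relative power in six canonical bands) and 7 aperiodic
features (offset of the power spectrum plus the slope over six fit ranges),
each present in raw and per-patient-normalized form (19 x 2 = 38).

Two classifiers are trained on a stratified 70/30 split with 5-fold
cross-validated hyperparameter selection: a random-subspace ensemble of 30
kNN learners (each on a random 19-dimensional feature subspace, majority vote)
and a cubic-kernel SVM (one-vs-one, features standardized on training
statistics only).  Evaluation reports the confusion matrix and per-class plus
macro precision / recall / F1, for the 4-class scheme (tumoral, close
peritumoral, far peritumoral, healthy) and a 2-class scheme (tumoral vs
non-tumoral by default; tumoral vs healthy as an alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .aperiodic import FIT_RANGES, _range_col
from .spectral import POWER_BANDS, normalize_per_patient

logger = logging.getLogger(__name__)

#: The 19 base feature columns, deterministic order.
PERIODIC_COLUMNS = ([f"abs_{b}" for b in POWER_BANDS] +
                    [f"rel_{b}" for b in POWER_BANDS])
APERIODIC_COLUMNS = ["offset"] + [_range_col(r) for r in FIT_RANGES]
BASE_COLUMNS = PERIODIC_COLUMNS + APERIODIC_COLUMNS

#: Full 38-column inventory: raw then normalized versions.
FEATURE_COLUMNS = BASE_COLUMNS + [f"{c}_norm" for c in BASE_COLUMNS]

ID_COLUMNS = ["channel_id", "patient_id", "label"]


def assemble_features(band_powers: pd.DataFrame,
                      aperiodic_block: pd.DataFrame | None,
                      meta: pd.DataFrame,
                      normalization_mode: str = "per_feature") -> pd.DataFrame:
    """Join periodic and aperiodic blocks into the electrode feature table.

    ``band_powers`` and ``aperiodic_block`` are indexed by ``channel_id``;
    ``meta`` supplies ``patient_id`` and compartment ``label`` per channel.
    Each base column is duplicated in a per-patient max-normalized version
    (suffix ``_norm``).  Rows with any missing feature are excluded with a
    logged count.  With both blocks present the table has exactly 38 feature
    columns; with the periodic block alone, 24.
    """
    base_cols = list(PERIODIC_COLUMNS)
    table = band_powers[[c for c in PERIODIC_COLUMNS if c in band_powers.columns]].copy()
    if aperiodic_block is not None:
        table = table.join(aperiodic_block[APERIODIC_COLUMNS], how="inner")
        base_cols += APERIODIC_COLUMNS
    missing_cols = [c for c in base_cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature assembly error: missing columns {missing_cols}")
    table = table.reset_index().rename(columns={"index": "channel_id"})
    table = meta[ID_COLUMNS].merge(table, on="channel_id", how="inner",
                                   validate="one_to_one")
    normed = normalize_per_patient(table[["patient_id"] + base_cols],
                                   feature_cols=base_cols,
                                   mode=normalization_mode)
    for c in base_cols:
        table[f"{c}_norm"] = normed[c]
    feature_cols = base_cols + [f"{c}_norm" for c in base_cols]
    expected = 38 if aperiodic_block is not None else 24
    if len(feature_cols) != expected:
        raise ValueError(
            f"feature assembly error: {len(feature_cols)} columns, expected {expected}")
    complete = table[feature_cols].notna().all(axis=1)
    if (~complete).any():
        logger.warning("excluding %d rows with missing features", int((~complete).sum()))
    return table.loc[complete, ID_COLUMNS + feature_cols].reset_index(drop=True)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy(dtype=object)


@dataclass
class SplitSpec:
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_test(table: pd.DataFrame, spec: SplitSpec,
                     label_col: str = "label") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive train/test split.

    The train size is round(fraction * n).  Stratified mode allocates per-class
    counts by largest remainder, preserving class proportions within one row.
    """
    n = len(table)
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        classes = sorted(table[label_col].unique().tolist())
        ideal = {c: spec.train_fraction * (table[label_col] == c).sum() for c in classes}
        take = {c: int(np.floor(ideal[c])) for c in classes}
        leftover = n_train - sum(take.values())
        order = sorted(classes, key=lambda c: (-(ideal[c] - take[c]), c))
        for c in order[:leftover]:
            take[c] += 1
        train_idx: list[int] = []
        for c in classes:
            idx = table.index[table[label_col] == c].to_numpy()
            rng.shuffle(idx)
            train_idx.extend(idx[: take[c]])
    else:
        idx = table.index.to_numpy().copy()
        rng.shuffle(idx)
        train_idx = list(idx[:n_train])
    train_mask = table.index.isin(train_idx)
    train = table.loc[train_mask]
    test = table.loc[~train_mask]
    absent = set(table[label_col]) - set(train[label_col])
    if absent:
        raise ValueError(
            f"classes {sorted(absent)} absent from the training split; "
            "use a stratified split or more data")
    return train.reset_index(drop=True), test.reset_index(drop=True)


class KnnSubspaceEnsemble(BaseEstimator, ClassifierMixin):
    """Random-subspace ensemble of k-nearest-neighbor learners.

    Each of ``n_learners`` kNN classifiers is trained on a random
    ``subspace_dim``-feature subset (without replacement, full training set);
    prediction is by majority vote with a deterministic tie-break toward the
    lowest class index (sorted class order).  With one learner on the full
    feature space the ensemble degenerates to plain kNN.
    """

    def __init__(self, n_learners: int = 30, subspace_dim: int = 19,
                 k_neighbors: int = 5, seed: int = 0):
        self.n_learners = n_learners
        self.subspace_dim = subspace_dim
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if self.k_neighbors >= len(X):
            raise ValueError("k_neighbors must be smaller than the training size")
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.seed)
        dim = min(self.subspace_dim, X.shape[1])
        self.subspaces_ = [np.sort(rng.choice(X.shape[1], size=dim, replace=False))
                           for _ in range(self.n_learners)]
        self.learners_ = []
        for sub in self.subspaces_:
            knn = KNeighborsClassifier(n_neighbors=self.k_neighbors)
            knn.fit(X[:, sub], y)
            self.learners_.append(knn)
        return self

    def vote_counts(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        counts = np.zeros((len(X), len(self.classes_)), dtype=int)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for sub, knn in zip(self.subspaces_, self.learners_):
            pred = knn.predict(X[:, sub])
            for r, p in enumerate(pred):
                counts[r, class_index[p]] += 1
        return counts

    def predict(self, X):
        counts = self.vote_counts(X)
        return self.classes_[np.argmax(counts, axis=1)]


def make_model(kind: str, seed: int = 0, **params):
    """Model factory: ``knn_ensemble`` or ``svm`` (cubic polynomial kernel)."""
    if kind == "knn_ensemble":
        return KnnSubspaceEnsemble(
            n_learners=params.get("n_learners", 30),
            subspace_dim=params.get("subspace_dim", 19),
            k_neighbors=params.get("k_neighbors", 5),
            seed=seed)
    if kind == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="poly", degree=3, C=params.get("C", 1.0))),
        ])
    raise ValueError(f"unknown model kind {kind!r}")


DEFAULT_GRIDS = {
    "knn_ensemble": [{"k_neighbors": k} for k in (1, 3, 5, 7, 9, 11, 13, 15, 17, 19)],
    "svm": [{"C": c} for c in (0.1, 1.0, 10.0)],
}


def cross_validate(X: np.ndarray, y: np.ndarray, model_kind: str, k: int = 5,
                   seed: int = 0, param_grid: list[dict] | None = None) -> dict:
    """Stratified k-fold CV selecting hyperparameters by mean macro F1.

    Returns ``best_params``, the per-fold macro F1 of the winner and its mean.
    Fold assignment is seeded and reproducible; grid candidates infeasible on
    a fold (e.g. more neighbors than training rows) are skipped.
    """
    y = np.asarray(y, dtype=object)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} folds exceed the smallest class count ({counts.min()})")
    if param_grid is None:
        param_grid = DEFAULT_GRIDS[model_kind]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    results = []
    for params in param_grid:
        scores, accs = [], []
        try:
            for tr, va in folds:
                model = make_model(model_kind, seed=seed, **params)
                model.fit(X[tr], y[tr])
                pred = model.predict(X[va])
                _, _, f1, _ = precision_recall_fscore_support(
                    y[va], pred, average="macro", zero_division=0)
                scores.append(float(f1))
                accs.append(float(np.mean(pred == y[va])))
        except ValueError:
            continue
        results.append((params, scores, float(np.mean(scores)), accs))
    if not results:
        raise ValueError("no feasible hyperparameter candidate")
    best = max(results, key=lambda r: r[2])
    return {"best_params": best[0], "fold_scores": best[1], "mean_score": best[2],
            "fold_accuracies": best[3],
            "mean_accuracy": float(np.mean(best[3])),
            "all_candidates": [(r[0], r[2]) for r in results]}


def collapse_labels(labels, scheme: str):
    """Map 4-compartment labels onto a 2-class scheme.

    ``tumoral_vs_nontumoral`` relabels every non-tumoral compartment as
    ``non_tumoral``; ``tumoral_vs_healthy`` keeps only tumoral and healthy
    rows (returns a keep-mask alongside the labels).
    """
    labels = np.asarray(labels, dtype=object)
    if scheme == "tumoral_vs_nontumoral":
        out = np.where(labels == "tumoral", "tumoral", "non_tumoral")
        return out, np.ones(len(labels), dtype=bool)
    if scheme == "tumoral_vs_healthy":
        keep = np.isin(labels, ["tumoral", "healthy"])
        return labels.copy(), keep
    raise ValueError(f"unknown 2-class scheme {scheme!r}")


@dataclass
class EvaluationReport:
    scheme: str
    class_order: list[str]
    confusion: pd.DataFrame  # true x predicted counts
    per_class: pd.DataFrame  # precision / recall / f1 / support per class
    precision_macro: float
    recall_macro: float
    f1_macro: float
    accuracy: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "class_order": self.class_order,
            "confusion": self.confusion.to_dict(),
            "per_class": self.per_class.to_dict(),
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "accuracy": self.accuracy,
            **self.extra,
        }


def evaluate(y_true, y_pred, scheme: str = "4class") -> EvaluationReport:
    """Confusion matrix plus per-class and macro precision / recall / F1."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    classes = sorted(set(y_true) | set(y_pred))
    unseen = sorted(set(y_pred) - set(y_true))
    if unseen:
        logger.warning("predicted classes unseen in test labels: %s", unseen)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    pm, rm, fm, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=classes)
    return EvaluationReport(
        scheme=scheme, class_order=list(classes),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        per_class=per_class,
        precision_macro=float(pm), recall_macro=float(rm), f1_macro=float(fm),
        accuracy=float((y_true == y_pred).mean()),
        extra={"unseen_predicted": unseen})


def permutation_null_accuracy(model_kind: str, X_train, y_train, X_test, y_test,
                              n_permutations: int = 100, seed: int = 0,
                              **params) -> tuple[float, float, np.ndarray]:
    """Test accuracy distribution under training-label permutation.

    Returns (mean, SD, accuracies) of a fresh model of the same kind trained
    on permuted training labels and scored against the true test labels.
    """
    rng = np.random.default_rng(seed)
    y_train = np.asarray(y_train, dtype=object)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(y_train))
        model = make_model(model_kind, seed=seed, **params)
        model.fit(X_train, y_train[perm])
        accs[i] = float(np.mean(model.predict(X_test) == np.asarray(y_test, object)))
    return float(accs.mean()), float(accs.std(ddof=1)), accs
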