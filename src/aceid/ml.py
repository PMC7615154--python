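"""Imbalance-aware ML stage: aggregate, split, SMOTE, RFE, train, report.

The sample unit is the technical replicate: feature rows from all assays
are joined on (condition, replicate), robust-Z normalized against the
neutral control, and missing values set to 0.  An 80/20 stratified split
is followed by SMOTE oversampling of the minority class (training
partition only), recursive feature elimination down to 10 features with a
gradient-boosted estimator, and training/evaluation of Random Forest,
Gradient Boosted Tree and K-Nearest Neighbor classifiers.  Overall
accuracy is reported as macro-averaged F1 with per-class
precision/recall/F1 alongside; feature importances are extracted from the
two tree models and normalized to sum to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors

from aceid.screen import MAD_SCALE

__all__ = [
    "MLDataset",
    "ModelReport",
    "prepare_dataset",
    "split_stratified",
    "smote_oversample",
    "rfe_select",
    "train_and_evaluate",
    "make_gb_estimator",
]

ID_COLS = ("condition_id", "replicate_id", "role", "label")
CLASSES = ("increase", "no_effect")


def make_gb_estimator(seed: int = 0) -> GradientBoostingClassifier:
    """The package's pinned gradient-boosted classifier.

    ``max_features="sqrt"`` randomizes split search over ~sqrt(p) features
    per node — the standard choice for wide tabular data (p >> n) that
    also keeps repeated fits inside recursive feature elimination cheap.
    """
    return GradientBoostingClassifier(random_state=seed, max_features="sqrt")


@dataclass
class MLDataset:
    """Samples x features matrix with binary labels and replicate ids."""

    X: pd.DataFrame
    y: pd.Series
    ids: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.ids):
            raise ValueError("X, y and ids must have equal lengths")
        bad = set(self.y.unique()) - set(CLASSES)
        if bad:
            raise ValueError(f"labels must come from {CLASSES}, got extra {sorted(bad)}")
        if self.X.isna().any().any():
            raise ValueError("X must have no missing values after preparation")

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class ModelReport:
    """Per-model metrics, selected features, and tree importances."""

    selected_features: list
    models: dict  # name -> {f1_macro, per_class, confusion, importances|None}
    seed: int = 0
    classes: tuple = CLASSES

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_features": list(self.selected_features),
                "models": self.models,
                "seed": self.seed,
                "classes": list(self.classes),
            },
            indent=1,
        )


def prepare_dataset(
    feature_tables,
    hit_labels: dict,
    *,
    control_condition: str = "NEUTRAL",
) -> MLDataset:
    """Join per-assay feature tables into one ML matrix.

    Parameters
    ----------
    feature_tables : DataFrame or iterable of DataFrames
        Each with id columns (``condition_id``, ``replicate_id``, optional
        ``role``/``label``) and a subset of manifest feature columns.
    hit_labels : dict[str, str]
        Condition id -> hit class ("increase"/"no_effect"/"decrease").
        "decrease" conditions are excluded from the binary problem.

    Rows sharing a replicate identifier are aggregated by median.  If
    neutral-control rows are present, every feature is robust-Z normalized
    against them; features whose control MAD is zero, and any remaining
    missing values, are set to 0.  Control rows are then dropped.

    Raises
    ------
    KeyError
        If a labelled condition has no feature rows (join error, listing
        the missing ids).
    """
    if isinstance(feature_tables, pd.DataFrame):
        tables = [feature_tables]
    else:
        tables = list(feature_tables)
    df = pd.concat(tables, axis=0, ignore_index=True, sort=False)
    feat_cols = [c for c in df.columns if c not in ID_COLS]

    agg = df.groupby(["condition_id", "replicate_id"], sort=True)[feat_cols].median()

    is_ctrl = agg.index.get_level_values("condition_id") == control_condition
    if is_ctrl.any():
        ctrl = agg[is_ctrl]
        med = ctrl.median(axis=0)
        mad = (ctrl - med).abs().median(axis=0)
        scaled = (agg - med) / (MAD_SCALE * mad)
        scaled[mad.index[mad == 0]] = np.nan  # degenerate control features
        agg = scaled
    agg = agg[~is_ctrl].fillna(0.0)

    labelled = {c: l for c, l in hit_labels.items() if l in CLASSES}
    have = set(agg.index.get_level_values("condition_id"))
    missing = sorted(set(labelled) - have)
    if missing:
        raise KeyError(f"conditions labelled but absent from feature tables: {missing}")

    keep = agg.index.get_level_values("condition_id").isin(labelled)
    agg = agg[keep]
    ids = agg.index.to_frame(index=False)
    y = ids["condition_id"].map(labelled).rename("label")
    return MLDataset(X=agg.reset_index(drop=True), y=y, ids=ids)


def split_stratified(
    dataset: MLDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple:
    """Disjoint, exhaustive, class-stratified train/test split."""
    counts = dataset.y.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to stratify")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples to stratify")
    idx = np.arange(len(dataset))
    tr, te = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=dataset.y,
        random_state=seed,
        shuffle=True,
    )
    tr, te = np.sort(tr), np.sort(te)

    def take(ix):
        return MLDataset(
            X=dataset.X.iloc[ix].reset_index(drop=True),
            y=dataset.y.iloc[ix].reset_index(drop=True),
            ids=dataset.ids.iloc[ix].reset_index(drop=True),
        )

    return take(tr), take(te)


def smote_oversample(train: MLDataset, k_neighbors: int = 5, seed: int = 0) -> MLDataset:
    """SMOTE: upsample the minority class to the majority count.

    Each synthetic sample lies on the segment between a randomly chosen
    minority sample and one of its ``k_neighbors`` minority-class nearest
    neighbors (Euclidean).  Applied to training data only — never call
    this on a test partition.
    """
    counts = train.y.value_counts()
    if len(counts) < 2 or counts.iloc[0] == counts.iloc[-1]:
        return train  # already balanced
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    Xm = train.X[train.y == minority].to_numpy(dtype=float)
    if len(Xm) < k_neighbors + 1:
        raise ValueError(
            f"minority class has {len(Xm)} samples; SMOTE with k={k_neighbors} "
            f"needs >= {k_neighbors + 1}"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)  # column 0 is the point itself

    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xm), size=deficit)
    pick = rng.integers(1, k_neighbors + 1, size=deficit)
    lam = rng.uniform(0.0, 1.0, size=deficit)
    synth = Xm[base] + lam[:, None] * (Xm[neigh[base, pick]] - Xm[base])

    X_new = pd.DataFrame(synth, columns=train.X.columns)
    ids_new = pd.DataFrame(
        {
            "condition_id": ["SMOTE"] * deficit,
            "replicate_id": np.arange(1, deficit + 1),
        }
    )
    return MLDataset(
        X=pd.concat([train.X, X_new], ignore_index=True),
        y=pd.concat([train.y, pd.Series([minority] * deficit, name="label")], ignore_index=True),
        ids=pd.concat([train.ids, ids_new], ignore_index=True),
    )


def rfe_select(
    train: MLDataset,
    n_features: int = 10,
    *,
    estimator=None,
    step: float = 0.1,
    seed: int = 0,
) -> list:
    """Recursive feature elimination down to ``n_features``.

    Each round drops the lowest-importance ``step`` fraction of the
    remaining features, refitting the estimator (a gradient-boosted
    classifier by default).  Deterministic for a fixed seed.
    """
    p = train.X.shape[1]
    if n_features >= p:
        raise ValueError(f"n_features={n_features} must be < feature count {p}")
    est = estimator if estimator is not None else make_gb_estimator(seed)
    rfe = RFE(est, n_features_to_select=n_features, step=step)
    rfe.fit(train.X.to_numpy(dtype=float), train.y.to_numpy())
    return [c for c, keep in zip(train.X.columns, rfe.support_) if keep]


def train_and_evaluate(
    train: MLDataset,
    test: MLDataset,
    features=None,
    seed: int = 0,
) -> ModelReport:
    """Train the three models on a feature subset and evaluate on the test set.

    Reports macro-F1 (headline), per-class precision/recall/F1, confusion
    counts, and — for the two tree models — importances normalized to sum
    to 1 over the selected features.
    """
    features = list(features) if features is not None else list(train.X.columns)
    unknown = [f for f in features if f not in train.X.columns]
    if unknown:
        raise KeyError(f"features not in the dataset: {unknown[:5]}")
    if test.y.nunique() < 2:
        raise ValueError("test set contains a single class; cannot evaluate")

    Xtr = train.X[features].to_numpy(dtype=float)
    Xte = test.X[features].to_numpy(dtype=float)
    ytr = train.y.to_numpy()
    yte = test.y.to_numpy()

    models = {
        "random_forest": RandomForestClassifier(random_state=seed),
        "gradient_boosted": make_gb_estimator(seed),
        "knn": KNeighborsClassifier(),
    }
    labels = list(CLASSES)
    report: dict = {}
    for name, model in models.items():
        model.fit(Xtr, ytr)
        pred = model.predict(Xte)
        prec, rec, f1, _ = precision_recall_fscore_support(
            yte, pred, labels=labels, zero_division=0
        )
        entry = {
            "f1_macro": float(f1_score(yte, pred, labels=labels, average="macro", zero_division=0)),
            "per_class": {
                lab: {"precision": float(p), "recall": float(r), "f1": float(f)}
                for lab, p, r, f in zip(labels, prec, rec, f1)
            },
            "confusion": confusion_matrix(yte, pred, labels=labels).tolist(),
            "importances": None,
        }
        if hasattr(model, "feature_importances_"):
            imp = np.asarray(model.feature_importances_, dtype=float)
            total = imp.sum()
            imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
            entry["importances"] = dict(zip(features, imp.tolist()))
        report[name] = entry
    return ModelReport(selected_features=features, models=report, seed=seed)
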