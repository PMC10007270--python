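"""Two-stage variety -> age classification pipeline.

Stage 1 predicts the variety from the 159-dim feature vector; stage 2
routes the sample to the predicted variety's own age classifier.  One
variety model plus six per-variety age models gives seven classifiers.

Each classifier is a stack: three gradient-boosted base learners produce
hard class labels, and a fixed-structure two-level cascaded ANFIS fuses the
three label streams into the final decision.  Fusion training inputs are
produced out-of-fold (stratified 5-fold) so the meta-learner never sees
resubstitution outputs; a resubstitution mode exists for strict mimicry of
a single-pass setup.

The three base-learner slots are XGBoost, scikit-learn's
HistGradientBoostingClassifier and LightGBM, with fixed hyperparameters
(no tuning sweep is performed here).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import (
    FusionModel,
    cascade_from_json,
    cascade_to_json,
    predict_fusion_batch,
    train_fusion,
)
from .imagedata import VARIETIES, YEARS, EXCLUDED_CLASSES
from .descriptors import feature_column_names

__all__ = [
    "BoosterConfig",
    "TwoStageModel",
    "split_dataset",
    "fit_boosters",
    "train_fused_classifier",
    "train_two_stage",
    "predict_two_stage",
    "evaluate_two_stage",
]

BOOSTER_ORDER = ("xgboost", "histgb", "lightgbm")


@dataclass(frozen=True)
class BoosterConfig:
    """Fixed hyperparameters of the three base learners."""

    xgboost: dict = field(default_factory=lambda: {
        "colsample_bytree": 0.5, "learning_rate": 0.3, "max_depth": 6,
        "reg_alpha": 10, "n_estimators": 750, "subsample": 0.7,
    })
    histgb: dict = field(default_factory=lambda: {
        "max_iter": 90, "learning_rate": 0.04, "max_depth": 4,
        "max_leaf_nodes": 64,
    })
    lightgbm: dict = field(default_factory=lambda: {
        "num_leaves": 31, "learning_rate": 0.1, "boosting_type": "gbdt",
    })
    # meta-training inputs for the fusion: "resub" feeds the final boosters'
    # own training-set outputs (hard labels, as the base learners emit them);
    # "oof" substitutes stratified out-of-fold predictions
    stacking_mode: str = "resub"
    oof_folds: int = 5
    anfis_iterations: int = 100
    anfis_learning_rate: float = 0.01
    anfis_target_error: float = 0.0
    normalize: bool = True      # min-max per feature, fit on the train split

    def __post_init__(self) -> None:
        for name in BOOSTER_ORDER:
            params = getattr(self, name)
            if params.get("learning_rate", 1.0) <= 0:
                raise ValueError(f"{name} learning_rate must be > 0")
        if self.stacking_mode not in ("resub", "oof"):
            raise ValueError("stacking_mode must be 'resub' or 'oof'")


class BoosterAdapter:
    """Uniform fit/predict surface over one gradient-boosting backend.

    ``predict_scalar`` returns hard class indices in [0, n_classes); a
    degenerate single-class training set yields a constant predictor.
    """

    def __init__(self, name: str, params: dict, seed: int):
        self.name = name
        self.params = dict(params)
        self.seed = int(seed)
        self._model = None
        self._constant: int | None = None

    def _build(self):
        if self.name == "xgboost":
            try:
                from xgboost import XGBClassifier
            except ImportError as exc:
                raise ImportError("xgboost backend unavailable") from exc
            return XGBClassifier(
                **self.params, tree_method="hist",
                random_state=self.seed, n_jobs=1, verbosity=0,
            )
        if self.name == "histgb":
            from sklearn.ensemble import HistGradientBoostingClassifier
            return HistGradientBoostingClassifier(
                **self.params, random_state=self.seed,
            )
        if self.name == "lightgbm":
            try:
                from lightgbm import LGBMClassifier
            except ImportError as exc:
                raise ImportError("lightgbm backend unavailable") from exc
            # objective left to the wrapper: binary for 2-class tasks,
            # multiclass softmax otherwise
            return LGBMClassifier(
                **self.params, random_state=self.seed, n_jobs=1, verbose=-1,
            )
        raise ValueError(f"unknown booster {self.name!r}")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BoosterAdapter":
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            self._constant = int(y[0])
            return self
        self._model = self._build()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model.fit(X, y)
        return self

    def predict_scalar(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self._constant is not None:
            return np.full(len(X), self._constant, dtype=np.int64)
        return np.asarray(self._model.predict(X), dtype=np.int64)


def fit_boosters(features, labels, config: BoosterConfig, seed: int = 0):
    """Fit the three base learners; returns them in BOOSTER_ORDER."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if len(X) == 0:
        raise ValueError("empty training split")
    return [
        BoosterAdapter(name, getattr(config, name), seed).fit(X, y)
        for name in BOOSTER_ORDER
    ]


def _booster_matrix(boosters, X: np.ndarray) -> np.ndarray:
    return np.column_stack([b.predict_scalar(X) for b in boosters]).astype(np.float64)


def _oof_predictions(X, y, config: BoosterConfig, seed: int) -> np.ndarray:
    """Out-of-fold hard-label predictions of the three base learners."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y, dtype=np.int64)
    min_count = np.bincount(y).min() if len(np.unique(y)) > 1 else len(y)
    folds = min(config.oof_folds, int(min_count))
    if folds < 2:
        warnings.warn("too few samples per class for out-of-fold stacking; "
                      "falling back to resubstitution outputs")
        return _booster_matrix(fit_boosters(X, y, config, seed), X)
    preds = np.empty((len(y), 3))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        boosters = fit_boosters(X[tr], y[tr], config, seed)
        preds[te] = _booster_matrix(boosters, X[te])
    return preds


# ---------------------------------------------------------------------------
# dataset splitting and normalization
# ---------------------------------------------------------------------------

def split_dataset(manifest: pd.DataFrame, ratio: float = 0.7,
                  rng_seed: int = 0) -> pd.DataFrame:
    """Stratified train/test assignment by (variety, harvest_year).

    Per class, floor(ratio * n) samples go to train (at least 1 when the
    class has >= 2), the rest to test; deterministic given ``rng_seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    out = manifest.reset_index(drop=True).copy()
    split = np.empty(len(out), dtype=object)
    for _, idx in out.groupby(["variety", "harvest_year"], sort=True).groups.items():
        idx = np.asarray(idx)
        n = len(idx)
        if n == 1:
            warnings.warn("class with a single sample assigned to train")
            split[idx] = "train"
            continue
        n_train = max(int(np.floor(ratio * n)), 1)
        perm = rng.permutation(n)
        split[idx[perm[:n_train]]] = "train"
        split[idx[perm[n_train:]]] = "test"
    out["split"] = split
    return out


@dataclass
class MinMaxScaler:
    """Per-feature min-max normalization fit on the training split."""

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        mins = X.min(axis=0)
        ranges = X.max(axis=0) - mins
        return cls(mins, ranges)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.zeros_like(X)
        nz = self.ranges > 0
        out[:, nz] = (X[:, nz] - self.mins[nz]) / self.ranges[nz]
        return out

    @classmethod
    def identity(cls, n_features: int) -> "MinMaxScaler":
        return cls(np.zeros(n_features), np.ones(n_features))


# ---------------------------------------------------------------------------
# fused classifier (boosters + ANFIS fusion) and the two-stage model
# ---------------------------------------------------------------------------

def seriate_codes(meta_preds: np.ndarray, y_idx: np.ndarray, k: int) -> np.ndarray:
    """Class -> scalar-code assignment by confusion-graph seriation.

    Squared-error fusion on scalar codes rounds blended outputs, so classes
    that the base learners confuse must sit at adjacent integers.  The
    order is the Fiedler-vector (second Laplacian eigenvector) seriation of
    the symmetrized pooled confusion graph of the meta-training
    predictions; returns ``order`` with ``order[code] = class index``.
    Falls back to the identity order when no confusions exist.
    """
    C = np.zeros((k, k))
    for col in range(meta_preds.shape[1]):
        np.add.at(C, (y_idx, meta_preds[:, col].astype(np.int64)), 1.0)
    S = C + C.T
    np.fill_diagonal(S, 0.0)
    if S.sum() == 0:
        return np.arange(k)
    lap = np.diag(S.sum(axis=1)) - S
    _, vecs = np.linalg.eigh(lap)
    return np.argsort(vecs[:, 1], kind="stable")


@dataclass
class FusedClassifier:
    """Three base learners fused by the two-level cascaded ANFIS.

    ``code_order`` maps the fusion's scalar code space back to class
    indices (``code_order[code] = class index``); boosters always work in
    the original class-index space.
    """

    boosters: list
    fusion: FusionModel | None
    class_labels: list  # actual labels (variety names or years), index-coded
    code_order: np.ndarray | None = None
    constant: int | None = None  # degenerate single-class training set

    def predict_index(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.constant is not None:
            return np.full(len(X), self.constant, dtype=np.int64)
        codes = np.asarray(
            predict_fusion_batch(self.fusion, self._meta_inputs(X)),
            dtype=np.int64,
        )
        return self.code_order[codes]

    def _meta_inputs(self, X: np.ndarray) -> np.ndarray:
        rank = np.empty(len(self.code_order), dtype=np.int64)
        rank[self.code_order] = np.arange(len(self.code_order))
        return rank[_booster_matrix(self.boosters, X).astype(np.int64)].astype(
            np.float64
        )

    def predict_continuous(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.constant is not None:
            return np.full(len(X), float(self.constant))
        return self.fusion.forward(self._meta_inputs(X))

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.class_labels, dtype=object)[self.predict_index(X)]


def train_fused_classifier(
    X, y_idx, class_labels, config: BoosterConfig, seed: int = 0
) -> FusedClassifier:
    """Fit the three boosters plus the ANFIS fusion for one task."""
    X = np.asarray(X, dtype=np.float64)
    y_idx = np.asarray(y_idx, dtype=np.int64)
    class_labels = list(class_labels)
    k = len(class_labels)
    if k < 2:
        warnings.warn("single-class task; using a constant predictor")
        return FusedClassifier([], None, class_labels, constant=0)
    boosters = fit_boosters(X, y_idx, config, seed)
    if config.stacking_mode == "oof":
        meta_in = _oof_predictions(X, y_idx, config, seed)
    else:
        meta_in = _booster_matrix(boosters, X)
    order = seriate_codes(meta_in, y_idx, k)
    rank = np.empty(k, dtype=np.int64)
    rank[order] = np.arange(k)
    fusion = train_fusion(
        rank[meta_in.astype(np.int64)].astype(np.float64),
        rank[y_idx],
        class_codes=list(range(k)),
        unit_iterations=config.anfis_iterations,
        target_error=config.anfis_target_error,
        learning_rate=config.anfis_learning_rate,
    )
    return FusedClassifier(boosters, fusion, class_labels, code_order=order)


@dataclass
class TwoStageModel:
    """The 1 + 6 = 7 fused classifiers plus the feature scaler."""

    variety_model: FusedClassifier
    age_models: dict          # variety name -> FusedClassifier over its years
    scaler: MinMaxScaler
    feature_columns: list

    @property
    def n_classifiers(self) -> int:
        return 1 + len(self.age_models)


def _feature_matrix(table: pd.DataFrame, columns) -> np.ndarray:
    return table[list(columns)].to_numpy(dtype=np.float64)


def variety_years(variety: str) -> list[int]:
    return [y for y in YEARS if (variety, y) not in EXCLUDED_CLASSES]


def train_two_stage(
    features: pd.DataFrame, config: BoosterConfig | None = None, seed: int = 0
) -> TwoStageModel:
    """Train the variety model and the six per-variety age models.

    ``features`` is the extracted table with variety / harvest_year / split
    columns; only split == 'train' rows influence the scaler, the boosters
    and the fusion.  Age models train on true-variety subsets; prediction
    routes through the predicted variety.
    """
    config = config or BoosterConfig()
    cols = feature_column_names()
    train = features[features["split"] == "train"]
    if len(train) == 0:
        raise ValueError("no rows with split == 'train'")
    Xtr_raw = _feature_matrix(train, cols)
    scaler = MinMaxScaler.fit(Xtr_raw) if config.normalize \
        else MinMaxScaler.identity(len(cols))
    Xtr = scaler.transform(Xtr_raw)

    v_index = {v: k for k, v in enumerate(VARIETIES)}
    y_variety = train["variety"].map(v_index).to_numpy(dtype=np.int64)
    variety_model = train_fused_classifier(
        Xtr, y_variety, list(VARIETIES), config, seed
    )

    age_models = {}
    for k, variety in enumerate(VARIETIES):
        years = variety_years(variety)
        rows = train["variety"] == variety
        sub = train[rows]
        y_age = sub["harvest_year"].map({y: i for i, y in enumerate(years)})
        if y_age.isna().any():
            raise ValueError(f"unexpected harvest year for {variety}")
        age_models[variety] = train_fused_classifier(
            Xtr[rows.to_numpy()], y_age.to_numpy(dtype=np.int64),
            years, config, seed + 1 + k,
        )
    return TwoStageModel(variety_model, age_models, scaler, cols)


def predict_two_stage(model: TwoStageModel, features) -> pd.DataFrame:
    """Predict (variety, harvest_year) for raw feature rows.

    The variety is predicted first; the matching age model then predicts
    the year — the age stage never sees the true variety, so variety errors
    propagate.  Continuous fused scores are attached for diagnostics.
    """
    X = model.scaler.transform(np.atleast_2d(np.asarray(features, dtype=np.float64)))
    v_idx = model.variety_model.predict_index(X)
    v_score = model.variety_model.predict_continuous(X)
    varieties = np.asarray([model.variety_model.class_labels[i] for i in v_idx],
                           dtype=object)
    years = np.empty(len(X), dtype=np.int64)
    a_score = np.empty(len(X))
    for v in np.unique(varieties):
        rows = varieties == v
        age_model = model.age_models[v]
        idx = age_model.predict_index(X[rows])
        years[rows] = np.asarray(age_model.class_labels, dtype=np.int64)[idx]
        a_score[rows] = age_model.predict_continuous(X[rows])
    return pd.DataFrame({
        "variety": varieties, "harvest_year": years,
        "variety_score": v_score, "age_score": a_score,
    })


def evaluate_two_stage(model: TwoStageModel, features: pd.DataFrame,
                       split: str = "test") -> dict:
    """Variety / age / joint accuracies plus full metric reports."""
    from .evaluation import confusion_matrix, metrics_report

    rows = features[features["split"] == split]
    X = _feature_matrix(rows, model.feature_columns)
    pred = predict_two_stage(model, X)
    true_v = rows["variety"].to_numpy()
    true_y = rows["harvest_year"].to_numpy()
    variety_ok = pred["variety"].to_numpy() == true_v
    year_ok = pred["harvest_year"].to_numpy() == true_y
    v_index = {v: k for k, v in enumerate(VARIETIES)}
    cm = confusion_matrix(
        [v_index[v] for v in true_v],
        [v_index[v] for v in pred["variety"]],
        len(VARIETIES),
    )
    return {
        "n": int(len(rows)),
        "variety_accuracy": float(variety_ok.mean()),
        "age_accuracy_given_variety": float(year_ok[variety_ok].mean())
        if variety_ok.any() else 0.0,
        "joint_accuracy": float((variety_ok & year_ok).mean()),
        "variety_metrics": metrics_report(cm, list(VARIETIES)),
    }


# ---------------------------------------------------------------------------
# model persistence (directory of JSON artifacts)
# ---------------------------------------------------------------------------

def _fused_to_json(fc: FusedClassifier) -> dict:
    return {
        "class_labels": [int(c) if isinstance(c, (int, np.integer)) else c
                         for c in fc.class_labels],
        "code_order": fc.code_order.tolist() if fc.code_order is not None else None,
        "constant": fc.constant,
        "fusion": cascade_to_json(fc.fusion) if fc.fusion is not None else None,
    }


def save_two_stage(model: TwoStageModel, out_dir) -> None:
    """Persist the fusion/scaler state as JSON plus pickled boosters.

    Booster backends have no portable text format; they are re-fit rather
    than serialized when a fully text-based artifact is required.
    """
    import pickle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "feature_columns": model.feature_columns,
        "scaler": {"mins": model.scaler.mins.tolist(),
                   "ranges": model.scaler.ranges.tolist()},
        "variety": _fused_to_json(model.variety_model),
        "age": {v: _fused_to_json(m) for v, m in model.age_models.items()},
    }
    with open(out_dir / "model.json", "w") as fh:
        json.dump(meta, fh)
    with open(out_dir / "boosters.pkl", "wb") as fh:
        pickle.dump({
            "variety": model.variety_model.boosters,
            "age": {v: m.boosters for v, m in model.age_models.items()},
        }, fh)


def load_two_stage(model_dir) -> TwoStageModel:
    import pickle

    model_dir = Path(model_dir)
    with open(model_dir / "model.json") as fh:
        meta = json.load(fh)
    with open(model_dir / "boosters.pkl", "rb") as fh:
        boosters = pickle.load(fh)

    def rebuild(spec: dict, bst) -> FusedClassifier:
        fusion = cascade_from_json(spec["fusion"]) if spec["fusion"] else None
        order = np.array(spec["code_order"], dtype=np.int64) \
            if spec["code_order"] is not None else None
        return FusedClassifier(bst, fusion, spec["class_labels"],
                               code_order=order, constant=spec["constant"])

    scaler = MinMaxScaler(np.array(meta["scaler"]["mins"]),
                          np.array(meta["scaler"]["ranges"]))
    return TwoStageModel(
        rebuild(meta["variety"], boosters["variety"]),
        {v: rebuild(s, boosters["age"][v]) for v, s in meta["age"].items()},
        scaler,
        meta["feature_columns"],
    )
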