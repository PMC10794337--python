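"""Random-forest phenotype classification and IL-10 regression.

Protocol: predictors are z-scored (scaler fitted on the training split
only), data is split stratified 70/30 into train/test, models are
random forests trained with 10-fold cross-validation on the training
split and reported on the held-out split. The classification panel is
accuracy, one-vs-rest macro AUC, macro recall, macro precision, F1
(harmonic mean of precision and recall), Cohen's kappa and the Matthews
correlation coefficient; the regression panel is R², MAE, MSE, RMSE,
RMSLE and MAPE.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    mean_absolute_error,
    mean_absolute_percentage_error,
    mean_squared_error,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from macromorph.io import MORPHOLOGY_FEATURES
from macromorph.supertiles import SuperTileParams, generate_supertiles

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "ClassificationReport",
    "RegressionReport",
    "split_train_test",
    "compute_classification_metrics",
    "train_classifier",
    "evaluate_classifier",
    "train_eval_regressor",
    "feature_attribution",
    "run_experiment",
]


@dataclass(frozen=True)
class ModelConfig:
    """Training protocol knobs (defaults follow the study protocol)."""

    task: str = "classify"  # classify | regress
    predictors: list[str] = field(default_factory=lambda: list(MORPHOLOGY_FEATURES))
    n_trees: int = 100
    cv_folds: int = 10
    test_fraction: float = 0.30
    seed: int = 0
    #: candidate-feature fraction per split; None = sqrt(p) for
    #: classification, 0.5 for regression. The shape panel is strongly
    #: collinear (e.g. roundness tracks 1/aspect_ratio), and regression
    #: forests that consider every feature at every split funnel all
    #: importance into one member of each correlated group; subsampling
    #: spreads usage so attribution reflects the true couplings.
    max_features: float | str | None = None

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must be in (0,1), got {self.test_fraction}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.task not in ("classify", "regress"):
            raise ValueError(f"task must be 'classify' or 'regress', got {self.task!r}")


@dataclass
class ClassificationReport:
    """The seven-metric classification panel plus the confusion matrix.

    ``auc`` is one-vs-rest macro AUC; it is NaN when undefined (no
    scores, or a single observed class) rather than fabricated.
    """

    accuracy: float
    auc: float
    recall: float
    precision: float
    f1: float
    kappa: float
    mcc: float
    confusion: np.ndarray
    classes: np.ndarray

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("accuracy", "auc", "recall", "precision", "f1", "kappa", "mcc")}
        d["confusion"] = self.confusion.tolist()
        d["classes"] = self.classes.tolist()
        return d

    def summary(self) -> str:
        head = "metric      value\n" + "-" * 18
        lines = [
            f"{k:<10}  {getattr(self, k):.4f}"
            for k in ("accuracy", "auc", "recall", "precision", "f1", "kappa", "mcc")
        ]
        return "\n".join([head, *lines])


@dataclass
class RegressionReport:
    r2: float
    mae: float
    mse: float
    rmse: float
    rmsle: float
    mape: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def summary(self) -> str:
        head = "metric  value\n" + "-" * 14
        lines = [f"{k:<6}  {v:.4f}" for k, v in self.to_dict().items()]
        return "\n".join([head, *lines])


def split_train_test(
    table: pd.DataFrame, labels: pd.Series | np.ndarray, config: ModelConfig
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Stratified 70/30 split (classification) of rows and labels."""
    labels = np.asarray(labels)
    stratify = labels if config.task == "classify" else None
    if config.task == "classify":
        _, cls_counts = np.unique(labels, return_counts=True)
        if (cls_counts < 2).any():
            raise ValueError("every class needs at least 2 rows for a stratified split")
    tr_x, te_x, tr_y, te_y = train_test_split(
        table,
        labels,
        test_size=config.test_fraction,
        stratify=stratify,
        random_state=config.seed,
    )
    return tr_x, te_x, tr_y, te_y


def compute_classification_metrics(
    y_true, y_pred, y_score: np.ndarray | None = None
) -> ClassificationReport:
    """The metric panel from predictions (and scores, for AUC).

    Recall/precision/F1 are macro-averaged over classes; F1 is the
    standard harmonic mean 2PR/(P+R) per class. ``y_score`` must be
    row-normalized class probabilities with one column per class
    observed in training.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    auc = np.nan
    if y_score is not None and len(np.unique(y_true)) > 1:
        y_score = np.asarray(y_score)
        if y_score.ndim == 2 and y_score.shape[1] == 2:
            auc = roc_auc_score(y_true, y_score[:, 1])
        else:
            auc = roc_auc_score(y_true, y_score, multi_class="ovr", average="macro")
    return ClassificationReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        auc=float(auc),
        recall=float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
        precision=float(precision_score(y_true, y_pred, average="macro", zero_division=0)),
        f1=float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        kappa=float(cohen_kappa_score(y_true, y_pred)),
        mcc=float(matthews_corrcoef(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred, labels=classes),
        classes=classes,
    )


def _drop_degenerate(table: pd.DataFrame, predictors: list[str]) -> list[str]:
    keep = []
    for c in predictors:
        if table[c].nunique() <= 1:
            logger.info("dropping zero-variance predictor %r", c)
        else:
            keep.append(c)
    if not keep:
        raise ValueError("all predictors are zero-variance")
    return keep


def _make_pipeline(config: ModelConfig) -> Pipeline:
    if config.task == "classify":
        mf = config.max_features if config.max_features is not None else "sqrt"
        model = RandomForestClassifier(
            n_estimators=config.n_trees, max_features=mf, random_state=config.seed, n_jobs=1
        )
    else:
        mf = config.max_features if config.max_features is not None else 0.5
        model = RandomForestRegressor(
            n_estimators=config.n_trees, max_features=mf, random_state=config.seed, n_jobs=1
        )
    return Pipeline([("scale", StandardScaler()), ("forest", model)])


def train_classifier(
    train: pd.DataFrame, labels, config: ModelConfig, with_cv: bool = True
) -> tuple[Pipeline, pd.DataFrame]:
    """Fit the forest on z-scored predictors with k-fold CV.

    Returns the fitted pipeline and a per-fold CV metric table
    (one row per fold; ``.describe()`` gives mean ± sd). ``with_cv=False``
    skips the fold loop (empty CV table) for repeated-seed sweeps where
    only the held-out report is consumed.
    """
    labels = np.asarray(labels)
    predictors = _drop_degenerate(train, list(config.predictors))
    X = train[predictors]
    if with_cv:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < config.cv_folds:
            raise ValueError(
                f"{config.cv_folds}-fold CV needs >= {config.cv_folds} rows per class; "
                f"smallest class has {counts.min()}"
            )
    cv_rows = []
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    for fold, (tr, va) in enumerate(skf.split(X, labels) if with_cv else ()):
        pipe = _make_pipeline(config)
        pipe.fit(X.iloc[tr], labels[tr])
        rep = compute_classification_metrics(
            labels[va], pipe.predict(X.iloc[va]), pipe.predict_proba(X.iloc[va])
        )
        cv_rows.append({"fold": fold, **{k: getattr(rep, k) for k in
                        ("accuracy", "auc", "recall", "precision", "f1", "kappa", "mcc")}})
    model = _make_pipeline(config)
    model.fit(X, labels)
    return model, pd.DataFrame(cv_rows)


def evaluate_classifier(model: Pipeline, test: pd.DataFrame, labels) -> ClassificationReport:
    """Metric panel on held-out rows."""
    if len(test) == 0:
        raise ValueError("empty test set")
    expected = list(model.feature_names_in_)
    missing = [c for c in expected if c not in test.columns]
    if missing:
        raise ValueError(f"test set is missing trained predictors: {missing}")
    X = test[expected]
    return compute_classification_metrics(labels, model.predict(X), model.predict_proba(X))


def _regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> RegressionReport:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.var(y_true) == 0:
        r2 = np.nan  # undefined for a constant target, reported as such
    else:
        r2 = r2_score(y_true, y_pred)
    mse = mean_squared_error(y_true, y_pred)
    shift = min(y_true.min(), y_pred.min())
    if shift < 0:  # rmsle needs nonnegative values; documented shift
        logger.info("rmsle: shifting values by %+.4g to be nonnegative", -shift)
        yt, yp = y_true - shift, y_pred - shift
    else:
        yt, yp = y_true, y_pred
    rmsle = float(np.sqrt(np.mean((np.log1p(yp) - np.log1p(yt)) ** 2)))
    return RegressionReport(
        r2=float(r2),
        mae=float(mean_absolute_error(y_true, y_pred)),
        mse=float(mse),
        rmse=float(np.sqrt(mse)),
        rmsle=rmsle,
        mape=float(mean_absolute_percentage_error(y_true, y_pred)),
    )


def train_eval_regressor(
    table: pd.DataFrame, target_col: str, config: ModelConfig, with_cv: bool = True
) -> tuple[Pipeline, RegressionReport, pd.DataFrame]:
    """70/30 forest regression of a marker target with k-fold CV.

    Returns (fitted pipeline, held-out RegressionReport, per-fold CV
    table computed on the training split). ``with_cv=False`` skips the
    fold loop for repeated-seed sweeps.
    """
    if len(table) < 20:
        raise ValueError("need at least 20 rows for regression")
    y = table[target_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"target {target_col!r} has non-finite values")
    config = dataclasses.replace(config, task="regress")
    predictors = _drop_degenerate(table, [c for c in config.predictors if c != target_col])
    X = table[predictors]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.test_fraction, random_state=config.seed
    )
    cv_rows = []
    from sklearn.model_selection import KFold

    folds = (
        KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed).split(X_tr)
        if with_cv
        else ()
    )
    for fold, (tr, va) in enumerate(folds):
        pipe = _make_pipeline(config)
        pipe.fit(X_tr.iloc[tr], y_tr[tr])
        cv_rows.append({"fold": fold, **_regression_metrics(y_tr[va], pipe.predict(X_tr.iloc[va])).to_dict()})
    model = _make_pipeline(config)
    model.fit(X_tr, y_tr)
    report = _regression_metrics(y_te, model.predict(X_te))
    return model, report, pd.DataFrame(cv_rows)


def feature_attribution(
    model: Pipeline,
    data: pd.DataFrame,
    target=None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature contribution ranking for a fitted forest.

    Uses permutation importance (mean decrease of the model score when
    one predictor is shuffled), the model-agnostic estimate of each
    feature's contribution; the ``method`` column flags the estimator.
    Returns a frame sorted by descending importance.
    """
    if not hasattr(model, "feature_names_in_"):
        raise ValueError("model is not fitted")
    features = list(model.feature_names_in_)
    X = data[features]
    if target is None:
        raise ValueError("feature_attribution needs the target values for scoring")
    res = permutation_importance(
        model, X, np.asarray(target), n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    out = pd.DataFrame(
        {
            "feature": features,
            "importance": res.importances_mean,
            "importance_sd": res.importances_std,
            "method": "permutation",
        }
    )
    return out.sort_values("importance", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# experiment orchestration


def run_experiment(
    table: pd.DataFrame,
    protocol: str,
    config: ModelConfig | None = None,
    source: str = "original",
    eval_on: str = "synthetic_split",
    tile_params: SuperTileParams | None = None,
    pair: tuple[int, int] | None = None,
    target_col: str = "il10_norm",
    label_col: str = "class_id",
    with_cv: bool = True,
) -> dict:
    """End-to-end experiment on a feature table.

    protocol: ``classify_all`` (all classes), ``classify_pair``
    (restrict to ``pair``), or ``regress_il10`` (forest regression of
    ``target_col``).

    source: ``original`` rows, ``supertiles`` (tiles only), or
    ``mixed`` (original training rows plus tiles built from them).

    eval_on (classification with supertiles): ``synthetic_split``
    splits the tile set 70/30; ``original_holdout`` holds out 30% of the
    original cells, builds tiles from the training cells only (no
    provenance leakage) and evaluates the tile-trained model on the
    held-out original cells.

    Returns a dict bundle with the report, CV table and provenance.
    """
    config = config or ModelConfig()
    if protocol == "regress_il10":
        if source != "original":
            raise ValueError("IL-10 regression runs on original rows (no augmentation needed)")
        model, report, cv = train_eval_regressor(table, target_col, config, with_cv=with_cv)
        # attribute on the held-out rows (same deterministic split as training)
        _, te_x, _, te_y = train_test_split(
            table, table[target_col].to_numpy(),
            test_size=config.test_fraction, random_state=config.seed,
        )
        attribution = feature_attribution(model, te_x, te_y, seed=config.seed)
        return {
            "protocol": protocol,
            "report": report,
            "cv": cv,
            "model": model,
            "attribution": attribution,
        }

    if protocol == "classify_pair":
        if pair is None:
            raise ValueError("classify_pair needs the pair of class ids")
        table = table[table[label_col].isin(pair)].reset_index(drop=True)
    elif protocol != "classify_all":
        raise ValueError(f"unknown protocol {protocol!r}")

    config = dataclasses.replace(config, task="classify")

    if source == "original":
        tr_x, te_x, tr_y, te_y = split_train_test(table, table[label_col], config)
        model, cv = train_classifier(tr_x, tr_y, config, with_cv=with_cv)
        report = evaluate_classifier(model, te_x, te_y)
        bundle_prov = {"source": source, "n_train": len(tr_x), "n_test": len(te_x)}
    elif source in ("supertiles", "mixed"):
        if tile_params is None:
            raise ValueError(f"source={source!r} needs tile_params")
        if eval_on == "synthetic_split":
            tiles = generate_supertiles(table, tile_params, label_col=label_col).table
            if source == "mixed":
                tiles = pd.concat(
                    [tiles, table[list(tiles.columns)]], ignore_index=True
                )
            tr_x, te_x, tr_y, te_y = split_train_test(tiles, tiles[label_col], config)
            model, cv = train_classifier(tr_x, tr_y, config, with_cv=with_cv)
            report = evaluate_classifier(model, te_x, te_y)
            bundle_prov = {"source": source, "eval_on": eval_on,
                           "n_train": len(tr_x), "n_test": len(te_x)}
        elif eval_on == "original_holdout":
            tr_x, te_x, tr_y, te_y = split_train_test(table, table[label_col], config)
            tile_set = generate_supertiles(
                tr_x.reset_index(drop=True), tile_params, label_col=label_col
            )
            train_tiles = tile_set.table
            if source == "mixed":
                train_tiles = pd.concat(
                    [train_tiles, tr_x[list(train_tiles.columns)]], ignore_index=True
                )
            model, cv = train_classifier(train_tiles, train_tiles[label_col], config, with_cv=with_cv)
            report = evaluate_classifier(model, te_x, te_y)
            bundle_prov = {
                "source": source,
                "eval_on": eval_on,
                "n_train_tiles": len(train_tiles),
                "n_test_original": len(te_x),
            }
        else:
            raise ValueError(f"unknown eval_on {eval_on!r}")
    else:
        raise ValueError(f"unknown source {source!r}")

    return {"protocol": protocol, "report": report, "cv": cv, "model": model, **bundle_prov}


def save_report(bundle: dict, path: str | Path) -> None:
    """Serialize an experiment bundle's report + provenance to JSON."""
    payload = {k: v for k, v in bundle.items() if isinstance(v, (str, int, float))}
    payload["report"] = bundle["report"].to_dict()
    if "cv" in bundle and isinstance(bundle["cv"], pd.DataFrame):
        payload["cv_mean"] = bundle["cv"].drop(columns="fold").mean().to_dict()
        payload["cv_sd"] = bundle["cv"].drop(columns="fold").std().to_dict()
    if "attribution" in bundle:
        payload["attribution"] = bundle["attribution"].drop(columns="method").to_dict("records")
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
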