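"""Packing-angle predictors: gradient boosted regression, a classifier-gated
variant and a multi-layer-perceptron baseline.

All predictors are scikit-learn style estimators (``fit`` / ``predict`` /
``get_params``) so they compose with pipelines and model selection.  The
shipped hyperparameter defaults are the grid-search optima used for the
production models:

* regression: alpha 0.01, learning_rate 0.1, max_depth 2,
  min_samples_leaf 10, n_estimators 50 000, random_state 100;
* classification (the "gatekeeper"): the same, plus warm_start.

``alpha`` only influences the fit for the huber/quantile losses of
scikit-learn's gradient boosting; with the default squared-error loss it
is recorded but inert.  Both readings are runnable via the ``loss``
parameter (see docs/methods.md for the ambiguity).

The gated predictor buckets angles into three classes -- ``normal``
(-50 to -40 deg inclusive, ~94% of natural antibodies), ``max_outlier``
(above -40) and ``min_outlier`` (below -50) -- trains a gradient boosted
classifier as gatekeeper plus one regressor per class, and routes each
query through the regressor of its predicted class.
"""

from __future__ import annotations

import datetime
import hashlib
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import RepeatedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataset import AngleRecord
from .evaluation import EvalReport, regression_metrics
from .features import FeatureSchema, FeatureVector, get_schema, load_encoding_table

logger = logging.getLogger(__name__)

ANGLE_CLASSES = ("min_outlier", "normal", "max_outlier")
NORMAL_RANGE = (-50.0, -40.0)  # inclusive on both ends


def classify_angle(angle_deg: float) -> str:
    """Three-class label of a packing angle.

    ``normal`` covers -50 to -40 deg inclusive; anything above is a
    ``max_outlier``, anything below a ``min_outlier``.
    """
    if not np.isfinite(angle_deg):
        raise ValueError(f"angle must be finite, got {angle_deg}")
    lo, hi = NORMAL_RANGE
    if angle_deg > hi:
        return "max_outlier"
    if angle_deg < lo:
        return "min_outlier"
    return "normal"


def classify_angles(angles: Iterable[float]) -> np.ndarray:
    return np.array([classify_angle(a) for a in angles], dtype=object)


@dataclass
class GBRConfig:
    """Hyperparameters of the angle regressor (shipped grid-search optima)."""

    alpha: float = 0.01
    learning_rate: float = 0.1
    max_depth: int = 2
    min_samples_leaf: int = 10
    n_estimators: int = 50_000
    random_state: int = 100
    loss: str = "squared_error"


@dataclass
class GBCConfig:
    """Hyperparameters of the gatekeeper classifier."""

    learning_rate: float = 0.1
    max_depth: int = 2
    min_samples_leaf: int = 10
    n_estimators: int = 50_000
    random_state: int = 100
    warm_start: bool = True


def _check_schema_width(X: np.ndarray, schema: FeatureSchema | None) -> None:
    if schema is not None and X.shape[1] != schema.length:
        raise ValueError(
            f"schema {schema.name} expects {schema.length} features, "
            f"got {X.shape[1]}"
        )


class PackingAngleGBR(RegressorMixin, BaseEstimator):
    """Gradient boosted regression of the packing angle from encoded features.

    Parameters default to the shipped grid-search optima.  ``schema``
    names the feature layout the estimator expects ('gbr1'..'gbr4', or
    None to accept any width).
    """

    def __init__(
        self,
        schema: str | None = "gbr4",
        loss: str = "squared_error",
        alpha: float = 0.01,
        learning_rate: float = 0.1,
        max_depth: int = 2,
        min_samples_leaf: int = 10,
        n_estimators: int = 50_000,
        random_state: int = 100,
    ):
        self.schema = schema
        self.loss = loss
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _make_gbr(self) -> GradientBoostingRegressor:
        return GradientBoostingRegressor(
            loss=self.loss,
            alpha=self.alpha,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            n_estimators=self.n_estimators,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        _check_schema_width(X, get_schema(self.schema) if self.schema else None)
        if len(y) < 2 * self.min_samples_leaf:
            raise ValueError(
                f"need at least {2 * self.min_samples_leaf} samples "
                f"(min_samples_leaf={self.min_samples_leaf}), got {len(y)}"
            )
        self.model_ = self._make_gbr().fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.y_range_ = (float(np.min(y)), float(np.max(y)))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.model_.predict(X)


class GatedPackingAngleRegressor(RegressorMixin, BaseEstimator):
    """Classifier-gated angle prediction.

    A gradient boosted classifier assigns each query to min_outlier /
    normal / max_outlier; a per-class gradient boosted regressor (trained
    only on that class's examples, with the standard regression
    hyperparameters) then produces the angle.  ``last_dispatch_counts_``
    records, after each ``predict`` call, how many queries each class
    regressor served.
    """

    def __init__(
        self,
        schema: str | None = "gbr4",
        loss: str = "squared_error",
        alpha: float = 0.01,
        learning_rate: float = 0.1,
        max_depth: int = 2,
        min_samples_leaf: int = 10,
        n_estimators: int = 50_000,
        random_state: int = 100,
        warm_start: bool = True,
    ):
        self.schema = schema
        self.loss = loss
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.warm_start = warm_start

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        _check_schema_width(X, get_schema(self.schema) if self.schema else None)
        labels = classify_angles(y)
        counts = Counter(labels)
        too_small = [
            c for c in ANGLE_CLASSES if counts.get(c, 0) < 2 * self.min_samples_leaf
        ]
        if too_small:
            raise ValueError(
                f"classes {too_small} have fewer than "
                f"{2 * self.min_samples_leaf} training examples; widen the "
                "data or use the plain (ungated) regressor"
            )
        self.classifier_ = GradientBoostingClassifier(
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            warm_start=self.warm_start,
        ).fit(X, labels)
        self.regressors_ = {}
        for cls in ANGLE_CLASSES:
            mask = labels == cls
            reg = PackingAngleGBR(
                schema=None,
                loss=self.loss,
                alpha=self.alpha,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                n_estimators=self.n_estimators,
                random_state=self.random_state,
            )
            self.regressors_[cls] = reg.fit(X[mask], y[mask])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_class(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        X = check_array(X)
        return self.classifier_.predict(X)

    def predict(self, X):
        check_is_fitted(self, "classifier_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        labels = self.classifier_.predict(X)
        out = np.empty(len(X), dtype=float)
        dispatch: Counter = Counter()
        for cls in ANGLE_CLASSES:
            mask = labels == cls
            if np.any(mask):
                out[mask] = self.regressors_[cls].predict(X[mask])
                dispatch[cls] = int(mask.sum())
        self.last_dispatch_counts_ = dict(dispatch)
        return out


class PackingAngleMLP(RegressorMixin, BaseEstimator):
    """Single-hidden-layer perceptron baseline (15 rectified-linear units).

    Mirrors scikit-learn's MLPRegressor defaults except for the hidden
    layer size and iteration cap.  Non-convergence is logged as a warning
    but the fitted model is still returned.
    """

    def __init__(
        self,
        schema: str | None = "gbr4",
        hidden: int = 15,
        max_iter: int = 1200,
        alpha: float = 1e-4,
        random_state: int | None = None,
    ):
        self.schema = schema
        self.hidden = hidden
        self.max_iter = max_iter
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        _check_schema_width(X, get_schema(self.schema) if self.schema else None)
        model = MLPRegressor(
            hidden_layer_sizes=(self.hidden,),
            activation="relu",
            alpha=self.alpha,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                logger.warning("MLP did not converge in %d iterations", self.max_iter)
        self.model_ = model
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.model_.predict(X)


# ---------------------------------------------------------------------------
# bundles and thin functional wrappers


@dataclass
class ModelBundle:
    """A trained predictor plus the feature schema and provenance it expects."""

    schema: FeatureSchema
    kind: str  # 'gbr' | 'gated' | 'mlp'
    model: Any
    metadata: dict = field(default_factory=dict)

    def predict_vector(self, x: FeatureVector | np.ndarray) -> float:
        if isinstance(x, FeatureVector):
            if x.schema != self.schema.name:
                raise ValueError(
                    f"bundle expects schema {self.schema.name}, got {x.schema}"
                )
            x = x.values
        x = np.asarray(x, dtype=float).reshape(1, -1)
        if x.shape[1] != self.schema.length:
            raise ValueError(
                f"bundle expects {self.schema.length} features, got {x.shape[1]}"
            )
        return float(self.model.predict(x)[0])

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path, expect_schema: str | None = None) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a ModelBundle")
        if expect_schema is not None and bundle.schema.name != get_schema(expect_schema).name:
            raise ValueError(
                f"bundle was trained with schema {bundle.schema.name}, "
                f"refusing to use it as {expect_schema}"
            )
        return bundle


def records_to_xy(
    records: Sequence[AngleRecord], schema: str | FeatureSchema
) -> tuple[np.ndarray, np.ndarray]:
    """Encode angle records into a feature matrix and target vector."""
    schema = get_schema(schema)
    table = load_encoding_table()
    X = np.empty((len(records), schema.length))
    y = np.empty(len(records))
    for i, rec in enumerate(records):
        if len(rec.feature_residues) != len(schema.residue_positions):
            raise ValueError(
                f"{rec.id}: residue string length {len(rec.feature_residues)} "
                f"does not match schema {schema.name}"
            )
        parts = [table.encode(aa if aa != "-" else None) for aa in rec.feature_residues]
        if schema.include_loop_lengths:
            if rec.loop_lengths is None:
                raise ValueError(f"{rec.id}: schema {schema.name} needs loop lengths")
            parts.append(np.asarray(rec.loop_lengths, dtype=float))
        X[i] = np.concatenate(parts)
        y[i] = rec.angle_deg
    return X, y


def _dataset_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _bundle(schema, kind: str, model, config) -> ModelBundle:
    return ModelBundle(
        schema=get_schema(schema),
        kind=kind,
        model=model,
        metadata={
            "config": asdict(config) if config is not None else {},
            "trained": datetime.datetime.now().isoformat(timespec="seconds"),
        },
    )


def _to_xy(train, schema):
    if train and isinstance(train[0], AngleRecord):
        return records_to_xy(train, schema)
    X = np.array([fv.values if isinstance(fv, FeatureVector) else fv for fv, _ in train])
    y = np.array([a for _, a in train], dtype=float)
    return X, y


def train_gbr(
    train, schema: str | FeatureSchema = "gbr4", config: GBRConfig | None = None
) -> ModelBundle:
    """Train the plain gradient boosted regressor on (features, angle) data.

    ``train`` is either a list of :class:`AngleRecord` or a list of
    (FeatureVector-or-array, angle) pairs.
    """
    config = config or GBRConfig()
    X, y = _to_xy(train, schema)
    est = PackingAngleGBR(schema=get_schema(schema).name, **asdict(config)).fit(X, y)
    bundle = _bundle(schema, "gbr", est, config)
    bundle.metadata["dataset_hash"] = _dataset_hash(X, y)
    return bundle


def train_gated(
    train,
    schema: str | FeatureSchema = "gbr4",
    gbc: GBCConfig | None = None,
    gbr: GBRConfig | None = None,
) -> ModelBundle:
    """Train the gatekeeper classifier plus three class-specific regressors."""
    gbc = gbc or GBCConfig()
    gbr = gbr or GBRConfig()
    X, y = _to_xy(train, schema)
    est = GatedPackingAngleRegressor(
        schema=get_schema(schema).name,
        loss=gbr.loss,
        alpha=gbr.alpha,
        learning_rate=gbr.learning_rate,
        max_depth=gbr.max_depth,
        min_samples_leaf=gbr.min_samples_leaf,
        n_estimators=gbr.n_estimators,
        random_state=gbr.random_state,
        warm_start=gbc.warm_start,
    ).fit(X, y)
    bundle = _bundle(schema, "gated", est, gbr)
    bundle.metadata["gbc_config"] = asdict(gbc)
    bundle.metadata["dataset_hash"] = _dataset_hash(X, y)
    return bundle


def train_mlp(
    train,
    schema: str | FeatureSchema = "gbr4",
    hidden: int = 15,
    max_iter: int = 1200,
    alpha: float = 1e-4,
    seed: int | None = None,
) -> ModelBundle:
    """Train the multi-layer-perceptron baseline."""
    X, y = _to_xy(train, schema)
    est = PackingAngleMLP(
        schema=get_schema(schema).name,
        hidden=hidden,
        max_iter=max_iter,
        alpha=alpha,
        random_state=seed,
    ).fit(X, y)
    bundle = _bundle(schema, "mlp", est, None)
    bundle.metadata["dataset_hash"] = _dataset_hash(X, y)
    return bundle


def predict(bundle: ModelBundle, x) -> float:
    """Predict the packing angle for one antibody.

    ``x`` may be a FeatureVector, a raw feature array, an FvStructure or
    a numbered-sequence mapping; structures and sequences are featurized
    with the bundle's schema.
    """
    from .features import featurize
    from .structure_io import FvStructure

    if isinstance(x, (FvStructure, dict)):
        x = featurize(x, bundle.schema)
    return bundle.predict_vector(x)


def cross_validate(
    records: Sequence[AngleRecord],
    schema: str | FeatureSchema = "gbr4",
    estimator: BaseEstimator | None = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 100,
) -> tuple[EvalReport, list[EvalReport], np.ndarray]:
    """Repeated K-fold cross-validation with pooled out-of-fold metrics.

    Every record is predicted exactly once per repeat by a model that was
    not trained on it.  Returns the report on the pooled out-of-fold
    predictions, the per-fold reports, and the pooled prediction array of
    shape (repeats, n) aligned with ``records``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(records) < folds:
        raise ValueError(f"need at least {folds} records for {folds}-fold CV")
    schema = get_schema(schema)
    X, y = records_to_xy(records, schema)
    base = estimator if estimator is not None else PackingAngleGBR(schema=schema.name)
    cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    oof = np.full((repeats, len(records)), np.nan)
    fold_reports: list[EvalReport] = []
    for i, (train_idx, test_idx) in enumerate(cv.split(X)):
        rep = i // folds
        model = clone(base).fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        oof[rep, test_idx] = pred
        if len(test_idx) >= 2:
            fold_reports.append(regression_metrics(y[test_idx], pred))
    pooled = regression_metrics(np.tile(y, repeats), oof.ravel())
    return pooled, fold_reports, oof
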