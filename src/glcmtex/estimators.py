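"""Scikit-learn style estimators wrapping the texture pipeline.

``GLCMFeatureExtractor`` turns (volume, mask) pairs into the multi-scale
descriptor matrix; ``MultiGroupHybridSelector`` is the adaptive group-wise
feature selector; ``GLCMGroupCNNClassifier`` classifies stacked GLCM
channels.  All three follow the fit/transform/predict contract and compose
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import features as feat
from .evalstats import make_scheme
from .glcm import compute_glcm_set, quantize_roi, DEFAULT_CLEANSE_THRESHOLD, DEFAULT_N_LEVELS
from .mgcnn import CNNConfig, build_model, train_cnn
from .selection import ClassifierConfig, FeatureTable, mghm_select

__all__ = [
    "GLCMFeatureExtractor",
    "MultiGroupHybridSelector",
    "GLCMGroupCNNClassifier",
]


class GLCMFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer: list of (volume, mask) pairs -> descriptor matrix.

    Stateless apart from recorded metadata; ``fit`` inspects one sample to
    populate ``feature_names_`` and ``group_assignment_``.
    """

    def __init__(
        self,
        n_levels: int = DEFAULT_N_LEVELS,
        cleanse_threshold: float = DEFAULT_CLEANSE_THRESHOLD,
        symmetrize: bool = True,
        registry: str = "eHM28",
    ):
        self.n_levels = n_levels
        self.cleanse_threshold = cleanse_threshold
        self.symmetrize = symmetrize
        self.registry = registry

    def _registry(self) -> feat.MeasureRegistry:
        if self.registry == "eHM28":
            return feat.default_registry()
        if self.registry == "haralick14":
            return feat.haralick14_registry()
        raise ValueError(f"unknown registry {self.registry!r}")

    def _one(self, pair, registry):
        vol, mask = pair
        roi = quantize_roi(vol, mask, n_levels=self.n_levels,
                           cleanse_threshold=self.cleanse_threshold)
        return feat.build_descriptor(compute_glcm_set(roi), registry,
                                     symmetrize=self.symmetrize)

    def fit(self, X, y=None):
        registry = self._registry()
        desc = self._one(X[0], registry)
        self.feature_names_ = desc.feature_names
        self.group_assignment_ = np.empty(len(desc.values), dtype=int)
        for g in (1, 2, 3):
            self.group_assignment_[desc.group_slices[g]] = g
        self.n_features_out_ = len(desc.values)
        return self

    def transform(self, X):
        check_is_fitted(self, "feature_names_")
        registry = self._registry()
        return np.vstack([self._one(pair, registry).values for pair in X])


class MultiGroupHybridSelector(TransformerMixin, BaseEstimator):
    """Adaptive multi-group feature selector (random forest + SVM wrapper).

    ``fit`` runs the two-stage procedure - per-group Gini ranking and
    forward-stepwise selection, baseline/complement splitting, descriptor-pool
    ordering and hierarchical integration - on the training data using an
    internal repeated two-fold scheme.  ``transform`` keeps the selected
    columns.  ``group_assignment`` maps each column to its scale group;
    without one, all columns form a single group.
    """

    def __init__(
        self,
        group_assignment=None,
        n_trees: int = 5000,
        n_repeats: int = 10,
        min_improve: float = 0.0,
        seed: int = 0,
    ):
        self.group_assignment = group_assignment
        self.n_trees = n_trees
        self.n_repeats = n_repeats
        self.min_improve = min_improve
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = (
            np.asarray(self.group_assignment)
            if self.group_assignment is not None
            else np.ones(X.shape[1], dtype=int)
        )
        table = FeatureTable(
            matrix=X,
            labels=y,
            feature_labels=[f"f{i}" for i in range(X.shape[1])],
            group_assignment=groups,
        )
        scheme = make_scheme(y, kind="two-fold", n_repeats=self.n_repeats,
                             seed=self.seed)
        result, splits = mghm_select(
            table, ClassifierConfig(seed=self.seed), scheme,
            n_trees=self.n_trees, seed=self.seed, min_improve=self.min_improve,
        )
        self.selected_idx_ = result.selected
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[result.selected] = True
        self.levels_ = result.levels
        self.pool_order_ = result.pool_order
        self.group_splits_ = splits
        self.auc_mean_ = result.final_auc
        self.auc_std_ = result.final_std
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return self.selected_idx_ if indices else self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]


class GLCMGroupCNNClassifier(ClassifierMixin, BaseEstimator):
    """Classifier over stacked GLCM channels (N, C, L, L) using the small CNN."""

    def __init__(
        self,
        epochs: int = 40,
        learning_rate: float = 1e-3,
        lr_decay_factor: float = 0.01,
        lr_decay_every: int = 10,
        batch_size: int | None = None,
        seed: int = 0,
    ):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.batch_size = batch_size
        self.seed = seed

    def _config(self, input_size: int) -> CNNConfig:
        return CNNConfig(
            input_size=input_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            lr_decay_factor=self.lr_decay_factor,
            lr_decay_every=self.lr_decay_every,
            batch_size=self.batch_size,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 4:
            raise ValueError(f"expected (N, C, L, L) input, got shape {X.shape}")
        self.classes_ = np.unique(y)
        cfg = self._config(X.shape[2])
        self.model_ = build_model(X.shape[1], cfg, seed=self.seed)
        self.loss_trace_ = train_cnn(self.model_, X, y, cfg, seed=self.seed)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
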