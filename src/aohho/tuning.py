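"""Scikit-learn-style hyperparameter search driven by the AO-HHO hybrid.

:class:`HyperparameterSearch` plays the role of a ``SearchCV`` object: ``fit``
runs the metaheuristic over the mixed search space, minimizing the composite
loss+cost objective, then refits a :class:`~aohho.cnn.CNNClassifier` with the
best configuration on the full training data.  Fitted attributes follow the
sklearn convention (``best_params_``, ``best_estimator_``, ``best_objective_``,
``history_``), and prediction delegates to the refitted estimator.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cnn import CNNClassifier
from .hybrid import HybridConfig, optimize
from .pipeline import ObjectiveWeights, make_objective, max_time_proxy
from .space import HyperparameterSpace
from .synth import ImageDataset

__all__ = ["HyperparameterSearch"]


class HyperparameterSearch(ClassifierMixin, BaseEstimator):
    """Tune CNN hyperparameters with AO, HHO or the AO->HHO hybrid.

    Parameters
    ----------
    space : HyperparameterSpace
        The mixed search space (defaults to the standard one).
    algorithm : {"ao-hho", "ao", "hho"}
        Which optimizer drives the search.
    population_size, max_iterations, switch_fraction, epsilon, patience
        Optimizer budget and convergence test; the switch fraction sets the
        AO->HHO hand-off point as a fraction of the iteration budget.
    tune_epochs, refit_epochs
        Training epochs per fitness evaluation and for the final refit.
    lambda1, lambda2
        Composite-objective weights (loss vs. normalized training cost).
    augmenter
        Optional per-image augmentation callable applied during the refit.
    random_state
        Seeds the optimizer, the fitness splits and the refit.
    """

    def __init__(self, space: Optional[HyperparameterSpace] = None,
                 algorithm: str = "ao-hho", population_size: int = 6,
                 max_iterations: int = 8, switch_fraction: float = 0.5,
                 epsilon: float = 1e-4, patience: int = 10,
                 tune_epochs: int = 3, refit_epochs: int = 5,
                 lambda1: float = 1.0, lambda2: float = 0.1,
                 augmenter=None, random_state: Optional[int] = None):
        self.space = space
        self.algorithm = algorithm
        self.population_size = population_size
        self.max_iterations = max_iterations
        self.switch_fraction = switch_fraction
        self.epsilon = epsilon
        self.patience = patience
        self.tune_epochs = tune_epochs
        self.refit_epochs = refit_epochs
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.augmenter = augmenter
        self.random_state = random_state

    def fit(self, X, y):
        space = self.space or HyperparameterSpace()
        X = CNNClassifier._as_images(X)
        y = np.asarray(y)
        data = ImageDataset(images=X, labels=y.astype(int),
                            class_names=tuple(str(c) for c in np.unique(y)))
        n_fit = int(round(len(data) * 0.8))
        weights = ObjectiveWeights(
            lambda1=self.lambda1, lambda2=self.lambda2,
            time_normalizer=max_time_proxy(space, n_fit, self.tune_epochs),
        )
        self.evaluation_log_ = []
        fitness = make_objective(data, weights=weights, train_epochs=self.tune_epochs,
                                 seed=self.random_state, space=space,
                                 log=self.evaluation_log_)
        config = HybridConfig(
            population_size=self.population_size, max_iterations=self.max_iterations,
            switch_fraction=self.switch_fraction, epsilon=self.epsilon,
            patience=self.patience, seed=self.random_state,
        )
        result = optimize(fitness, space, config, algorithm=self.algorithm)
        self.best_config_ = result.best_config
        self.best_params_ = result.best_config.as_dict()
        self.best_objective_ = result.best_objective
        self.history_ = result.history
        self.evaluations_used_ = result.evaluations_used
        self.converged_early_ = result.converged_early

        self.best_estimator_ = CNNClassifier(
            learning_rate=self.best_config_.learning_rate,
            batch_size=self.best_config_.batch_size,
            base_filters=self.best_config_.base_filters,
            dropout=self.best_config_.dropout_rate,
            optimizer=self.best_config_.optimizer_kind,
            epochs=self.refit_epochs,
            augmenter=self.augmenter,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.best_estimator_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict_proba(X)
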