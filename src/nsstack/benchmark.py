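"""Method factories for the replicate benchmark.

Each method is a callable ``method(train_dataset, seed) -> predict``
with ``predict(test_dataset) -> probabilities``, the contract used by
:func:`nsstack.evaluation.replicate_experiment`.

The three stacking variants share one first layer: within a replicate
the out-of-fold prediction matrix and the full-data sub-model refits
are computed once and reused by every super learner (they depend only
on the base learner and the fold plan, not on the second layer).
"""

from __future__ import annotations

import numpy as np

from .penalized_glm import lasso_cv
from .stacking import (
    LassoLearner,
    cv_base_predictions,
    fit_super,
    make_folds,
    segment,
)

__all__ = ["make_methods", "SUPER_IDS"]

SUPER_IDS = {"nsslasso-stack": "nsslasso", "nlasso-stack": "nlasso",
             "lbfgs-stack": "lbfgs"}


def _lasso_single_model(d_train, seed: int):
    """Plain lasso logistic regression on all features (no grouping)."""
    fit, _, _, _ = lasso_cv(d_train.X, d_train.y, family="binomial",
                            nonneg=False, seed=seed)

    def predict(d_test):
        return fit.predict(d_test.X)

    return predict


class _SharedFirstLayer:
    """Per-replicate cache of the CV prediction matrix and sub-model refits."""

    def __init__(self, learner_factory=LassoLearner):
        self.learner_factory = learner_factory
        self.key = None
        self.Z = None
        self.fitted_subs = None
        self.group_names = None

    def get(self, d_train, seed: int):
        key = (id(d_train), seed)
        if key != self.key:
            learner = self.learner_factory()
            plan = make_folds(d_train.y, K=5, seed=seed, stratified=True)
            Z = cv_base_predictions(d_train.X, d_train.y, d_train.groups,
                                    learner, plan,
                                    feature_names=d_train.feature_names)
            sub = segment(d_train.X, d_train.groups,
                          feature_names=d_train.feature_names)
            fitted = {name: learner.fit(sub[name], d_train.y, seed=seed)
                      for name in d_train.groups.names}
            self.key = key
            self.Z = Z
            self.fitted_subs = fitted
            self.group_names = d_train.groups.names
        return self.Z, self.fitted_subs, self.group_names


def _stack_method(super_id: str, shared: _SharedFirstLayer):
    def method(d_train, seed: int):
        Z, fitted, names = shared.get(d_train, seed)
        w0, w, _ = fit_super(Z, d_train.y, super_learner=super_id,
                             family="binomial", seed=seed)
        groups = d_train.groups

        def predict(d_test):
            sub = segment(d_test.X, groups, feature_names=d_test.feature_names)
            F = np.column_stack([fitted[n].predict(sub[n]) for n in names])
            eta = w0 + F @ w
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))

        return predict

    return method


def make_methods(names: list[str]) -> dict:
    """Build the method mapping for a benchmark run."""
    shared = _SharedFirstLayer()
    methods = {}
    for name in names:
        if name == "lasso":
            methods[name] = _lasso_single_model
        elif name in SUPER_IDS:
            methods[name] = _stack_method(SUPER_IDS[name], shared)
        else:
            raise ValueError(f"unknown method {name!r}")
    return methods
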