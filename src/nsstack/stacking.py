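"""Two-layer stacking with group-segmented base learners.

The pipeline mirrors the classic stacked-generalization recipe,
specialized to grouped omics features:

1.  ``segment`` splits the feature matrix by a :class:`GroupStructure`
    (e.g. pathway membership; overlaps allowed — a shared feature simply
    appears in every group that lists it).
2.  ``cv_base_predictions`` fits one base learner per group under a
    shared K-fold plan and collects the pooled out-of-fold predictions
    into the N x J matrix Z.  Every entry is strictly out-of-fold, so Z
    is an honest covariate matrix for the second layer.
3.  ``fit_super`` regresses y on Z with one of three super learners,
    all constrained to non-negative weights: the spike-and-slab lasso
    (``nsslasso``), a non-negative lasso with CV-chosen uniform penalty
    (``nlasso``), or an unpenalized box-constrained maximum-likelihood
    GLM (``lbfgs``).  No sum-to-one constraint is imposed.
4.  ``refit_and_stack`` refits each sub-model on the full training data
    and packages everything; prediction for a new sample x is
    h^{-1}(w0 + sum_j w_j f_j(x)).

``screen_groups`` supports the pre-modelling filter used on real data:
rank groups by the CV AUC of their single-group base learner and keep
those above a threshold (or the top m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Protocol

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import KFold, StratifiedKFold

from .evaluation import auc
from .penalized_glm import GlmFit, log_likelihood, lasso_cv
from .spike_slab import SpikeSlabPrior, fit_nsslasso, select_s0_cv

__all__ = [
    "GroupStructure",
    "FoldPlan",
    "SubModel",
    "StackedModel",
    "BaseLearner",
    "LassoLearner",
    "BASE_LEARNERS",
    "make_folds",
    "segment",
    "fit_base_lasso",
    "cv_base_predictions",
    "fit_super",
    "refit_and_stack",
    "normalize_weights",
    "screen_groups",
]


class GroupStructure:
    """Ordered mapping from group names to member feature identifiers.

    Overlapping membership is allowed; empty groups are not.
    """

    def __init__(self, groups: Mapping[str, Iterable[str]]):
        self._groups: dict[str, list[str]] = {}
        for name, members in groups.items():
            members = list(members)
            if not members:
                raise ValueError(f"group {name!r} is empty")
            if name in self._groups:
                raise ValueError(f"duplicate group name {name!r}")
            self._groups[name] = members

    @property
    def names(self) -> list[str]:
        return list(self._groups)

    def members(self, name: str) -> list[str]:
        return list(self._groups[name])

    def items(self):
        return self._groups.items()

    def __len__(self) -> int:
        return len(self._groups)

    def __contains__(self, name: str) -> bool:
        return name in self._groups

    def subset(self, names: Iterable[str]) -> "GroupStructure":
        return GroupStructure({n: self._groups[n] for n in names})

    def validate_against(self, feature_names: Iterable[str]) -> None:
        known = set(feature_names)
        for name, members in self._groups.items():
            missing = [m for m in members if m not in known]
            if missing:
                raise KeyError(
                    f"group {name!r} references unknown feature(s): {missing[:5]}"
                )


@dataclass(frozen=True)
class FoldPlan:
    """A fixed K-fold assignment (labels 1..K), reproducible from its seed."""

    K: int
    assignment: np.ndarray
    seed: int
    stratified: bool

    def split(self):
        """Yield (train_idx, val_idx) pairs for folds 1..K."""
        for k in range(1, self.K + 1):
            val = np.flatnonzero(self.assignment == k)
            train = np.flatnonzero(self.assignment != k)
            yield train, val


def make_folds(y: np.ndarray, K: int = 5, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Partition samples into K mutually exclusive, exhaustive folds of
    (roughly) equal size, optionally stratified by the binary outcome so
    per-fold event counts differ by at most one."""
    y = np.asarray(y).ravel()
    n = y.shape[0]
    if not (2 <= K <= n):
        raise ValueError("K must be between 2 and N")
    assignment = np.zeros(n, dtype=np.int64)
    if stratified:
        n_events = int(np.sum(y == 1))
        if n_events < K or (n - n_events) < K:
            raise ValueError(
                "stratified folds require at least K samples in each class"
            )
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros((n, 1)), y)
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros((n, 1)))
    for k, (_, val) in enumerate(splits, start=1):
        assignment[val] = k
    if not stratified:
        for k in range(1, K + 1):
            if np.sum(y[assignment == k] == 1) == 0:
                warnings.warn(f"fold {k} contains no events", RuntimeWarning, stacklevel=2)
    return FoldPlan(K=K, assignment=assignment, seed=seed, stratified=stratified)


def segment(
    X: pd.DataFrame | np.ndarray,
    groups: GroupStructure,
    feature_names: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Split the feature matrix into one sub-matrix per group.

    Columns follow the order in which each group lists its members;
    features shared between groups are duplicated into every sub-matrix.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        values = X.to_numpy(dtype=np.float64)
    else:
        values = np.asarray(X, dtype=np.float64)
        if feature_names is None:
            feature_names = [str(i) for i in range(values.shape[1])]
    index = {name: i for i, name in enumerate(feature_names)}
    out: dict[str, np.ndarray] = {}
    for name, members in groups.items():
        try:
            cols = [index[m] for m in members]
        except KeyError as exc:
            raise KeyError(
                f"group {name!r} references unknown feature {exc.args[0]!r}"
            ) from None
        out[name] = np.ascontiguousarray(values[:, cols])
    return out


@dataclass
class SubModel:
    """A per-group base model refit on the full training data."""

    group_id: str
    learner: str
    feature_names: list[str]
    intercept: float
    coefficients: np.ndarray
    family: str = "binomial"
    cv_auc: float | None = None
    hyper: dict = field(default_factory=dict)

    def predict(self, Xg: np.ndarray) -> np.ndarray:
        fit = GlmFit(self.intercept, self.coefficients, np.nan, 0, True, self.family)
        return fit.predict(Xg)


class BaseLearner(Protocol):
    """Pluggable first-layer learner: ``fit`` on a group sub-matrix, return
    an object with ``predict(Xg) -> mean response`` (probabilities for a
    binomial outcome)."""

    name: str

    def fit(self, Xg: np.ndarray, y: np.ndarray, seed: int): ...


class _FittedLasso:
    def __init__(self, fit: GlmFit):
        self._fit = fit
        self.intercept = fit.intercept
        self.coefficients = fit.coefficients

    def predict(self, Xg: np.ndarray) -> np.ndarray:
        return self._fit.predict(Xg)


class LassoLearner:
    """Lasso GLM base learner with the penalty chosen by inner K-fold CV
    at minimum mean held-out deviance, then refit at that penalty on all
    rows supplied."""

    name = "lasso"

    def __init__(self, family: str = "binomial", inner_cv: int = 5,
                 n_lambda: int = 12, lambda_min_ratio: float = 0.01):
        self.family = family
        self.inner_cv = inner_cv
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio

    def fit(self, Xg: np.ndarray, y: np.ndarray, seed: int = 0) -> _FittedLasso:
        y = np.asarray(y, dtype=np.float64).ravel()
        if self.family == "binomial" and min(np.sum(y == 1), np.sum(y == 0)) < 2:
            warnings.warn(
                "fewer than 2 events: falling back to intercept-only sub-model",
                RuntimeWarning, stacklevel=2,
            )
            ybar = float(np.clip(y.mean(), 1e-8, 1 - 1e-8))
            fit = GlmFit(float(np.log(ybar / (1 - ybar))),
                         np.zeros(Xg.shape[1]), np.nan, 0, True, self.family)
            return _FittedLasso(fit)
        fit, _, _, _ = lasso_cv(
            Xg, y, family=self.family, nonneg=False, n_folds=self.inner_cv,
            seed=seed, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
        )
        return _FittedLasso(fit)


BASE_LEARNERS: dict[str, Callable[..., BaseLearner]] = {"lasso": LassoLearner}


def fit_base_lasso(Xg: np.ndarray, y: np.ndarray, inner_cv: int = 5,
                   seed: int = 0, family: str = "binomial",
                   group_id: str = "", feature_names: list[str] | None = None) -> SubModel:
    """Convenience wrapper producing a :class:`SubModel` from the lasso learner."""
    learner = LassoLearner(family=family, inner_cv=inner_cv)
    fitted = learner.fit(np.asarray(Xg, dtype=np.float64), y, seed=seed)
    return SubModel(
        group_id=group_id, learner="lasso",
        feature_names=feature_names or [str(i) for i in range(np.asarray(Xg).shape[1])],
        intercept=fitted.intercept, coefficients=fitted.coefficients,
        family=family, hyper={"inner_cv": inner_cv},
    )


def cv_base_predictions(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    groups: GroupStructure,
    learner: BaseLearner,
    fold_plan: FoldPlan,
    feature_names: list[str] | None = None,
) -> np.ndarray:
    """The N x J matrix of pooled out-of-fold base-learner predictions.

    Entry (n, j) is the prediction for sample n from the group-j learner
    trained only on the folds that do NOT contain n.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    if fold_plan.assignment.shape[0] != n:
        raise ValueError("fold plan does not cover all rows")
    sub = segment(X, groups, feature_names=feature_names)
    Z = np.full((n, len(groups)), np.nan)
    for j, name in enumerate(groups.names):
        Xg = sub[name]
        for k, (tr, va) in enumerate(fold_plan.split(), start=1):
            fold_seed = int(
                np.random.SeedSequence([fold_plan.seed, k]).generate_state(1)[0]
                % (2**31)
            )
            try:
                fitted = learner.fit(Xg[tr], y[tr], seed=fold_seed)
            except Exception as exc:
                raise RuntimeError(
                    f"base learner failed for group {name!r} on fold {k}: {exc}"
                ) from exc
            Z[va, j] = fitted.predict(Xg[va])
    assert not np.isnan(Z).any()
    return Z


def _fit_lbfgs_super(Z: np.ndarray, y: np.ndarray, family: str) -> tuple[float, np.ndarray]:
    """Box-constrained (w >= 0) maximum-likelihood GLM, no penalty."""
    n, J = Z.shape

    def negll(par):
        eta = par[0] + Z @ par[1:]
        return -log_likelihood(y, eta, family)

    def grad(par):
        eta = par[0] + Z @ par[1:]
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        else:
            mu = eta
        r = mu - y
        return np.concatenate(([r.sum()], Z.T @ r))

    x0 = np.zeros(J + 1)
    bounds = [(None, None)] + [(0.0, None)] * J
    res = minimize(negll, x0, jac=grad, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9})
    return float(res.x[0]), np.maximum(res.x[1:], 0.0)


def fit_super(
    Z: np.ndarray,
    y: np.ndarray,
    super_learner: str = "nsslasso",
    family: str = "binomial",
    seed: int = 0,
    s0_grid: np.ndarray | None = None,
    n_folds: int = 5,
    prior: SpikeSlabPrior | None = None,
) -> tuple[float, np.ndarray, dict]:
    """Fit the second-layer model on the CV prediction matrix Z.

    All three variants return non-negative weights and an unpenalized
    intercept; no sum-to-one constraint is applied.  Returns
    ``(w0, weights, info)`` where ``info`` carries fit details (selected
    s0 and inclusion probabilities for nsslasso, the chosen penalty for
    nlasso).
    """
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    info: dict = {"super": super_learner}
    if super_learner == "nsslasso":
        template = prior or SpikeSlabPrior(nonneg=True)
        best_s0, cv_table = select_s0_cv(
            Z, y, s0_grid=s0_grid, n_folds=n_folds, seed=seed,
            prior=template, family=family,
        )
        model = fit_nsslasso(Z, y, prior=template.with_s0(best_s0), family=family)
        info.update(s0=best_s0, cv_table=cv_table, p=model.state.p,
                    theta=model.state.theta, model=model)
        return model.state.w0, model.state.w, info
    if super_learner == "nlasso":
        fit, best_lam, grid, mean_dev = lasso_cv(
            Z, y, family=family, nonneg=True, n_folds=n_folds, seed=seed
        )
        info.update(penalty=best_lam)
        return fit.intercept, np.maximum(fit.coefficients, 0.0), info
    if super_learner == "lbfgs":
        w0, w = _fit_lbfgs_super(Z, y, family)
        return w0, w, info
    raise ValueError(f"unknown super learner {super_learner!r}")


@dataclass
class StackedModel:
    """The full two-layer model: refit sub-models plus super-learner weights."""

    w0: float
    weights: np.ndarray
    sub_models: list[SubModel]
    super_learner: str
    family: str
    fold_plan: FoldPlan
    info: dict = field(default_factory=dict)

    @property
    def group_ids(self) -> list[str]:
        return [s.group_id for s in self.sub_models]

    def sub_predictions(self, X, feature_names: list[str] | None = None) -> np.ndarray:
        groups = GroupStructure({s.group_id: s.feature_names for s in self.sub_models})
        sub = segment(X, groups, feature_names=feature_names)
        return np.column_stack(
            [s.predict(sub[s.group_id]) for s in self.sub_models]
        )

    def predict(self, X, feature_names: list[str] | None = None) -> np.ndarray:
        """h^{-1}(w0 + sum_j w_j f_j(x)) on new samples."""
        F = self.sub_predictions(X, feature_names=feature_names)
        eta = self.w0 + F @ self.weights
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        return eta

    def weight_table(self) -> pd.DataFrame:
        rel = normalize_weights(self.weights, warn=False)
        tab = pd.DataFrame({
            "group": self.group_ids,
            "weight": self.weights,
            "relative_weight": rel,
        })
        p = self.info.get("p")
        if p is not None:
            tab["p_inclusion"] = p
        return tab


def refit_and_stack(
    X,
    y: np.ndarray,
    groups: GroupStructure,
    learner: BaseLearner | None = None,
    super_learner: str = "nsslasso",
    fold_plan: FoldPlan | None = None,
    family: str = "binomial",
    seed: int = 0,
    feature_names: list[str] | None = None,
    **super_kwargs,
) -> StackedModel:
    """Run the full two-layer procedure on training data.

    Sub-models are refit on ALL training rows (the CV folds only serve
    to build the out-of-fold prediction matrix for the super learner).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    learner = learner or LassoLearner(family=family)
    if fold_plan is None:
        fold_plan = make_folds(y, K=5, seed=seed, stratified=family == "binomial")
    Z = cv_base_predictions(X, y, groups, learner, fold_plan,
                            feature_names=feature_names)
    w0, w, info = fit_super(Z, y, super_learner=super_learner, family=family,
                            seed=seed, **super_kwargs)
    sub = segment(X, groups, feature_names=feature_names)
    sub_models = []
    for name in groups.names:
        fitted = learner.fit(sub[name], y, seed=seed)
        sub_models.append(SubModel(
            group_id=name, learner=getattr(learner, "name", "custom"),
            feature_names=groups.members(name),
            intercept=float(fitted.intercept),
            coefficients=np.asarray(fitted.coefficients, dtype=np.float64),
            family=family,
        ))
    info = {k: v for k, v in info.items() if k != "model"}
    return StackedModel(w0=w0, weights=w, sub_models=sub_models,
                        super_learner=super_learner, family=family,
                        fold_plan=fold_plan, info=info)


def normalize_weights(weights: np.ndarray, warn: bool = True) -> np.ndarray:
    """Relative weights W_j = w_j / sum(w); all-zero input stays all-zero."""
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        if warn:
            warnings.warn("all weights are zero; relative weights undefined",
                          RuntimeWarning, stacklevel=2)
        return np.zeros_like(w)
    return w / total


def screen_groups(
    X,
    y: np.ndarray,
    groups: GroupStructure,
    learner: BaseLearner | None = None,
    fold_plan: FoldPlan | None = None,
    min_auc: float | None = None,
    top_m: int | None = None,
    family: str = "binomial",
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> tuple[GroupStructure, pd.DataFrame]:
    """Screen groups by the AUC of their out-of-fold base-learner predictions.

    Exactly one of ``min_auc`` (keep groups with CV AUC above the
    threshold) or ``top_m`` (keep the m best) must be given.  Returns the
    retained groups in descending AUC order plus the full score table.
    """
    if (min_auc is None) == (top_m is None):
        raise ValueError("specify exactly one of min_auc or top_m")
    y = np.asarray(y, dtype=np.float64).ravel()
    learner = learner or LassoLearner(family=family)
    if fold_plan is None:
        fold_plan = make_folds(y, K=5, seed=seed, stratified=family == "binomial")
    Z = cv_base_predictions(X, y, groups, learner, fold_plan,
                            feature_names=feature_names)
    scores = np.array([auc(y, Z[:, j]) for j in range(Z.shape[1])])
    table = pd.DataFrame({"group": groups.names, "cv_auc": scores})
    table = table.sort_values("cv_auc", ascending=False, kind="stable").reset_index(drop=True)
    if min_auc is not None:
        kept = table.loc[table["cv_auc"] > min_auc, "group"].tolist()
    else:
        kept = table["group"].head(top_m).tolist()
    return groups.subset(kept), table
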