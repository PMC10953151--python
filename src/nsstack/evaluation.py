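"""Prediction-performance metrics and the replicate experiment runner.

Metrics for a binary outcome y and predicted probabilities p_hat:

* ``deviance``: -2 sum_n [y_n log p_n + (1 - y_n) log(1 - p_n)], with
  probabilities clipped to [1e-8, 1 - 1e-8].
* ``brier``: mean squared difference (1/N) sum (y_n - p_n)^2.
* ``auc``: the Mann-Whitney statistic, P(p_case > p_control) plus half
  the tie probability over all case-control pairs.
* ``misclassification``: fraction with |y_n - p_n| >= 0.5, i.e. the
  predicted class is 1 iff p_n >= 0.5 and the boundary p = 0.5 counts
  as an error for either outcome.

``replicate_experiment`` runs a simulation scenario repeatedly —
independent training/test pair each replicate, every method fit on the
training half and scored on the test half — and aggregates the four
metrics as mean (SD) per method, the layout used for benchmark tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "adjusted_generalized_r2",
    "deviance",
    "brier",
    "auc",
    "misclassification",
    "compute_metrics",
    "balanced_split",
    "replicate_experiment",
]

_PROB_CLIP = 1e-8


def _check_pair(y, p_hat):
    y = np.asarray(y, dtype=np.float64).ravel()
    p = np.asarray(p_hat, dtype=np.float64).ravel()
    if y.shape[0] != p.shape[0]:
        raise ValueError("y and p_hat have different lengths")
    return y, p


def deviance(y, p_hat) -> float:
    """Binomial deviance -2 log-likelihood (probabilities clipped at 1e-8)."""
    y, p = _check_pair(y, p_hat)
    p = np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def brier(y, p_hat) -> float:
    """Brier score: mean squared error of the predicted probability."""
    y, p = _check_pair(y, p_hat)
    return float(np.mean((y - p) ** 2))


def auc(y, p_hat) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count half)."""
    y, p = _check_pair(y, p_hat)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, p))


def misclassification(y, p_hat) -> float:
    """Fraction misclassified at the 0.5 threshold; |y - p| = 0.5 exactly
    (e.g. p = 0.5) counts as an error."""
    y, p = _check_pair(y, p_hat)
    return float(np.mean(np.abs(y - p) >= 0.5))


@dataclass
class MetricsReport:
    """The four test-set metrics for one method on one dataset."""

    deviance: float
    brier: float
    auc: float
    misclassification: float
    n: int
    method: str = ""
    run: str = ""

    @classmethod
    def from_predictions(cls, y, p_hat, method: str = "", run: str = "") -> "MetricsReport":
        y = np.asarray(y, dtype=np.float64).ravel()
        return cls(
            deviance=deviance(y, p_hat),
            brier=brier(y, p_hat),
            auc=auc(y, p_hat),
            misclassification=misclassification(y, p_hat),
            n=y.shape[0],
            method=method,
            run=run,
        )

    def as_dict(self) -> dict:
        return {
            "method": self.method, "run": self.run, "n": self.n,
            "deviance": self.deviance, "brier": self.brier,
            "auc": self.auc, "misclassification": self.misclassification,
        }


compute_metrics = MetricsReport.from_predictions


def adjusted_generalized_r2(y, p_hat, n_params: int = 0) -> float:
    """Nagelkerke generalized R^2 of a fitted binary model, adjusted for
    model complexity.

    The likelihood-ratio statistic G^2 = -2 (ll0 - ll1) is reduced by the
    number of fitted covariates before the Cox-Snell transform, then
    rescaled by its maximum: R^2 = [1 - exp(-(G^2 - k)/N)] / [1 - exp(2 ll0/N)].
    With ``n_params = 0`` this is plain Nagelkerke R^2.
    """
    y, p = _check_pair(y, p_hat)
    n = y.shape[0]
    p = np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)
    ll1 = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    p0 = y.mean()
    if p0 in (0.0, 1.0):
        raise ValueError("outcome has a single class")
    ll0 = n * (p0 * np.log(p0) + (1.0 - p0) * np.log(1.0 - p0))
    g2 = max(-2.0 * (ll0 - ll1) - n_params, 0.0)
    r2_cs = 1.0 - np.exp(-g2 / n)
    return float(r2_cs / (1.0 - np.exp(2.0 * ll0 / n)))


def balanced_split(
    y,
    frac: float = 0.5,
    seed: int = 0,
    p_threshold: float = 0.2,
    max_tries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split retained only if event counts are balanced.

    A candidate split of the stated fraction is accepted when the Pearson
    chi-square test (no continuity correction) on the 2x2 table of
    events/non-events by train/test gives p > ``p_threshold``; otherwise a
    fresh draw is made, up to ``max_tries``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    n_train = int(np.ceil(frac * n))
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        table = np.array([
            [np.sum(y[train] == 1), np.sum(y[train] == 0)],
            [np.sum(y[test] == 1), np.sum(y[test] == 0)],
        ])
        if np.any(table.sum(axis=0) == 0):
            continue
        _, p, _, _ = chi2_contingency(table, correction=False)
        if p > p_threshold:
            return train, test
    raise RuntimeError(f"no balanced split found in {max_tries} tries")


def replicate_experiment(
    spec,
    methods: Mapping[str, Callable],
    n_replicates: int = 100,
    seed: int = 0,
    simulate: Callable | None = None,
) -> pd.DataFrame:
    """Run a scenario's replicate experiment and summarize mean (SD) metrics.

    For each replicate a fresh training/test pair is simulated; every
    method (a callable ``method(dataset_train, seed) -> predict`` where
    ``predict(dataset_test) -> p_hat``) is fit on the training half and
    scored on the test half with all four metrics.  A method failure in
    a replicate is recorded and that replicate is dropped for the method
    only.  Returns a tidy frame with one row per method x metric.
    """
    if simulate is None:
        from .simulation import simulate_scenario
        simulate = simulate_scenario
    ss = np.random.SeedSequence(seed)
    records: list[dict] = []
    failures: dict[str, int] = {name: 0 for name in methods}
    for rep in range(n_replicates):
        child = ss.spawn(1)[0]
        s_train, s_test, s_fit = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3)]
        d_train = simulate(spec, seed=s_train)
        d_test = simulate(spec, seed=s_test)
        for name, method in methods.items():
            try:
                predict = method(d_train, s_fit)
                p_hat = predict(d_test)
                rep_metrics = MetricsReport.from_predictions(
                    d_test.y, p_hat, method=name, run=str(rep)
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures[name] += 1
                warnings.warn(f"method {name!r} failed in replicate {rep}: {exc}",
                              RuntimeWarning, stacklevel=2)
                continue
            records.append(rep_metrics.as_dict())
    per_rep = pd.DataFrame.from_records(records)
    rows = []
    for name in methods:
        sub = per_rep[per_rep["method"] == name]
        for metric in ("deviance", "brier", "auc", "misclassification"):
            vals = sub[metric].to_numpy()
            rows.append({
                "method": name,
                "metric": metric,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sd": float(np.std(vals, ddof=1)) if vals.size >= 2 else np.nan,
                "n_replicates": int(vals.size),
                "n_failures": failures[name],
            })
    summary = pd.DataFrame(rows)
    summary.attrs["per_replicate"] = per_rep
    return summary
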