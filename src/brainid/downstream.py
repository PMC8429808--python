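"""Downstream evaluation: diagnosis classification, age regression, statistics.

A linear classifier with logistic loss is fit on the training-2 identity
features and applied to the held-out test subjects; accuracy against chance
(50%) is assessed with an exact one-sided sign test, i.e. the binomial
upper-tail probability P(X >= n_correct | n, 1/2). A linear (ridge)
regressor predicts age, and agreement with actual age is summarized by
Pearson's r with the two-sided p-value from the t-transform
t = r * sqrt(n-2) / sqrt(1-r^2).

With D features and few training-2 subjects both linear problems are
underdetermined, so both estimators carry a fixed L2 penalty by default
(exposed as a parameter); the design keeps a single fixed split — no
cross-validation, no multiple-testing correction across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, Ridge

from .features import IdentitySet

__all__ = [
    "LinearModel",
    "EvalResult",
    "fit_diagnosis",
    "predict_diagnosis",
    "sign_test",
    "fit_age",
    "predict_age",
    "pearson_test",
    "evaluate_diagnosis",
    "evaluate_age",
    "run_experiment3",
]

PATIENT, CONTROL = "patient", "control"


@dataclass
class LinearModel:
    """Weights + intercept of a fitted linear model."""

    weights: np.ndarray
    intercept: float
    task: str  # diagnosis | age
    loss: str  # logistic | squared

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("non-finite model coefficients")

    def score(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.weights + self.intercept


@dataclass
class EvalResult:
    task: str
    method: str
    n_test: int
    metric: float  # accuracy (diagnosis) or Pearson r (age)
    statistic: float  # n_correct (diagnosis) or r again (age)
    p_value: float
    predictions: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def _binary_labels(groups: Sequence[str]) -> np.ndarray:
    labels = np.asarray([1 if g == PATIENT else 0 for g in groups])
    return labels


def fit_diagnosis(
    identities: IdentitySet,
    groups: Sequence[str],
    c: float = 1.0,
    seed: int = 0,
) -> LinearModel:
    """Logistic-loss linear classifier: patient (1) vs control (0).

    L2-penalized (inverse strength ``c``) with the deterministic lbfgs
    solver, so refitting the same data reproduces the same decision
    function.
    """
    y = _binary_labels(groups)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present in training data")
    clf = LogisticRegression(
        C=c, solver="lbfgs", max_iter=5000, random_state=seed
    )
    clf.fit(identities.values, y)
    return LinearModel(
        weights=clf.coef_[0], intercept=float(clf.intercept_[0]),
        task="diagnosis", loss="logistic",
    )


def predict_diagnosis(model: LinearModel, identities: IdentitySet) -> np.ndarray:
    """Class by the sign of the linear score; an exact 0 ties to control."""
    if identities.values.shape[1] != len(model.weights):
        raise ValueError(
            f"feature dim {identities.values.shape[1]} != model dim "
            f"{len(model.weights)}"
        )
    scores = model.score(identities.values)
    return np.where(scores > 0, PATIENT, CONTROL)


def sign_test(n_correct: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided binomial upper tail P(X >= n_correct | n, p0)."""
    if not (0 <= n_correct <= n):
        raise ValueError(f"need 0 <= n_correct <= n, got {n_correct}/{n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(
        stats.binomtest(n_correct, n, p0, alternative="greater").pvalue
    )


def fit_age(
    identities: IdentitySet, ages: Sequence[float], alpha: float = 1.0
) -> LinearModel:
    """Squared-loss linear age model with ridge penalty ``alpha``."""
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 2:
        raise ValueError("need at least 2 subjects to fit the age model")
    reg = Ridge(alpha=alpha)
    reg.fit(identities.values, ages)
    return LinearModel(
        weights=reg.coef_, intercept=float(reg.intercept_),
        task="age", loss="squared",
    )


def predict_age(model: LinearModel, identities: IdentitySet) -> np.ndarray:
    if identities.values.shape[1] != len(model.weights):
        raise ValueError("feature dimension mismatch")
    return model.score(identities.values)


def pearson_test(predicted: Sequence[float], actual: Sequence[float]) -> tuple[float, float]:
    """Pearson r between predictions and truth, two-sided p via t-transform."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if len(predicted) != len(actual) or len(predicted) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if predicted.std() == 0 or actual.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(predicted, actual)
    return float(res.statistic), float(res.pvalue)


def _cohort_lookup(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort.set_index("subject_id")


def evaluate_diagnosis(
    identities: IdentitySet,
    cohort: pd.DataFrame,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    method: str = "features",
    c: float = 1.0,
    seed: int = 0,
) -> EvalResult:
    """Fit on training-2 identities, score held-out test subjects, sign-test."""
    info = _cohort_lookup(cohort)
    train = identities.subset(list(train_ids))
    test = identities.subset(list(test_ids))
    model = fit_diagnosis(
        train, info.loc[list(train_ids), "group"].tolist(), c=c, seed=seed
    )
    pred = predict_diagnosis(model, test)
    truth = info.loc[list(test_ids), "group"].to_numpy()
    n_correct = int(np.sum(pred == truth))
    n = len(test_ids)
    return EvalResult(
        task="diagnosis",
        method=method,
        n_test=n,
        metric=n_correct / n,
        statistic=float(n_correct),
        p_value=sign_test(n_correct, n),
        predictions=pd.DataFrame(
            {"subject_id": list(test_ids), "predicted": pred, "actual": truth}
        ),
    )


def evaluate_age(
    identities: IdentitySet,
    cohort: pd.DataFrame,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    method: str = "features",
    alpha: float = 1.0,
) -> EvalResult:
    """Ridge age regression on training-2 identities, Pearson test on test."""
    info = _cohort_lookup(cohort)
    train = identities.subset(list(train_ids))
    test = identities.subset(list(test_ids))
    model = fit_age(train, info.loc[list(train_ids), "age"].to_numpy(), alpha=alpha)
    pred = predict_age(model, test)
    truth = info.loc[list(test_ids), "age"].to_numpy(dtype=float)
    r, p = pearson_test(pred, truth)
    return EvalResult(
        task="age",
        method=method,
        n_test=len(test_ids),
        metric=r,
        statistic=r,
        p_value=p,
        predictions=pd.DataFrame(
            {"subject_id": list(test_ids), "predicted": pred, "actual": truth}
        ),
    )


def run_experiment3(
    identities_by_method: Mapping[str, IdentitySet],
    cohort: pd.DataFrame,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    tasks: Sequence[str] = ("diagnosis", "age"),
    c: float = 1.0,
    alpha: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per (method × task): metric, test statistic and p-value.

    Every method is evaluated on the identical train-2/test split; the
    result table mirrors the usual method-comparison figure in
    machine-readable form.
    """
    rows = []
    for method in identities_by_method:
        ids = identities_by_method[method]
        for task in tasks:
            if task == "diagnosis":
                res = evaluate_diagnosis(
                    ids, cohort, train_ids, test_ids, method=method, c=c, seed=seed
                )
            elif task == "age":
                res = evaluate_age(
                    ids, cohort, train_ids, test_ids, method=method, alpha=alpha
                )
            else:
                raise ValueError(f"unknown task {task!r}")
            rows.append(
                {
                    "method": method,
                    "task": task,
                    "n_test": res.n_test,
                    "metric": res.metric,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(
        rows, columns=["method", "task", "n_test", "metric", "statistic", "p_value"]
    )
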