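"""Statistical layer: gated group tests, correlations, explorative model grid, CV.

Conventions throughout: two-sided tests, significance at alpha = 0.05, no
multiple-testing correction (the model grid is explicitly explorative).
Group comparisons are gated on a Shapiro-Wilk normality test per group:
both groups normal -> Welch two-sample t-test, otherwise Wilcoxon rank-sum
(Mann-Whitney) with continuity correction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .discretize import DEFAULT_FEATURE_NAMES

log = logging.getLogger(__name__)

ALPHA = 0.05

#: Endpoints of the explorative grid, in report order.  The two binary
#: endpoints are fit with logistic regression, the rest with OLS.
DEFAULT_ENDPOINTS = (
    "qmg_drop_m12_36",
    "mms_m12_36",
    "qmg_baseline",
    "mg_duration_months",
    "prednisone_pre_g",
    "prednisone_post_g",
)
LOGISTIC_ENDPOINTS = frozenset({"qmg_drop_m12_36", "mms_m12_36"})


class ModelError(ValueError):
    """Degenerate modeling input (zero-variance endpoint, constant predictor...)."""


# ---------------------------------------------------------------------
# group comparison and correlation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GatedTestResult:
    test_used: str  # "t" | "wilcoxon"
    shapiro_p: tuple[float, float]
    statistic: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_ns: tuple[int, int]
    forced: bool = False  # gate forced to wilcoxon (constant group)


def gated_two_group_test(
    values: Sequence[float],
    group_labels: Sequence,
    alpha_gate: float = ALPHA,
) -> GatedTestResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal at ``alpha_gate`` -> Welch t-test; otherwise
    Wilcoxon rank-sum with continuity correction.  A constant group makes
    the normality test undefined and forces the rank test.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) != 2:
        raise ModelError(f"need exactly two groups, got {len(uniq)}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 3 or len(b) < 3:
        raise ModelError("each group needs n >= 3")

    forced = False
    shapiro_p = []
    for g in (a, b):
        if np.ptp(g) == 0:
            shapiro_p.append(float("nan"))
            forced = True
        else:
            shapiro_p.append(float(sps.shapiro(g).pvalue))
    if forced:
        log.warning("constant group values: normality gate forced to wilcoxon")

    normal = (not forced) and all(p > alpha_gate for p in shapiro_p)
    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        used = "t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", use_continuity=True)
        used = "wilcoxon"
    return GatedTestResult(
        test_used=used,
        shapiro_p=(shapiro_p[0], shapiro_p[1]),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        group_ns=(len(a), len(b)),
        forced=forced,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ModelError("Pearson correlation needs n >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ModelError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def entropy_sample_size_check(
    entropy_frame: pd.DataFrame,
    feature: str = "n_follicle_cd23",
    estimator: str = "shannon",
) -> CorrelationResult:
    """Correlate a feature's per-case entropy with its number of measurement points.

    A strong correlation would warn that entropy differences reflect
    sampling depth rather than biology.  Defaults to the per-level Shannon
    estimator: the point-sum statistic scales linearly with m for any fixed
    level distribution, which would make this diagnostic uninformative.
    """
    h = entropy_frame[f"H_{estimator}_{feature}"]
    m = entropy_frame[f"m_{feature}"]
    return pearson_with_p(h.to_numpy(), m.to_numpy())


# ---------------------------------------------------------------------
# explorative model grid
# ---------------------------------------------------------------------

@dataclass
class ModelGridResult:
    """Endpoint x predictor grid of p-values with full per-model detail.

    ``p_values``: DataFrame, rows = endpoints, columns = intercept +
    predictors.  ``families`` maps endpoint -> "logistic" | "linear".
    ``coefficients`` maps endpoint -> DataFrame(coef, se, p).  ``r_squared``
    holds R^2 for the linear rows; ``converged`` flags non-converged /
    separated logistic fits (their cells are NaN, never a crash).
    """

    p_values: pd.DataFrame
    families: dict[str, str]
    coefficients: dict[str, pd.DataFrame]
    r_squared: dict[str, float]
    n_obs: dict[str, int]
    converged: dict[str, bool]
    predictors: tuple[str, ...] = ()

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        """Write the p-value grid with ``*`` marking cells significant at 5 %."""
        out = self.p_values.copy().astype(object)
        for ep in out.index:
            for col in out.columns:
                p = self.p_values.loc[ep, col]
                if pd.isna(p):
                    out.loc[ep, col] = "NA"
                else:
                    star = "*" if p < ALPHA else ""
                    out.loc[ep, col] = f"{p:.4g}{star}"
        out.insert(0, "family", [self.families[ep] for ep in out.index])
        out.index.name = "endpoint"
        out.to_csv(path, sep=sep)

    def to_json(self, path: str | Path) -> None:
        """Full coefficient tables as a JSON sidecar."""
        payload = {
            ep: {
                "family": self.families[ep],
                "n": int(self.n_obs[ep]),
                "converged": bool(self.converged[ep]),
                "r_squared": self.r_squared.get(ep),
                "coefficients": self.coefficients[ep].round(10).to_dict(orient="index"),
            }
            for ep in self.p_values.index
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _entropy_predictor_columns(estimator: str = "pointsum") -> tuple[str, ...]:
    return tuple(f"H_{estimator}_{f}" for f in DEFAULT_FEATURE_NAMES)


def fit_model_grid(
    entropy_frame: pd.DataFrame,
    clinical_frame: pd.DataFrame,
    endpoints: Sequence[str] = DEFAULT_ENDPOINTS,
    predictors: Sequence[str] | None = None,
    estimator: str = "pointsum",
) -> ModelGridResult:
    """Explorative grid: each endpoint modeled on the four entropy features.

    One multivariable fit per endpoint (intercept + all predictors),
    logistic for the binary endpoints and OLS otherwise, on complete-case
    rows (listwise deletion).  Cells hold per-coefficient two-sided
    p-values; separation or non-convergence flags the row instead of
    raising.
    """
    predictors = tuple(predictors or _entropy_predictor_columns(estimator))
    data = clinical_frame.merge(
        entropy_frame.reset_index(), on="case_id", how="inner", validate="one_to_one"
    )
    columns = ("intercept",) + predictors
    p_values = pd.DataFrame(np.nan, index=list(endpoints), columns=list(columns))
    families: dict[str, str] = {}
    coefficients: dict[str, pd.DataFrame] = {}
    r_squared: dict[str, float] = {}
    n_obs: dict[str, int] = {}
    converged: dict[str, bool] = {}

    for ep in endpoints:
        family = "logistic" if ep in LOGISTIC_ENDPOINTS else "linear"
        families[ep] = family
        sub = data[[ep, *predictors]].dropna()
        n_obs[ep] = len(sub)
        y = sub[ep].to_numpy(dtype=float)
        if len(sub) == 0 or np.ptp(y) == 0:
            raise ModelError(f"endpoint {ep}: zero variance (or no complete cases)")
        X = sm.add_constant(sub[list(predictors)].to_numpy(), has_constant="add")
        names = ["intercept", *predictors]
        try:
            if family == "logistic":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                ok = bool(fit.mle_retvals.get("converged", False)) and bool(
                    np.all(np.isfinite(fit.bse))
                )
            else:
                fit = sm.OLS(y, X).fit()
                r_squared[ep] = float(fit.rsquared)
                ok = True
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            log.warning("endpoint %s: fit failed (%s); cells flagged", ep, exc)
            converged[ep] = False
            coefficients[ep] = pd.DataFrame(
                np.nan, index=names, columns=["coef", "se", "p"]
            )
            continue
        converged[ep] = ok
        coefficients[ep] = pd.DataFrame(
            {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}, index=names
        )
        if ok:
            p_values.loc[ep, :] = fit.pvalues
        else:
            log.warning("endpoint %s: logistic fit did not converge; cells flagged", ep)
    return ModelGridResult(
        p_values=p_values,
        families=families,
        coefficients=coefficients,
        r_squared=r_squared,
        n_obs=n_obs,
        converged=converged,
        predictors=predictors,
    )


@dataclass(frozen=True)
class SinglePredictorFit:
    slope: float
    intercept: float
    se: float
    p_value: float
    r_squared: float
    n: int


def fit_single_predictor(
    endpoint: Sequence[float], predictor: Sequence[float]
) -> SinglePredictorFit:
    """OLS of one endpoint on one predictor: slope, two-sided p, R^2."""
    y = np.asarray(endpoint, dtype=float)
    x = np.asarray(predictor, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    if len(y) < 3:
        raise ModelError("single-predictor fit needs n >= 3 complete pairs")
    if np.ptp(x) == 0:
        raise ModelError("constant predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return SinglePredictorFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        n=len(y),
    )


# ---------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CVReport:
    """k-fold CV of a linear model: held-out MSE per fold vs full-data MSE."""

    k: int
    seed: int
    fold_sizes: tuple[int, ...]
    fold_mse: tuple[float, ...]
    mean_mse: float
    sd_mse: float
    full_data_mse: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "fold_sizes": list(self.fold_sizes),
                "fold_mse": list(self.fold_mse),
                "mean_mse": self.mean_mse,
                "sd_mse": self.sd_mse,
                "full_data_mse": self.full_data_mse,
            },
            indent=1,
            sort_keys=True,
        )


def _ols_mse(X_train, y_train, X_test, y_test) -> float:
    A = np.column_stack([np.ones(len(X_train)), X_train])
    coef, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    pred = np.column_stack([np.ones(len(X_test)), X_test]) @ coef
    return float(np.mean((y_test - pred) ** 2))


def kfold_cv(
    endpoint: Sequence[float],
    predictors: Sequence[Sequence[float]] | np.ndarray | pd.DataFrame,
    k: int = 3,
    seed: int = 0,
) -> CVReport:
    """Seeded k-fold CV of an OLS model.

    Cases are shuffled with the given seed and split into k near-equal
    folds (sizes differ by at most one; remainder cases distributed one per
    fold).  Each fold's MSE comes from a model trained on the other k-1
    folds; the full-data training MSE is reported alongside as the
    overfitting check.
    """
    y = np.asarray(endpoint, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ModelError("endpoint and predictors must have equal length")
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[keep], X[keep]
    n, p = X.shape
    if k < 2:
        raise ModelError("k must be >= 2")
    if n < 2 * k:
        raise ModelError(f"need n >= 2k complete cases, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    if min(len(f) for f in folds) < p + 1:
        raise ModelError("fold smaller than predictor count + 1")
    fold_mse = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        fold_mse.append(_ols_mse(X[train_idx], y[train_idx], X[test_idx], y[test_idx]))
    full = _ols_mse(X, y, X, y)
    return CVReport(
        k=k,
        seed=seed,
        fold_sizes=tuple(len(f) for f in folds),
        fold_mse=tuple(fold_mse),
        mean_mse=float(np.mean(fold_mse)),
        sd_mse=float(np.std(fold_mse, ddof=1)),
        full_data_mse=full,
    )
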