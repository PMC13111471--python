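"""Clinical-validation statistics: PLSR/LOOCV, odds ratios, subgroup tables.

The biomechanical predictors (rheology, joint and loading variables) are
strongly collinear, so the continuous WOMAC-improvement outcome is
regressed with partial least squares (NIPALS); predictive accuracy is
reported as leave-one-out cross-validated R^2 and RMSE.  The binary
responder endpoint (>= 30 % WOMAC improvement) is analysed with a
covariate-adjusted logistic regression whose exponentiated alignment
coefficient is the headline odds ratio, plus a per-stratum responder
table with crude odds ratios against the pooled non-aligned arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import RESPONDER_THRESHOLD, Stratum
from .exceptions import ParameterError, RankError, SeparationError
from .io import load_reference_formulations

#: Predictor columns of the cohort design matrix, in order.
PREDICTOR_COLUMNS = [
    "g_prime",
    "eta",
    "tan_delta",
    "mw",
    "concentration",
    "joint_volume",
    "frequency",
    "bmi",
    "kl",
    "steps_day",
]

#: Default number of latent PLSR components (minimises mean LOOCV RMSE
#: on calibration cohorts).
DEFAULT_N_COMPONENTS = 2


def design_matrix(cohort: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Build the (X, y) regression problem from a cohort table.

    Formulation names are resolved against the packaged reference table
    to recover their rheological covariates.
    """
    forms = {f.name: f for f in load_reference_formulations()}
    try:
        rows = [forms[name] for name in cohort["formulation"]]
    except KeyError as exc:
        raise ParameterError(f"unknown formulation in cohort: {exc.args[0]!r}") from None
    X = np.column_stack(
        [
            [f.g_prime for f in rows],
            [f.eta_ref for f in rows],
            [f.tan_delta for f in rows],
            [f.mol_weight for f in rows],
            [f.concentration for f in rows],
            cohort["synovial_volume"].to_numpy(float),
            cohort["frequency"].to_numpy(float),
            cohort["bmi"].to_numpy(float),
            cohort["kl"].to_numpy(float),
            cohort["steps_day"].to_numpy(float),
        ]
    )
    y = cohort["womac_improvement"].to_numpy(float)
    return X, y


@dataclass(frozen=True)
class PLSRModel:
    """Fitted NIPALS partial-least-squares regression (single response)."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p_kept, k)
    x_loadings: np.ndarray  # (p_kept, k)
    y_loadings: np.ndarray  # (k,)
    coef: np.ndarray  # (p,) original scale, dropped columns get 0
    intercept: float
    kept: np.ndarray  # boolean mask of retained columns
    n_components: int

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return X @ self.coef + self.intercept


def plsr_fit(X, y, n_components: int = DEFAULT_N_COMPONENTS) -> PLSRModel:
    """Fit a PLSR model by NIPALS on internally standardised predictors.

    Successive weight vectors maximise covariance between the deflated
    predictor block and the response residual; scores are mutually
    orthogonal, and with ``n_components = rank(X)`` the predictions
    coincide with ordinary least squares.  Constant predictor columns
    are dropped with a warning.

    Raises
    ------
    RankError
        If more components are requested than the predictor block
        supports.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ParameterError(f"X has {n} rows but y has {y.shape[0]}")

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=0)
    kept = x_std > 0.0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} constant predictor column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    if n_components < 1 or n_components > min(n - 1, int(kept.sum())):
        raise RankError(
            f"n_components={n_components} exceeds the rank supported by X "
            f"({n} samples, {int(kept.sum())} non-constant columns)"
        )
    x_scale = np.where(kept, x_std, 1.0)
    Xc = ((X - x_mean) / x_scale)[:, kept]
    y_mean = float(y.mean())
    yc = y - y_mean

    p_kept = Xc.shape[1]
    W = np.zeros((p_kept, n_components))
    P = np.zeros((p_kept, n_components))
    q = np.zeros(n_components)
    eps = np.finfo(float).eps
    for k in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= np.sqrt(eps) * max(1.0, np.linalg.norm(yc)):
            raise RankError(
                f"predictor block deflated to rank {k}; cannot extract component {k + 1}"
            )
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        pk = Xc.T @ t / tt
        qk = float(yc @ t / tt)
        Xc = Xc - np.outer(t, pk)
        yc = yc - qk * t
        W[:, k], P[:, k], q[k] = w, pk, qk

    # regression vector on the standardised scale: B = W (P'W)^-1 q
    beta_std = W @ np.linalg.solve(P.T @ W, q)
    coef = np.zeros(p)
    coef[kept] = beta_std / x_scale[kept]
    intercept = y_mean - float(x_mean @ coef)
    return PLSRModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=intercept,
        kept=kept,
        n_components=n_components,
    )


def loocv_metrics(X, y, n_components: int = DEFAULT_N_COMPONENTS) -> Tuple[float, float]:
    """Leave-one-out cross-validated R^2 and RMSE of the PLSR pipeline.

    Each observation is predicted by a model fitted to the remaining
    n - 1; R^2 = 1 - SSE/SST about the full-sample mean, RMSE is the
    root mean squared leave-one-out error (same units as y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < n_components + 2:
        raise ParameterError(f"need n >= n_components + 2, got n={n}")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise ParameterError("y has zero variance; R^2 undefined")
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-column drops
        for i in range(n):
            mask[i] = False
            model = plsr_fit(X[mask], y[mask], n_components)
            preds[i] = model.predict(X[i])[0]
            mask[i] = True
    sse = float(((y - preds) ** 2).sum())
    return 1.0 - sse / sst, float(np.sqrt(sse / n))


@dataclass(frozen=True)
class OddsRatioResult:
    """Logistic-regression odds ratio with 95 % Wald interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def adjusted_odds_ratio(
    cohort: pd.DataFrame,
    adjustment: Sequence[str] = ("age", "sex"),
) -> OddsRatioResult:
    """Odds ratio for responder status by alignment, covariate-adjusted.

    Fits responder ~ aligned (+ covariates) by maximum-likelihood
    logistic regression (iteratively reweighted least squares) and
    returns exp(coefficient of the alignment flag) with its 95 % Wald
    interval.  With an empty adjustment set this equals the closed-form
    2x2 odds ratio ad/bc.  ``sex`` is encoded as an indicator for male.
    """
    y = cohort["responder"].to_numpy(dtype=float)
    if cohort["aligned"].nunique() < 2:
        raise ParameterError("both alignment arms must be non-empty")
    cols = {"aligned": cohort["aligned"].to_numpy(dtype=float)}
    for cov in adjustment:
        if cov == "sex":
            cols["sex_male"] = (cohort["sex"] == "M").to_numpy(dtype=float)
        else:
            cols[cov] = cohort[cov].to_numpy(dtype=float)
    Xd = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(f"logistic regression failed to converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic regression failed to converge")
    b = float(fit.params["aligned"])
    se = float(fit.bse["aligned"])
    zcrit = float(norm.ppf(0.975))
    return OddsRatioResult(
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - zcrit * se)),
        ci_high=float(np.exp(b + zcrit * se)),
        p_value=float(fit.pvalues["aligned"]),
        n=len(cohort),
    )


def subgroup_analysis(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum responder rates with crude ORs vs the non-aligned arm.

    Returns one row per stratum (A1, A2, A3, N): n, responder percentage
    and the crude 2x2 odds ratio against the pooled non-aligned arm
    (NaN for an empty stratum and for the reference arm itself; +inf
    when the stratum has no non-responders).
    """
    non = cohort[cohort["stratum"] == Stratum.N.value]
    c = int(non["responder"].sum())
    d = len(non) - c
    rows = []
    for s in [Stratum.A1, Stratum.A2, Stratum.A3, Stratum.N]:
        sub = cohort[cohort["stratum"] == s.value]
        n_s = len(sub)
        if n_s == 0:
            rows.append({"stratum": s.value, "n": 0, "responder_pct": np.nan, "crude_or": np.nan})
            continue
        a = int(sub["responder"].sum())
        b = n_s - a
        pct = 100.0 * a / n_s
        if s is Stratum.N or c == 0 or d == 0:
            or_ = np.nan
        elif b == 0:
            or_ = np.inf
        else:
            or_ = (a * d) / (b * c)
        rows.append({"stratum": s.value, "n": n_s, "responder_pct": pct, "crude_or": or_})
    return pd.DataFrame(rows)


def _jsonable(value):
    """Map NaN to null and infinities to strings for strict JSON output."""
    if isinstance(value, float):
        if np.isnan(value):
            return None
        if np.isinf(value):
            return "inf" if value > 0 else "-inf"
    return value


@dataclass(frozen=True)
class ValidationResult:
    """Bundle of the clinical-validation statistics for one cohort."""

    r2_loocv: float
    rmse_loocv: float
    or_adjusted: float
    or_ci: Tuple[float, float]
    p_value: float
    subgroup_table: pd.DataFrame
    n_components: int

    def to_dict(self) -> dict:
        return {
            "r2_loocv": self.r2_loocv,
            "rmse_loocv": self.rmse_loocv,
            "or_adjusted": self.or_adjusted,
            "or_ci_95": list(self.or_ci),
            "p_value": self.p_value,
            "n_components": self.n_components,
            "subgroups": [
                {k: _jsonable(v) for k, v in rec.items()}
                for rec in self.subgroup_table.to_dict(orient="records")
            ],
        }


def validate_cohort(
    cohort: pd.DataFrame,
    n_components: int = DEFAULT_N_COMPONENTS,
    adjustment: Sequence[str] = ("age", "sex"),
) -> ValidationResult:
    """Run the full validation battery on one cohort table.

    The default adjustment set is {age, sex}: both are generated
    independent of outcome, so the conditional and marginal odds ratios
    coincide asymptotically.  Adjusting additionally for BMI — a stratum
    determinant — changes the estimand through non-collapsibility; pass
    ``adjustment=("age", "sex", "bmi")`` explicitly for that variant.
    """
    X, y = design_matrix(cohort)
    r2, rmse = loocv_metrics(X, y, n_components)
    orr = adjusted_odds_ratio(cohort, adjustment)
    return ValidationResult(
        r2_loocv=r2,
        rmse_loocv=rmse,
        or_adjusted=orr.odds_ratio,
        or_ci=(orr.ci_low, orr.ci_high),
        p_value=orr.p_value,
        subgroup_table=subgroup_analysis(cohort),
        n_components=n_components,
    )
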