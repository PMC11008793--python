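"""Model fitting and term tests for the 2x2 design.

Three standard-error regimes for the same linear model ``response ~ sex +
treatment (+ sex:treatment)`` with treatment-dummy coding (reference sex and
control treatment as baselines):

* classical OLS — ``s^2 (X'X)^-1``, valid only under homoscedasticity;
* heteroscedasticity-consistent sandwich covariances (HC0-HC3), which keep
  the OLS point estimates but repair their standard errors;
* feasible GLS — iteratively reweighted least squares with one variance per
  sex, which changes the point estimates too and is the efficient analysis
  when the two sexes genuinely differ in spread.

All tests are two-sided t tests on ``n - k`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datagen import Dataset

__all__ = [
    "FitResult",
    "TermTest",
    "FGLSConvergenceError",
    "fit_ols",
    "fit_fgls",
    "sandwich_cov",
    "term_test",
    "MAIN_TERMS",
    "INTERACTION_TERMS",
]

MAIN_TERMS = ("intercept", "sex", "treatment")
INTERACTION_TERMS = MAIN_TERMS + ("sex:treatment",)

HC_FLAVORS = ("HC0", "HC1", "HC2", "HC3")
SE_SOURCES = ("classical",) + HC_FLAVORS + ("fgls",)


class FGLSConvergenceError(RuntimeError):
    """FGLS failed to converge; carries the last iterate as ``last_fit``."""

    def __init__(self, message: str, last_fit: "FitResult") -> None:
        super().__init__(message)
        self.last_fit = last_fit


@dataclass(frozen=True)
class FitResult:
    """A fitted 2x2 linear model.

    ``cov_classical`` is ``s^2 (X'X)^-1`` for OLS fits and the model-based
    ``(X' W X)^-1`` covariance for FGLS fits.  ``sigma2_by_sex`` holds the
    per-sex residual-variance estimates (FGLS only).
    """

    terms: tuple[str, ...]
    params: np.ndarray
    X: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    df_resid: int
    cov_classical: np.ndarray
    method: str  # "ols" | "fgls"
    sex_is_variable: np.ndarray  # bool per observation
    sigma2_by_sex: tuple[float, float] | None = None
    n_iter: int | None = None
    converged: bool | None = None

    @property
    def nobs(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def param(self, term: str) -> float:
        return float(self.params[self._term_index(term)])

    def _term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(
                f"unknown term {term!r}; available: {list(self.terms)}"
            ) from None

    def summary_dict(self, se_source: str = "classical") -> dict[str, dict]:
        """JSON-ready summary: term -> estimate/SE/t/df/p."""
        out = {}
        for term in self.terms:
            tt = term_test(self, term, se_source=se_source)
            out[term] = {
                "estimate": tt.estimate,
                "se": tt.se,
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
            }
        return out


@dataclass(frozen=True)
class TermTest:
    term: str
    se_source: str
    estimate: float
    se: float
    t: float
    df: int
    p: float


# ----------------------------------------------------------------------
# Design construction

def design_matrix(
    sex_is_variable: np.ndarray, is_treated: np.ndarray, include_interaction: bool
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Treatment-dummy design: intercept, sex, treatment, optional product."""
    cols = [np.ones_like(sex_is_variable, dtype=float),
            sex_is_variable.astype(float),
            is_treated.astype(float)]
    terms: tuple[str, ...] = MAIN_TERMS
    if include_interaction:
        cols.append(cols[1] * cols[2])
        terms = INTERACTION_TERMS
    return np.column_stack(cols), terms


def _dataset_arrays(data: Dataset | pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frame = data.frame if isinstance(data, Dataset) else data
    sex_var = (frame["sex"].to_numpy() == "variable")
    treated = (frame["treatment"].to_numpy() == "treated")
    y = frame["response"].to_numpy(dtype=float)
    return sex_var, treated, y


# ----------------------------------------------------------------------
# OLS

def fit_ols_arrays(
    X: np.ndarray,
    y: np.ndarray,
    terms: tuple[str, ...],
    sex_is_variable: np.ndarray,
) -> FitResult:
    """Least-squares core operating on plain arrays (used by the MC engine)."""
    n, k = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError(
            "rank-deficient design (an empty or confounded cell?)"
        )
    xtx_inv = np.linalg.inv(xtx)
    params = xtx_inv @ (X.T @ y)
    resid = y - X @ params
    leverage = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    df_resid = n - k
    s2 = float(resid @ resid) / df_resid
    return FitResult(
        terms=terms,
        params=params,
        X=X,
        residuals=resid,
        leverage=leverage,
        df_resid=df_resid,
        cov_classical=s2 * xtx_inv,
        method="ols",
        sex_is_variable=sex_is_variable,
    )


def fit_ols(data: Dataset | pd.DataFrame, include_interaction: bool = False) -> FitResult:
    """Fit the 2x2 model by ordinary least squares.

    Requires at least two observations per occupied design cell and a
    full-rank design (all four cells present).
    """
    sex_var, treated, y = _dataset_arrays(data)
    X, terms = design_matrix(sex_var, treated, include_interaction)
    return fit_ols_arrays(X, y, terms, sex_var)


# ----------------------------------------------------------------------
# Sandwich covariances

def _hc_weights(flavor: str, resid: np.ndarray, leverage: np.ndarray, n: int, k: int) -> np.ndarray:
    e2 = resid * resid
    if flavor == "HC0":
        return e2
    if flavor == "HC1":
        return e2 * (n / (n - k))
    if (leverage >= 1.0).any():
        raise ValueError(
            f"{flavor} undefined: a leverage value reaches 1 "
            "(an observation fully determines its own fit)"
        )
    if flavor == "HC2":
        return e2 / (1.0 - leverage)
    if flavor == "HC3":
        return e2 / (1.0 - leverage) ** 2
    raise ValueError(f"unknown sandwich flavor {flavor!r}; choose from {HC_FLAVORS}")


def sandwich_cov(fit: FitResult, flavor: str = "HC3") -> np.ndarray:
    """Heteroscedasticity-consistent coefficient covariance.

    ``(X'X)^-1 X' diag(w) X (X'X)^-1`` with ``w_i = e_i^2`` (HC0), scaled by
    ``n/(n-k)`` (HC1), or leverage-adjusted ``e_i^2/(1-h_i)`` (HC2) and
    ``e_i^2/(1-h_i)^2`` (HC3).  HC3 has the best small-sample behaviour and
    is the default flavor throughout.
    """
    if fit.method != "ols":
        raise ValueError("sandwich covariances apply to OLS fits")
    X = fit.X
    n, k = X.shape
    w = _hc_weights(flavor, fit.residuals, fit.leverage, n, k)
    xtx_inv = np.linalg.inv(X.T @ X)
    meat = (X * w[:, None]).T @ X
    return xtx_inv @ meat @ xtx_inv


# ----------------------------------------------------------------------
# Feasible GLS

def _sex_variances(
    resid: np.ndarray, sex_is_variable: np.ndarray, k: int
) -> tuple[float, float]:
    """Per-sex residual variances with the sex's proportional share of the
    model degrees of freedom removed from each denominator."""
    n = resid.size
    out = []
    for mask in (~sex_is_variable, sex_is_variable):
        n_s = int(mask.sum())
        denom = n_s - k * (n_s / n)
        ss = float(resid[mask] @ resid[mask])
        out.append(ss / denom)
    return out[0], out[1]


def fit_fgls_arrays(
    X: np.ndarray,
    y: np.ndarray,
    terms: tuple[str, ...],
    sex_is_variable: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> FitResult:
    """Iteratively reweighted least squares with one variance per sex."""
    n, k = X.shape
    for mask in (~sex_is_variable, sex_is_variable):
        if mask.sum() < 2:
            raise ValueError("FGLS needs at least 2 observations per sex")
    # start from the OLS residuals
    params = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ params
    last: FitResult | None = None
    for it in range(1, max_iter + 1):
        s2_ref, s2_var = _sex_variances(resid, sex_is_variable, k)
        # degenerate relative to the overall residual scale (or exactly 0)
        floor = 1e-12 * float(resid @ resid) / n
        if s2_ref <= floor or s2_var <= floor:
            raise ValueError(
                f"zero within-sex residual variance (sigma2={s2_ref, s2_var}); "
                "FGLS weights undefined"
            )
        w = np.where(sex_is_variable, 1.0 / s2_var, 1.0 / s2_ref)
        xtwx = (X * w[:, None]).T @ X
        xtwx_inv = np.linalg.inv(xtwx)
        new_params = xtwx_inv @ ((X * w[:, None]).T @ y)
        delta = float(np.max(np.abs(new_params - params)))
        params = new_params
        resid = y - X @ params
        leverage = np.einsum("ij,jk,ik->i", X * w[:, None], xtwx_inv, X)
        last = FitResult(
            terms=terms,
            params=params,
            X=X,
            residuals=resid,
            leverage=leverage,
            df_resid=n - k,
            cov_classical=xtwx_inv,
            method="fgls",
            sex_is_variable=sex_is_variable,
            sigma2_by_sex=(s2_ref, s2_var),
            n_iter=it,
            converged=delta < tol,
        )
        if delta < tol:
            return last
    assert last is not None
    raise FGLSConvergenceError(
        f"FGLS did not converge in {max_iter} iterations "
        f"(last max coefficient change {delta:.3e})",
        last_fit=last,
    )


def fit_fgls(
    data: Dataset | pd.DataFrame,
    include_interaction: bool = False,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> FitResult:
    """Feasible GLS fit with sex-specific variances.

    Alternates a weighted least-squares solve (weights ``1/sigma_hat_sex^2``)
    with re-estimation of the two variances from the current residuals until
    the largest coefficient change drops below ``tol``.  The reported
    covariance is the model-based ``(X' W X)^-1``.
    """
    sex_var, treated, y = _dataset_arrays(data)
    X, terms = design_matrix(sex_var, treated, include_interaction)
    return fit_fgls_arrays(X, y, terms, sex_var, max_iter=max_iter, tol=tol)


# ----------------------------------------------------------------------
# Term tests

def term_test(fit: FitResult, term: str, se_source: str = "classical") -> TermTest:
    """Two-sided t test of one model term.

    ``se_source`` selects the covariance: ``classical`` (OLS or the FGLS
    model-based covariance depending on the fit), ``HC0``..``HC3`` (sandwich,
    OLS fits only) or ``fgls`` (requires an FGLS fit).  The reference
    distribution is Student t on ``n - k`` degrees of freedom for every
    source — conservative relative to a normal reference at small n.
    """
    idx = fit._term_index(term)
    if se_source == "classical":
        cov = fit.cov_classical
    elif se_source in HC_FLAVORS:
        cov = sandwich_cov(fit, se_source)
    elif se_source == "fgls":
        if fit.method != "fgls":
            raise ValueError("se_source='fgls' requires a fit from fit_fgls")
        cov = fit.cov_classical
    else:
        raise ValueError(f"unknown se_source {se_source!r}; choose from {SE_SOURCES}")
    est = float(fit.params[idx])
    se = float(np.sqrt(cov[idx, idx]))
    t = est / se
    p = 2.0 * float(stats.t.sf(abs(t), fit.df_resid))
    return TermTest(
        term=term, se_source=se_source, estimate=est, se=se, t=t,
        df=fit.df_resid, p=p,
    )
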