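"""OLS and two-stage least squares with correct IV uncertainty, plus the
endogeneity and auxiliary tests used around a Mendelian randomization fit.

All effect estimates are reported on the standardized (per-SD) scale with
classical homoskedastic standard errors and 95% confidence intervals of
+/- 1.959964 SE. The 2SLS standard error follows the instrumental-variable
convention: residuals are evaluated at the 2SLS coefficients with the
OBSERVED exposure, not the naive second-stage OLS residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bimr.instruments import FirstStageFit, first_stage_fit

Z_95 = 1.959964  # normal 97.5% quantile, as used for all reported CIs

#: hard floor on the first-stage F below which 2SLS refuses to run
F_HARD_FLOOR = 1.0


@dataclass(frozen=True)
class RegressionResult:
    """Standardized effect estimate with uncertainty."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    method: str  # OLS | 2SLS
    model: str = "crude"  # crude | adjusted
    weak_instrument: bool = False

    def __str__(self) -> str:  # Table-style rendering
        return (
            f"{self.method} ({self.model}): beta={self.beta:.3f} "
            f"({self.ci_low:.3f}, {self.ci_high:.3f}), p={self.p_value:.3g}, n={self.n}"
        )


@dataclass(frozen=True)
class HausmanResult:
    """Durbin-Wu-Hausman comparison of OLS and 2SLS estimates.

    The augmented (control-function) form is always defined; the contrast
    form (beta_IV - beta_OLS)^2 / (var_IV - var_OLS) is reported only when
    the variance difference is positive.
    """

    statistic: float
    p_value: float
    form: str = "augmented_regression"
    contrast_statistic: float | None = None
    contrast_p_value: float | None = None
    note: str = ""


def _as_matrix(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    cov = np.asarray(
        covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates,
        dtype=float,
    )
    if cov.ndim == 1:
        cov = cov[:, None]
    return cov


def _design(n: int, *blocks) -> np.ndarray:
    cols = [np.ones(n)]
    for b in blocks:
        if b is None:
            continue
        b = np.asarray(b, dtype=float)
        cols.append(b[:, None] if b.ndim == 1 else b)
    return np.column_stack(cols)


def _check_conditioning(X: np.ndarray) -> None:
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(f"design matrix is (near-)collinear: condition number {cond:.3g}")


def _classical_fit(X: np.ndarray, y: np.ndarray):
    """beta, se per coefficient, residuals, sigma2 for an OLS design."""
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    return beta, se, resid, sigma2, dof


def ols_fit(outcome, exposure, covariates=None, model: str = "crude") -> RegressionResult:
    """Intercept-included least squares of outcome on exposure (+ covariates).

    Classical homoskedastic SE, t-based p-value.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    cov = _as_matrix(covariates)
    X = _design(len(y), x, cov)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need n > {X.shape[1] + 1}, got {len(y)}")
    _check_conditioning(X)
    beta, se, _, _, dof = _classical_fit(X, y)
    b, s = float(beta[1]), float(se[1])
    p = 2.0 * stats.t.sf(abs(b) / s, dof) if s > 0 else 0.0
    return RegressionResult(
        beta=b,
        se=s,
        ci_low=b - Z_95 * s,
        ci_high=b + Z_95 * s,
        p_value=float(p),
        n=len(y),
        method="OLS",
        model=model,
    )


def wald_ratio(outcome, exposure, instrument) -> float:
    """Single-instrument IV estimate cov(Z, Y) / cov(Z, X)."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    czx = float(np.cov(z, x)[0, 1])
    if czx == 0.0:
        raise ValueError("instrument is uncorrelated with the exposure in-sample")
    return float(np.cov(z, y)[0, 1] / czx)


def tsls_fit(
    outcome,
    exposure,
    instrument,
    covariates=None,
    model: str = "crude",
) -> tuple[RegressionResult, FirstStageFit]:
    """Two-stage least squares with the IV residual convention for SEs.

    Stage 1 regresses the exposure on the instrument (and any exogenous
    covariates); stage 2 regresses the outcome on the stage-1 fitted values
    (and the same covariates). The variance estimate uses residuals
    y - X beta_2sls computed with the observed exposure:
    sigma2 = RSS / (n - p), Var(beta) = sigma2 (Xhat' Xhat)^-1.

    With a single instrument and no covariates the point estimate equals the
    Wald ratio exactly. A first-stage F at or below 10 sets the
    weak-instrument flag; below the hard floor of 1 the fit is refused.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    cov = _as_matrix(covariates)
    n = len(y)
    p_total = 2 + (0 if cov is None else cov.shape[1])
    if n <= p_total + 2:
        raise ValueError(f"need n > {p_total + 2}, got {n}")

    first = first_stage_fit(x, z, covariates=cov)
    f_check = first.partial_f if first.partial_f is not None else first.f_statistic
    if not f_check >= F_HARD_FLOOR:
        raise ValueError(
            f"first-stage F {f_check:.3f} below hard floor {F_HARD_FLOOR}: "
            "instrument carries essentially no signal"
        )
    weak = not f_check > 10.0

    Z_design = _design(n, z, cov)
    x_hat = Z_design @ np.linalg.lstsq(Z_design, x, rcond=None)[0]

    X_hat = _design(n, x_hat, cov)
    _check_conditioning(X_hat)
    beta2, _, _, _ = np.linalg.lstsq(X_hat, y, rcond=None)

    # IV residuals: observed exposure at the 2SLS coefficients
    X_obs = _design(n, x, cov)
    resid = y - X_obs @ beta2
    dof = n - X_hat.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X_hat.T @ X_hat)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))

    b = float(beta2[1])
    p = 2.0 * stats.norm.sf(abs(b) / se) if se > 0 else 0.0
    result = RegressionResult(
        beta=b,
        se=se,
        ci_low=b - Z_95 * se,
        ci_high=b + Z_95 * se,
        p_value=float(p),
        n=n,
        method="2SLS",
        model=model,
        weak_instrument=weak,
    )
    return result, first


def durbin_hausman(outcome, exposure, instrument, covariates=None) -> HausmanResult:
    """Durbin-Wu-Hausman test of exposure endogeneity.

    Primary (always defined) form: augment the OLS outcome model with the
    first-stage residual and t-test its coefficient — under exogeneity the
    residual carries no information about the outcome. Secondary form: the
    estimate contrast (b_IV - b_OLS)^2 / (Var_IV - Var_OLS) against
    chi-square(1), attached only when the variance difference is positive.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    cov = _as_matrix(covariates)
    n = len(y)

    Z_design = _design(n, z, cov)
    v_hat = x - Z_design @ np.linalg.lstsq(Z_design, x, rcond=None)[0]

    X_aug = _design(n, x, cov)
    X_aug = np.column_stack([X_aug, v_hat])
    _check_conditioning(X_aug)
    beta, se, _, _, dof = _classical_fit(X_aug, y)
    t_stat = float(beta[-1] / se[-1])
    p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    res = HausmanResult(statistic=t_stat, p_value=p, form="augmented_regression")

    ols = ols_fit(y, x, covariates=cov)
    try:
        iv, _ = tsls_fit(y, x, z, covariates=cov)
    except ValueError as exc:
        return HausmanResult(
            statistic=t_stat,
            p_value=p,
            form="augmented_regression",
            note=f"contrast form suppressed: {exc}",
        )
    var_diff = iv.se**2 - ols.se**2
    if var_diff > 0:
        c_stat = (iv.beta - ols.beta) ** 2 / var_diff
        return HausmanResult(
            statistic=t_stat,
            p_value=p,
            form="augmented_regression",
            contrast_statistic=float(c_stat),
            contrast_p_value=float(stats.chi2.sf(c_stat, df=1)),
        )
    return HausmanResult(
        statistic=t_stat,
        p_value=p,
        form="augmented_regression",
        note="contrast form suppressed: non-positive variance difference",
    )


def partial_correlation(a, b, covariates=None) -> tuple[float, float]:
    """Pearson correlation of a and b after removing covariate effects.

    Both variables are residualized on the covariates (with intercept); the
    t-test uses n - #covariates - 2 degrees of freedom. With no covariates
    this is the plain Pearson correlation.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    cov = _as_matrix(covariates)
    k = 0 if cov is None else cov.shape[1]
    n = len(x)
    if n <= k + 3:
        raise ValueError(f"need n > {k + 3}, got {n}")
    C = _design(n, cov) if cov is not None else np.ones((n, 1))
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    sx, sy = float(rx @ rx), float(ry @ ry)
    # residuals that are pure rounding noise (variable determined by the
    # covariates) make the correlation meaningless
    if sx <= 1e-10 * float(x @ x) or sy <= 1e-10 * float(y @ y):
        raise ValueError("zero residual variance after removing covariates")
    r = float((rx @ ry) / np.sqrt(sx * sy))
    dof = n - k - 2
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's z-transformation.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    for r in (r1, r2):
        if not abs(r) < 1.0:
            raise ValueError(f"|r| must be < 1, got {r}")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError(f"need n > 3 in each group, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def sex_interaction(
    beta_men: float, se_men: float, beta_women: float, se_women: float
) -> tuple[float, float]:
    """Sex-difference statistic (b_men - b_women) / sqrt(se_men^2 + se_women^2)."""
    if se_men <= 0 or se_women <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_men - beta_women) / np.sqrt(se_men**2 + se_women**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
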