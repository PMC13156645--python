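"""Global Poisson and negative binomial count regression.

Both models use a log link, log(mu_i) = x_i' beta.  The negative binomial
(NB) model is the Poisson-Gamma mixture with variance function

    Var(Y) = mu + theta * mu**2

so ``theta`` here is the *dispersion* parameter (the reciprocal of the
"size" parameter used by some other software); theta -> 0 recovers the
Poisson model.  Beta is estimated by iteratively reweighted least squares
(Fisher scoring) for a given theta, and theta by 1-D maximization of the
profile log-likelihood on a log scale, alternating until the joint fit is
stationary.  Standard errors come from the inverse information at the
optimum; AIC counts theta as one extra parameter.

Also provided: the deviance/df overdispersion diagnostic, Wald Z tests,
VIF collinearity screening, and the simultaneous (deviance vs chi-square)
significance test.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special, stats

from .io import SpatialCountDataset

logger = logging.getLogger("gwnbr")

__all__ = [
    "GLMFit",
    "DispersionDiagnostic",
    "EstimationError",
    "poisson_loglik",
    "nb_logpmf",
    "nb_loglik",
    "fit_poisson",
    "fit_negbin",
    "wald_z",
    "overdispersion_ratio",
    "vif",
    "simultaneous_deviance_test",
    "theta_to_size",
    "size_to_theta",
]

THETA_MIN = 1e-8
THETA_MAX = 1e6


class EstimationError(RuntimeError):
    """Model could not be estimated (rank deficiency, singular information)."""


@dataclasses.dataclass(frozen=True)
class GLMFit:
    """A fitted global count regression model.

    ``coefficients`` has the intercept first; ``theta`` is None for the
    Poisson family.  ``aic = -2 loglik + 2k`` with k = p+1 coefficients
    plus one for theta under the NB family.
    """

    family: str
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    theta: float | None
    log_likelihood: float
    deviance: float
    residual_df: int
    aic: float
    fitted_means: np.ndarray
    pearson_residuals: np.ndarray
    converged: bool
    iterations: int
    parameter_names: tuple[str, ...] = ()

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients) + (1 if self.family == "negbin" else 0)

    def summary_frame(self, alpha: float = 0.05):
        """Per-parameter table: coefficient, SE, Z, p, significance flag."""
        import pandas as pd

        names = self.parameter_names or tuple(
            f"beta{k}" for k in range(len(self.coefficients))
        )
        return pd.DataFrame(
            {
                "parameter": names,
                "coefficient": self.coefficients,
                "std_error": self.standard_errors,
                "z_value": self.z_values,
                "p_value": self.p_values,
                "significant": self.p_values < alpha,
            }
        )


@dataclasses.dataclass(frozen=True)
class DispersionDiagnostic:
    """Deviance/df ratio with an equi-/over-/under-dispersion verdict."""

    ratio: float
    deviance: float
    df: int
    verdict: str


def poisson_loglik(y, mu) -> float:
    """Poisson log-likelihood sum(y*log(mu) - mu - log(y!))."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have the same length")
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    return float(np.sum(special.xlogy(y, mu) - mu - special.gammaln(y + 1.0)))


def nb_logpmf(y, mu, theta: float) -> np.ndarray:
    """Per-observation NB log-density under the Var = mu + theta*mu^2 convention.

    Stable down to theta ~ 1e-8: the two theta-singular terms are combined as
    ``gammaln(y + r) - gammaln(r) - r*log1p(theta*mu)`` with r = 1/theta, and
    y*log(theta*mu/(1+theta*mu)) is evaluated with log1p.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if theta <= 0:
        raise ValueError("theta must be strictly positive")
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    r = 1.0 / theta
    tm = theta * mu
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        - r * np.log1p(tm)
        + special.xlogy(y, tm)
        - y * np.log1p(tm)
    )


def nb_loglik(y, mu, theta: float) -> float:
    """Negative binomial log-likelihood sum (see :func:`nb_logpmf`)."""
    return float(np.sum(nb_logpmf(y, mu, theta)))


def nb_unit_deviance(y, mu, theta: float) -> np.ndarray:
    """Per-observation NB deviance 2*[l(y;y,theta) - l(y;mu,theta)] (>= 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = special.xlogy(y, y / mu) - (y + 1.0 / theta) * (
            np.log1p(theta * y) - np.log1p(theta * mu)
        )
    return 2.0 * term


def _check_design(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved via QR pivoting
        _, R = np.linalg.qr(X)
        small = np.abs(np.diag(R)) < 1e-10 * np.abs(R).max()
        cols = [names[j] for j in np.where(small)[0]] if names else np.where(small)[0].tolist()
        raise EstimationError(f"design matrix is rank deficient; collinear columns: {cols}")


def _finish_fit(family, y, X, res, theta, names) -> GLMFit:
    beta = np.asarray(res.params, dtype=float)
    mu = np.asarray(res.fittedvalues, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    n, k_beta = X.shape
    if family == "poisson":
        ll = poisson_loglik(y, mu)
        var = mu
        k = k_beta
    else:
        ll = nb_loglik(y, mu, theta)
        var = mu + theta * mu**2
        k = k_beta + 1
    pearson = (y - mu) / np.sqrt(var)
    return GLMFit(
        family=family,
        coefficients=beta,
        standard_errors=se,
        z_values=z,
        p_values=pvals,
        theta=theta,
        log_likelihood=ll,
        deviance=float(res.deviance),
        residual_df=n - k_beta,
        aic=-2.0 * ll + 2.0 * k,
        fitted_means=mu,
        pearson_residuals=pearson,
        converged=bool(getattr(res, "converged", True)),
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0)),
        parameter_names=tuple(names),
    )


def _param_names(dataset: SpatialCountDataset) -> list[str]:
    return ["intercept", *dataset.covariate_names]


def fit_poisson(dataset: SpatialCountDataset) -> GLMFit:
    """Maximum-likelihood Poisson regression with log link."""
    y = dataset.response.astype(float)
    X = dataset.design_matrix()
    names = _param_names(dataset)
    _check_design(X, names)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    fit = _finish_fit("poisson", y, X, res, None, names)
    if not fit.converged:
        warnings.warn("Poisson IRLS did not converge", RuntimeWarning, stacklevel=2)
    return fit


def _fit_beta_given_theta(y, X, theta, start=None):
    fam = sm.families.NegativeBinomial(alpha=theta)
    return sm.GLM(y, X, family=fam).fit(start_params=start, maxiter=200)


def fit_negbin(dataset: SpatialCountDataset) -> GLMFit:
    """Joint maximum likelihood NB fit: IRLS for beta, profile likelihood for theta.

    theta is searched on a log scale in [1e-8, 1e6]; a theta estimate at the
    lower bound means the data show no overdispersion (Poisson-compatible)
    and triggers a warning.
    """
    y = dataset.response.astype(float)
    X = dataset.design_matrix()
    names = _param_names(dataset)
    _check_design(X, names)

    start = None

    def neg_profile(log_theta: float) -> float:
        theta = float(np.exp(log_theta))
        res = _fit_beta_given_theta(y, X, theta, start)
        return -nb_loglik(y, np.asarray(res.fittedvalues), theta)

    # warm start the profile search from the Poisson coefficients
    start = np.asarray(sm.GLM(y, X, family=sm.families.Poisson()).fit().params)
    opt = optimize.minimize_scalar(
        neg_profile,
        bounds=(np.log(THETA_MIN), np.log(THETA_MAX)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta_hat = float(np.exp(opt.x))
    if theta_hat <= THETA_MIN * 10:
        warnings.warn(
            "estimated dispersion at lower bound: data consistent with equidispersion",
            RuntimeWarning,
            stacklevel=2,
        )
    res = _fit_beta_given_theta(y, X, theta_hat, start)
    return _finish_fit("negbin", y, X, res, theta_hat, names)


def wald_z(coefficient: float, standard_error: float):
    """Wald Z statistic coefficient/SE with its two-sided normal p-value."""
    if standard_error <= 0:
        raise ValueError("standard error must be positive")
    z = coefficient / standard_error
    return z, 2.0 * float(stats.norm.sf(abs(z)))


def overdispersion_ratio(
    deviance: float, df: int, threshold: float = 1.5
) -> DispersionDiagnostic:
    """Deviance/df overdispersion diagnostic.

    A ratio near 1 supports equidispersion; above ``threshold`` (default
    1.5, the usual rule of thumb) the data are flagged overdispersed, and
    below 1/threshold underdispersed.
    """
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    ratio = deviance / df
    if ratio > threshold:
        verdict = "overdispersed"
    elif ratio < 1.0 / threshold:
        verdict = "underdispersed"
    else:
        verdict = "equidispersed"
    return DispersionDiagnostic(ratio=ratio, deviance=deviance, df=int(df), verdict=verdict)


def vif(covariates: np.ndarray, names=None) -> np.ndarray:
    """Variance inflation factors 1/(1-R^2_j) per covariate column.

    R^2_j comes from an OLS regression of column j on the remaining columns
    plus an intercept.  Exactly collinear columns get ``inf`` with a warning;
    values above 10 are the conventional multicollinearity flag.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two covariates")
    out = np.empty(p)
    for j in range(p):
        xj = X[:, j]
        if np.ptp(xj) == 0:
            raise ValueError(f"covariate column {j} is constant")
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((xj - xj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            label = names[j] if names else j
            warnings.warn(
                f"covariate {label!r} is exactly collinear with the others",
                RuntimeWarning,
                stacklevel=2,
            )
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2)
    return out


def simultaneous_deviance_test(fit: GLMFit, alpha: float = 0.05) -> dict:
    """Simultaneous significance test of the covariates.

    Compares the model deviance statistic against the chi-square critical
    value with df = number of covariates; rejecting means at least one
    covariate matters.
    """
    df = len(fit.coefficients) - 1
    if df < 1:
        raise ValueError("model has no covariates to test")
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    statistic = float(fit.deviance)
    return {
        "test": "simultaneous_deviance",
        "statistic": statistic,
        "df": df,
        "critical_value": critical,
        "alpha": alpha,
        "reject": statistic > critical,
    }


def theta_to_size(theta: float) -> float:
    """Convert the dispersion parameter to the 'size' convention (1/theta)."""
    return 1.0 / theta


def size_to_theta(size: float) -> float:
    """Convert a 'size' parameter to the dispersion convention (1/size)."""
    return 1.0 / size
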