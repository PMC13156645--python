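"""Geographically weighted negative binomial regression (GWNBR).

The model lets both the regression coefficients and the dispersion vary
over space:

    log(mu_i) = x_i' beta(u_i, v_i),     Var(Y_i) = mu_i + theta(u_i, v_i) mu_i^2.

At each focal location i the parameters maximize the kernel-weighted NB
log-likelihood  sum_j w_ij * l_NB(y_j; exp(x_j' beta), theta).  Estimation
is Newton-Raphson on beta (analytic gradient and Hessian, step-halving,
ridge fallback for ill-conditioned Hessians) alternated with a 1-D profile
search for theta on a log scale, initialized from the global NB fit.  Local
standard errors come from the final Hessian; effective model complexity is
the trace of the spatial hat matrix S built from the IRLS working weights.

Derivatives used (per observation, eta = x'beta, mu = exp(eta)):

    dl/deta   = (y - mu) / (1 + theta*mu)
    d2l/deta2 = -mu (1 + theta*y) / (1 + theta*mu)^2

so g = X' [w * (y-mu)/(1+theta*mu)] and H = -X' diag(w * mu(1+theta*y) /
(1+theta*mu)^2) X.  Both are validated against finite differences in the
test suite.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import optimize, stats

from .glm import (
    EstimationError,
    GLMFit,
    fit_negbin,
    nb_logpmf,
    nb_unit_deviance,
)
from .io import SpatialCountDataset
from .kernels import KernelWeights

logger = logging.getLogger("gwnbr")

__all__ = [
    "LocalFit",
    "GWNBRFit",
    "local_weighted_loglik",
    "local_newton_raphson",
    "profile_local_theta",
    "fit_gwnbr",
    "restricted_local_loglik",
    "hat_trace",
]

THETA_LO = 1e-8
THETA_HI = 1e4
_ETA_MAX = 500.0  # cap on the linear predictor to keep exp() finite


@dataclasses.dataclass(frozen=True)
class LocalFit:
    """Parameter estimates and inference at one focal location."""

    index: int
    coords: tuple[float, float]
    coefficients: np.ndarray
    theta: float
    standard_errors: np.ndarray
    z_values: np.ndarray
    log_likelihood: float
    leverage: float
    converged: bool
    iterations: int


@dataclasses.dataclass(frozen=True)
class GWNBRFit:
    """A fitted GWNBR model: n local fits plus whole-model summaries.

    ``log_likelihood`` sums, over units, each unit's NB log-density under
    its own local parameters; ``deviance`` is the matching saturated-model
    deviance; ``aic = -2 loglik + 2 (tr(S) + 1)``, counting one pooled
    dispersion degree of freedom on top of the effective number of
    coefficients tr(S).
    """

    local_fits: tuple[LocalFit, ...]
    kernel: KernelWeights
    fitted_means: np.ndarray
    trace_S: float
    effective_df: float
    deviance: float
    log_likelihood: float
    aic: float
    n_failed: int

    @property
    def coefficients(self) -> np.ndarray:
        """(n, p+1) matrix of local coefficients."""
        return np.vstack([lf.coefficients for lf in self.local_fits])

    @property
    def thetas(self) -> np.ndarray:
        return np.array([lf.theta for lf in self.local_fits])

    def coefficients_frame(self, dataset: SpatialCountDataset):
        import pandas as pd

        names = ["intercept", *dataset.covariate_names]
        df = pd.DataFrame(self.coefficients, columns=names)
        df.insert(0, "unit", list(dataset.unit_labels))
        df.insert(1, "longitude", dataset.coords[:, 0])
        df.insert(2, "latitude", dataset.coords[:, 1])
        df["theta"] = self.thetas
        return df

    def inference_frame(self, dataset: SpatialCountDataset, alpha: float = 0.05):
        import pandas as pd

        names = ["intercept", *dataset.covariate_names]
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        rows = []
        for lf in self.local_fits:
            row: dict = {"unit": dataset.unit_labels[lf.index]}
            for k, name in enumerate(names):
                row[f"{name}_se"] = lf.standard_errors[k]
                row[f"{name}_z"] = lf.z_values[k]
                row[f"{name}_significant"] = abs(lf.z_values[k]) > zcrit
            row["converged"] = lf.converged
            row["iterations"] = lf.iterations
            rows.append(row)
        return pd.DataFrame(rows)


def _mu(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(X @ beta, -_ETA_MAX, _ETA_MAX))


def local_weighted_loglik(beta, theta: float, X, y, w_row) -> float:
    """Kernel-weighted NB log-likelihood at one focal location."""
    w = np.asarray(w_row, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if (w > 0).sum() < X.shape[1] + 1:
        raise ValueError("degenerate weights: local fit underdetermined")
    mu = _mu(X, np.asarray(beta, dtype=float))
    return float(np.sum(w * nb_logpmf(y, mu, theta)))


def _grad_hess(beta, theta, X, y, w):
    mu = _mu(X, beta)
    denom = 1.0 + theta * mu
    g = X.T @ (w * (y - mu) / denom)
    h_w = w * mu * (1.0 + theta * y) / denom**2
    H = -(X.T * h_w) @ X
    return g, H, mu


def local_newton_raphson(X, y, w_row, beta_init, theta: float,
                         tolerance: float = 1e-8, max_iterations: int = 20):
    """Newton-Raphson maximization of the local weighted NB log-likelihood.

    Returns ``(beta, hessian, iterations, converged)``; the Hessian is the
    observed one at the final iterate, for use in local inference.  Steps
    that would decrease the objective are halved (up to 10 times);
    ill-conditioned Hessians get a small ridge, and a still-singular system
    raises :class:`EstimationError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w_row, dtype=float)
    beta = np.asarray(beta_init, dtype=float).copy()
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta_init must be finite")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if (w > 0).sum() < X.shape[1] + 1:
        raise ValueError("degenerate weights: local fit underdetermined")

    ll = local_weighted_loglik(beta, theta, X, y, w)
    converged = False
    it = 0
    H = None
    for it in range(1, max_iterations + 1):
        g, H, _ = _grad_hess(beta, theta, X, y, w)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            ridge = 1e-8 * np.eye(len(beta))
            try:
                step = np.linalg.solve(-H + ridge, g)
                warnings.warn("ridge-stabilized Newton step", RuntimeWarning, stacklevel=2)
            except np.linalg.LinAlgError as exc:
                raise EstimationError("singular Hessian in local Newton-Raphson") from exc
        # step halving: never accept a decrease in the objective
        scale = 1.0
        for _ in range(10):
            cand = beta + scale * step
            ll_new = local_weighted_loglik(cand, theta, X, y, w)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            cand, ll_new = beta, ll  # no admissible step: stop here
        delta = np.max(np.abs(cand - beta))
        beta, ll = cand, ll_new
        if delta < tolerance:
            converged = True
            break
    if H is None:
        _, H, _ = _grad_hess(beta, theta, X, y, w)
    return beta, H, it, converged


def profile_local_theta(X, y, w_row, beta, bounds=(THETA_LO, THETA_HI),
                        tolerance: float = 1e-8, max_iterations: int = 20,
                        max_cycles: int = 50):
    """Local profile-likelihood dispersion estimate.

    Alternates a bounded 1-D maximization of the weighted log-likelihood
    over log(theta) with Newton updates of beta until the joint parameter
    change falls below ``tolerance`` (or ``max_cycles`` alternations).
    Returns ``(theta, beta, hessian, converged)``.  A theta at the lower
    bound means the location is locally equidispersed (Poisson-like).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w_row, dtype=float)
    beta = np.asarray(beta, dtype=float).copy()
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    theta = None
    H = None
    converged = False
    for _ in range(max_cycles):
        res = optimize.minimize_scalar(
            lambda lt: -local_weighted_loglik(beta, float(np.exp(lt)), X, y, w),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-9},
        )
        theta_new = float(np.exp(res.x))
        beta_new, H, _, _ = local_newton_raphson(
            X, y, w, beta, theta_new, tolerance, max_iterations
        )
        change = max(
            np.max(np.abs(beta_new - beta)),
            abs(theta_new - (theta if theta is not None else np.inf)),
        )
        beta, theta = beta_new, theta_new
        if change < max(tolerance, 1e-10):
            converged = True
            break
    if not converged:
        logger.warning("theta/beta alternation did not converge; returning last iterate")
    return theta, beta, H, converged


def fit_gwnbr(dataset: SpatialCountDataset, kernel_weights: KernelWeights,
              config=None, global_fit: GLMFit | None = None,
              max_failed_frac: float = 0.2) -> GWNBRFit:
    """Fit the GWNBR model at every areal unit.

    Each unit gets its own Newton-Raphson fit of beta with a local
    profile-likelihood theta, initialized from the global NB estimates.
    Units whose local estimation fails are flagged and skipped (carrying the
    global estimates); more than ``max_failed_frac`` failures aborts.
    """
    tol = getattr(config, "tolerance", 1e-8) if config is not None else 1e-8
    max_iter = getattr(config, "max_iterations", 20) if config is not None else 20
    y = dataset.response.astype(float)
    X = dataset.design_matrix()
    n, k = X.shape
    if global_fit is None or global_fit.family != "negbin":
        global_fit = fit_negbin(dataset)
    beta0 = global_fit.coefficients
    theta0 = float(np.clip(global_fit.theta, THETA_LO, THETA_HI))

    locals_: list[LocalFit] = []
    n_failed = 0
    for i in range(n):
        w = kernel_weights.matrix[i]
        try:
            beta_i, _, it, conv = local_newton_raphson(X, y, w, beta0, theta0, tol, max_iter)
            theta_i, beta_i, H, prof_conv = profile_local_theta(
                X, y, w, beta_i, tolerance=tol, max_iterations=max_iter
            )
            cov = np.linalg.inv(-H)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                cov = np.linalg.inv(-H + 1e-8 * np.eye(k))
                diag = np.diag(cov)
            se = np.sqrt(np.abs(diag))
            ok = conv and prof_conv
        except (EstimationError, ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("local fit failed at unit %d: %s", i, exc)
            n_failed += 1
            beta_i, theta_i = beta0, theta0
            se = np.full(k, np.nan)
            it, ok = 0, False
        ll_i = local_weighted_loglik(beta_i, theta_i, X, y, w)
        locals_.append(
            LocalFit(
                index=i,
                coords=(float(dataset.coords[i, 0]), float(dataset.coords[i, 1])),
                coefficients=beta_i,
                theta=theta_i,
                standard_errors=se,
                z_values=beta_i / se,
                log_likelihood=ll_i,
                leverage=np.nan,  # filled after hat_trace
                converged=ok,
                iterations=it,
            )
        )
    if n_failed > max_failed_frac * n:
        raise EstimationError(
            f"{n_failed}/{n} local fits failed; bandwidth or data unsuitable"
        )

    B = np.vstack([lf.coefficients for lf in locals_])
    thetas = np.array([lf.theta for lf in locals_])
    mu_hat = np.exp(np.clip(np.sum(X * B, axis=1), -_ETA_MAX, _ETA_MAX))

    leverages = _leverages(X, kernel_weights.matrix, B, thetas)
    tr_s = float(np.sum(leverages))
    locals_ = [dataclasses.replace(lf, leverage=float(leverages[lf.index]))
               for lf in locals_]

    ll = float(np.sum([nb_logpmf(np.array([y[i]]), np.array([mu_hat[i]]), thetas[i])[0]
                       for i in range(n)]))
    dev = float(np.sum([nb_unit_deviance(np.array([y[i]]), np.array([mu_hat[i]]),
                                         thetas[i])[0] for i in range(n)]))
    aic = -2.0 * ll + 2.0 * (tr_s + 1.0)
    return GWNBRFit(
        local_fits=tuple(locals_),
        kernel=kernel_weights,
        fitted_means=mu_hat,
        trace_S=tr_s,
        effective_df=n - tr_s,
        deviance=dev,
        log_likelihood=ll,
        aic=aic,
        n_failed=n_failed,
    )


def restricted_local_loglik(dataset: SpatialCountDataset,
                            kernel_weights: KernelWeights,
                            theta_init: float | None = None,
                            tolerance: float = 1e-8,
                            max_iterations: int = 20) -> float:
    """Log-likelihood of the covariate-free GWNBR (local intercepts + local theta).

    This is the restricted model of the MLRT simultaneous test: each
    location keeps its own intercept and dispersion but drops every
    covariate, so the test df equals the number of covariates.  Returns
    sum_i l(y_i; mu_i, theta_i) with each unit evaluated under its own
    local fit.
    """
    y = dataset.response.astype(float)
    n = dataset.n
    X0 = np.ones((n, 1))
    beta0 = np.array([np.log(max(y.mean(), 0.1))])
    theta0 = float(np.clip(theta_init if theta_init is not None else 1.0,
                           THETA_LO, THETA_HI))
    total = 0.0
    for i in range(n):
        w = kernel_weights.matrix[i]
        beta_i, _, _, _ = local_newton_raphson(X0, y, w, beta0, theta0,
                                               tolerance, max_iterations)
        theta_i, beta_i, _, _ = profile_local_theta(
            X0, y, w, beta_i, tolerance=tolerance, max_iterations=max_iterations
        )
        mu_i = float(np.exp(np.clip(beta_i[0], -_ETA_MAX, _ETA_MAX)))
        total += float(nb_logpmf(np.array([y[i]]), np.array([mu_i]), theta_i)[0])
    return total


def _leverages(X, W, B, thetas) -> np.ndarray:
    """Diagonal of the spatial hat matrix S.

    s_ii = a_ii * x_i' (X' A_i X)^{-1} x_i with A_i = diag(w_ij * v_j) and
    v_j = mu_j / (1 + theta_i * mu_j) the IRLS working weights of the local
    fit at i (a_ii = v_i since the self-weight is 1).
    """
    n, k = X.shape
    s = np.empty(n)
    for i in range(n):
        mu = np.exp(np.clip(X @ B[i], -_ETA_MAX, _ETA_MAX))
        v = mu / (1.0 + thetas[i] * mu)
        a = W[i] * v
        M = (X.T * a) @ X
        try:
            sol = np.linalg.solve(M, X[i])
        except np.linalg.LinAlgError:
            warnings.warn(
                f"ridge-stabilized leverage at unit {i}", RuntimeWarning, stacklevel=2
            )
            sol = np.linalg.solve(M + 1e-8 * np.eye(k), X[i])
        s[i] = a[i] * float(X[i] @ sol)
    return s


def hat_trace(X, kernel_matrix, local_coefficients, local_thetas) -> float:
    """Trace of the spatial hat matrix S (effective number of coefficients)."""
    return float(np.sum(_leverages(np.asarray(X, dtype=float),
                                   np.asarray(kernel_matrix, dtype=float),
                                   np.asarray(local_coefficients, dtype=float),
                                   np.asarray(local_thetas, dtype=float))))
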