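"""Spatial dependence and heterogeneity diagnostics on global-model residuals.

Moran's I (with a zero-diagonal weight matrix) tests for residual spatial
autocorrelation; the Breusch-Pagan score test checks whether residual
variance drifts with the covariates.  In the intended workflow both are
applied to the Pearson residuals of the global negative binomial fit: if
either rejects, a spatially varying (geographically weighted) model is
warranted.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = [
    "MoranResult",
    "BPResult",
    "moran_weights",
    "morans_i",
    "breusch_pagan",
]


@dataclasses.dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    assumption: str  # "normality" or "randomization"

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclasses.dataclass(frozen=True)
class BPResult:
    statistic: float
    df: int
    p_value: float
    variant: str  # "classical" or "koenker"

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def moran_weights(distance_matrix, scheme="inverse_distance", kernel_spec=None,
                  row_standardize: bool = False) -> np.ndarray:
    """Build a zero-diagonal spatial weight matrix from pairwise distances.

    scheme:
        ``"inverse_distance"`` (default): w_ij = 1/d_ij off the diagonal.
        ``"kernel"``: evaluate ``kernel_spec`` (family/mode/bandwidth) on the
        distances, then zero the diagonal; adaptive specs are symmetrized by
        averaging with the transpose.

    The result is symmetric with zero diagonal; ``row_standardize`` rescales
    rows to sum to one (and breaks exact symmetry).
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    if scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            W = np.where(D > 0, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    elif scheme == "kernel":
        if kernel_spec is None:
            raise ValueError("kernel scheme requires a kernel_spec")
        from .kernels import build_kernel_weights

        kw = build_kernel_weights(D, kernel_spec, min_positive=1)
        W = 0.5 * (kw.matrix + kw.matrix.T)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    np.fill_diagonal(W, 0.0)
    if not np.any(W > 0):
        raise ValueError("degenerate weights: all off-diagonal weights are zero")
    if row_standardize:
        sums = W.sum(axis=1, keepdims=True)
        W = np.divide(W, sums, out=np.zeros_like(W), where=sums > 0)
    return W


def morans_i(x, W, assumption: str = "normality") -> MoranResult:
    """Moran's I spatial autocorrelation statistic with analytic inference.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with S0 = sum_ij w_ij.  E(I) = -1/(n-1); the variance uses the classical
    closed form under the normality assumption (default) or under random
    permutation of x, and the z statistic is referred to the standard normal
    (two-sided).
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I requires at least 3 units")
    if W.shape != (n, n):
        raise ValueError("weight matrix shape does not match x")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix must have zero diagonal")
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("x is constant; Moran's I is undefined")
    s0 = float(W.sum())
    if s0 <= 0:
        raise ValueError("weights sum to zero")
    num = float(d @ W @ d)
    I = (n / s0) * num / denom
    expected = -1.0 / (n - 1)
    s1 = 0.5 * float(((W + W.T) ** 2).sum())
    rs = W.sum(axis=1)
    cs = W.sum(axis=0)
    s2 = float(((rs + cs) ** 2).sum())
    if assumption == "normality":
        var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / (
            (n * n - 1.0) * s0 * s0
        ) - expected**2
    elif assumption == "randomization":
        b2 = n * float((d**4).sum()) / denom**2
        var = (
            n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
            - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
        ) / ((n - 1.0) * (n - 2.0) * (n - 3.0) * s0 * s0) - expected**2
    else:
        raise ValueError(f"unknown variance assumption {assumption!r}")
    if var <= 1e-15:
        # degenerate topology (e.g. complete graph at small n): I is
        # deterministic and equals its expectation
        z = 0.0 if abs(I - expected) < 1e-10 else math.copysign(math.inf, I - expected)
        var = max(var, 0.0)
    else:
        z = (I - expected) / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return MoranResult(I=I, expected=expected, variance=var, z=z, p_value=p,
                       assumption=assumption)


def breusch_pagan(residuals, covariates, variant: str = "classical") -> BPResult:
    """Breusch-Pagan test for residual variance depending on the covariates.

    The classical form (default) is the score statistic

        BP = (1/2) f' Z (Z'Z)^{-1} Z' f,   f_i = e_i^2 / sigma2_hat - 1,

    with sigma2_hat = sum(e^2)/n and Z = [1 | standardized covariates];
    it is chi-square with df = number of covariate columns.  The
    ``"koenker"`` variant is the studentized version (n * R^2 of e^2 on Z),
    robust to non-normal residuals.
    """
    e = np.asarray(residuals, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(e):
        raise ValueError("residuals and covariates must have the same length")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more observations than covariates plus intercept")
    sigma2 = float(e @ e) / n
    if sigma2 == 0:
        raise ValueError("residuals are all zero")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate column in heterogeneity test")
    Zs = (X - X.mean(axis=0)) / sd
    Z = np.column_stack([np.ones(n), Zs])
    f = e**2 / sigma2 - 1.0
    ztz = Z.T @ Z
    try:
        coef = np.linalg.solve(ztz, Z.T @ f)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Z'Z in Breusch-Pagan test") from exc
    if variant == "classical":
        statistic = 0.5 * float(f @ Z @ coef)
    elif variant == "koenker":
        g = e**2
        gc = g - g.mean()
        coef_g = np.linalg.solve(ztz, Z.T @ g)
        resid = g - Z @ coef_g
        r2 = 1.0 - float(resid @ resid) / float(gc @ gc)
        statistic = n * r2
    else:
        raise ValueError(f"unknown Breusch-Pagan variant {variant!r}")
    statistic = max(statistic, 0.0)
    p_value = float(stats.chi2.sf(statistic, p))
    return BPResult(statistic=statistic, df=p, p_value=p_value, variant=variant)
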