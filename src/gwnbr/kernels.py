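"""Distance matrices, spatial kernel weights, and CV bandwidth selection.

Kernel weights enter the geographically weighted likelihood: observation j
contributes to the local fit at location i with weight w_ij = K(d_ij / b_i).
Two families are supported,

    bisquare:  (1 - (d/b)^2)^2  for d < b, else 0   (compact support)
    gaussian:  exp(-(d/b)^2 / 2)                    (always positive)

in fixed mode (one bandwidth b, in distance units) or adaptive mode (b_i =
distance to the ceil(q*n)-th nearest neighbour, q a proportion in (0, 1]).
The self-weight at d = 0 is always 1 — unlike the zero-diagonal matrices
used for Moran's I.

The bandwidth is chosen by minimizing the leave-one-out cross-validation
score CV(b) = sum_i (y_i - yhat_{-i}(b))^2, where yhat_{-i} comes from the
local fit at i with the self-weight forced to zero.  The search is a
golden-section line search (log scale for fixed bandwidths), and the
evaluated (bandwidth, CV) curve is returned for auditing.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger("gwnbr")

__all__ = [
    "KernelSpec",
    "KernelWeights",
    "DegenerateBandwidthError",
    "euclidean_distance_matrix",
    "bisquare_weight",
    "gaussian_weight",
    "adaptive_bandwidths",
    "build_kernel_weights",
    "cv_score",
    "select_bandwidth",
]

#: CV value assigned to a bandwidth at which too many local fits degenerate
CV_SENTINEL = np.inf


class DegenerateBandwidthError(ValueError):
    """Bandwidth leaves some location with too few positive weights."""


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Kernel family ('gaussian' | 'bisquare'), mode ('fixed' | 'adaptive'),
    and bandwidth (distance if fixed, neighbour proportion in (0,1] if
    adaptive)."""

    family: str
    mode: str
    bandwidth: float

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "bisquare"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown kernel mode {self.mode!r}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.mode == "adaptive" and self.bandwidth > 1.0:
            raise ValueError("adaptive bandwidth is a proportion in (0, 1]")

    def label(self) -> str:
        return f"{self.mode} {self.family}"


@dataclasses.dataclass(frozen=True)
class KernelWeights:
    """n x n kernel weight matrix (diagonal 1) with per-location bandwidths."""

    matrix: np.ndarray
    bandwidths: np.ndarray
    spec: KernelSpec


def euclidean_distance_matrix(coords) -> np.ndarray:
    """Pairwise planar Euclidean distances between coordinate pairs."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    return squareform(pdist(coords, metric="euclidean"))


def bisquare_weight(d, b):
    """Bisquare kernel (1 - (d/b)^2)^2 for d < b, else 0."""
    if np.any(np.asarray(b) <= 0):
        raise ValueError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    u = d / b
    w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w if w.ndim else float(w)


def gaussian_weight(d, b):
    """Gaussian kernel exp(-(d/b)^2 / 2)."""
    if np.any(np.asarray(b) <= 0):
        raise ValueError("bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    w = np.exp(-0.5 * (d / b) ** 2)
    return w if w.ndim else float(w)


_KERNELS = {"bisquare": bisquare_weight, "gaussian": gaussian_weight}


def adaptive_bandwidths(distance_matrix, q: float, min_neighbors: int | None = None
                        ) -> np.ndarray:
    """Per-location adaptive bandwidths b_i.

    b_i is the distance from unit i to its ceil(q*n)-th nearest neighbour
    (self excluded; capped at the n-1 available neighbours).  Distance ties
    are broken by unit order, so the result is deterministic.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two units")
    if not 0.0 < q <= 1.0:
        raise ValueError("adaptive proportion q must lie in (0, 1]")
    k = min(math.ceil(q * n), n - 1)
    if min_neighbors is not None and k < min_neighbors:
        warnings.warn(
            f"adaptive bandwidth uses only {k} neighbours; local fits may be "
            f"underdetermined (need {min_neighbors})",
            RuntimeWarning,
            stacklevel=2,
        )
    b = np.empty(n)
    for i in range(n):
        neigh = np.sort(np.delete(D[i], i), kind="stable")
        b[i] = neigh[k - 1]
    if np.any(b <= 0):
        raise ValueError("zero adaptive bandwidth: duplicated coordinates")
    return b


def build_kernel_weights(distance_matrix, spec: KernelSpec,
                         min_positive: int = 2) -> KernelWeights:
    """Evaluate a kernel spec into an n x n weight matrix (diagonal 1).

    ``min_positive`` is the minimum number of positive weights each row must
    keep for the local fit to be determined (use p + 2 for a model with p
    covariates); a bisquare bandwidth violating it raises
    :class:`DegenerateBandwidthError` naming the unit.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    kern = _KERNELS[spec.family]
    if spec.mode == "fixed":
        b = np.full(n, float(spec.bandwidth))
    else:
        b = adaptive_bandwidths(D, spec.bandwidth, min_neighbors=min_positive)
    W = np.vstack([kern(D[i], b[i]) for i in range(n)])
    np.fill_diagonal(W, 1.0)
    counts = (W > 0).sum(axis=1)
    if np.any(counts < min_positive):
        bad = int(np.argmin(counts))
        raise DegenerateBandwidthError(
            f"unit {bad} has only {counts[bad]} positive weights "
            f"(need {min_positive}); bandwidth too small"
        )
    return KernelWeights(matrix=W, bandwidths=b, spec=spec)


def cv_score(dataset, spec: KernelSpec, theta: float,
             beta_init=None, max_degenerate_frac: float = 0.2) -> float:
    """Leave-one-out CV score sum_i (y_i - yhat_{-i})^2 for one bandwidth.

    Each yhat_{-i} = exp(x_i' beta_{-i}) comes from the local NB fit at
    location i with the self-weight zeroed and the dispersion fixed at
    ``theta``.  Locations whose local fit fails contribute a large penalty;
    if more than ``max_degenerate_frac`` of them fail the bandwidth is
    rejected with a sentinel score.
    """
    from .gwnbr import local_newton_raphson  # deferred: avoids import cycle

    if theta <= 0:
        raise ValueError("theta must be positive")
    y = dataset.response.astype(float)
    X = dataset.design_matrix()
    n, k = X.shape
    D = euclidean_distance_matrix(dataset.coords)
    try:
        kw = build_kernel_weights(D, spec, min_positive=k + 1)
    except DegenerateBandwidthError:
        return CV_SENTINEL
    if beta_init is None:
        beta_init = np.zeros(k)
        beta_init[0] = np.log(max(y.mean(), 0.1))
    score = 0.0
    n_bad = 0
    penalty = float(np.sum((y - y.mean()) ** 2)) + 1.0
    for i in range(n):
        w = kw.matrix[i].copy()
        w[i] = 0.0
        if (w > 0).sum() < k + 1:
            n_bad += 1
            score += penalty
            continue
        try:
            beta, _, _, converged = local_newton_raphson(
                X, y, w, beta_init, theta
            )
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            converged = False
        if not converged:
            n_bad += 1
            score += penalty
            logger.debug("CV: location %d failed at bandwidth %s", i, spec.bandwidth)
            continue
        eta = float(np.clip(X[i] @ beta, -500, 500))
        score += (y[i] - math.exp(eta)) ** 2
    if n_bad > max_degenerate_frac * n:
        logger.info(
            "bandwidth %s rejected: %d/%d locations degenerate", spec.bandwidth, n_bad, n
        )
        return CV_SENTINEL
    return float(score)


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def select_bandwidth(dataset, family: str, mode: str, theta: float,
                     beta_init=None, rel_tol: float = 1e-3):
    """Golden-section search for the CV-minimizing bandwidth.

    Fixed mode searches log-bandwidth between (roughly) the smallest
    non-degenerate distance scale and twice the data diameter; adaptive mode
    searches the neighbour proportion q in [(p+2)/n, 1].  Returns the chosen
    :class:`KernelSpec` and the list of evaluated (bandwidth, CV) pairs.
    """
    y = dataset.response
    k = dataset.p + 1
    D = euclidean_distance_matrix(dataset.coords)
    off = D[~np.eye(len(y), dtype=bool)]
    curve: list[tuple[float, float]] = []

    if mode == "fixed":
        # smallest scale keeping every row determined even for bisquare
        kth = np.sort(D, axis=1)[:, min(k + 1, len(y) - 1)]
        lo, hi = math.log(float(kth.max()) * 1.05), math.log(2.0 * float(off.max()))
        to_bw = math.exp
    else:
        lo, hi = (k + 1) / len(y), 1.0
        to_bw = float

    def evaluate(t: float) -> float:
        bw = to_bw(t)
        s = cv_score(dataset, KernelSpec(family, mode, bw), theta, beta_init)
        curve.append((bw, s))
        return s

    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = evaluate(c), evaluate(d)
    while abs(b - a) > rel_tol * (abs(a) + abs(b)) / 2.0:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = evaluate(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = evaluate(d)
    t_best = c if fc < fd else d
    finite = [s for _, s in curve if np.isfinite(s)]
    if not finite:
        raise DegenerateBandwidthError("every candidate bandwidth was degenerate")
    if abs(t_best - hi) <= rel_tol * (abs(hi) + abs(lo)):
        warnings.warn(
            "CV decreases out to the upper search bound; returning the bound "
            "(data may favour the global model)",
            RuntimeWarning,
            stacklevel=2,
        )
        t_best = hi
    spec = KernelSpec(family, mode, to_bw(t_best))
    curve.sort(key=lambda t: t[0])
    return spec, curve
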