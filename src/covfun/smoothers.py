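"""Kernel smoothers for conditional means.

This module houses the building blocks used by the conditional covariance
estimator: symmetric kernel densities (Gaussian and Epanechnikov), the
Aitchison-Aitken discrete kernel for categorical covariates, local constant
(Nadaraya-Watson) and local linear conditional-mean estimators for one or
several continuous covariates, and a leave-one-out squared-error bandwidth
selector for the mean.

Conventions
-----------
* A scaled kernel is ``Kh(u) = K(u/h) / h`` with bandwidth ``h > 0`` in
  covariate units.
* With ``q`` continuous covariates the weight of observation ``i`` at point
  ``u`` is the product over dimensions of per-dimension scaled kernels,
  optionally multiplied by Aitchison-Aitken weights for each categorical
  covariate.
* Estimation is only supported where the total kernel weight is
  non-negligible; outside the data range an :class:`ExtrapolationError`
  is raised rather than returning NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import (
    DegenerateNeighborhoodError,
    ExtrapolationError,
    InvalidParameterError,
    NoValidBandwidthError,
)

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: relative total-weight threshold below which a point is considered
#: outside the estimable range (sum of kernel weights < n * DEGENERACY_RTOL)
DEGENERACY_RTOL = 1e-12


def _gaussian(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / _SQRT_2PI


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)


KERNEL_FAMILIES = {"gaussian": _gaussian, "epanechnikov": _epanechnikov}


@dataclass(frozen=True)
class KernelSpec:
    """A symmetric kernel density with its bandwidth(s).

    Parameters
    ----------
    family : {"gaussian", "epanechnikov"}
        Kernel shape. The Gaussian kernel has unbounded support and is the
        default (it can never produce an empty neighborhood in the interior
        of the data); the Epanechnikov kernel is compactly supported.
    h : float or sequence of float
        Bandwidth, strictly positive, in the units of the covariate. A
        sequence gives one bandwidth per continuous covariate dimension
        (product kernel).
    """

    family: Literal["gaussian", "epanechnikov"] = "gaussian"
    h: float | Sequence[float] = 1.0

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise InvalidParameterError(
                f"unknown kernel family {self.family!r}; "
                f"choose from {sorted(KERNEL_FAMILIES)}"
            )
        h = np.atleast_1d(np.asarray(self.h, dtype=float))
        if h.ndim != 1 or h.size == 0 or not np.all(np.isfinite(h)) or np.any(h <= 0):
            raise InvalidParameterError(f"bandwidth must be positive and finite, got {self.h!r}")
        object.__setattr__(self, "_h_vec", h)

    @property
    def h_vec(self) -> np.ndarray:
        """Bandwidths as a 1-D array (length 1 for a scalar bandwidth)."""
        return self._h_vec  # type: ignore[attr-defined]


@dataclass(frozen=True)
class CategoricalKernelSpec:
    """Aitchison-Aitken unordered discrete kernel.

    Gives weight ``lam`` to an observation whose factor level matches the
    target level and ``(1 - lam) / (k - 1)`` to each of the other ``k - 1``
    levels. ``lam = 1`` stratifies (only matching levels contribute);
    ``lam = 1/k`` weights every level uniformly. The weights over the ``k``
    levels always sum to one.
    """

    lam: float
    k: int

    def __post_init__(self):
        if self.k < 2:
            raise InvalidParameterError(f"need at least 2 factor levels, got k={self.k}")
        if not (1.0 / self.k <= self.lam <= 1.0):
            raise InvalidParameterError(
                f"lambda must lie in [1/k, 1] = [{1.0 / self.k:.4g}, 1], got {self.lam}"
            )

    def weight(self, match: np.ndarray | bool) -> np.ndarray:
        """Kernel weight given a boolean match indicator (vectorized)."""
        mismatch_w = (1.0 - self.lam) / (self.k - 1)
        return np.where(match, self.lam, mismatch_w)


def kernel_weight(spec: KernelSpec, distance) -> np.ndarray | float:
    """Scaled kernel weight ``Kh(distance) = K(distance / h) / h``.

    ``spec`` must carry a scalar bandwidth. Symmetric in the sign of
    ``distance`` and nonnegative everywhere.
    """
    h = spec.h_vec
    if h.size != 1:
        raise InvalidParameterError("kernel_weight expects a scalar bandwidth")
    d = np.asarray(distance, dtype=float)
    out = KERNEL_FAMILIES[spec.family](d / h[0]) / h[0]
    return float(out) if np.isscalar(distance) else out


def categorical_weight(spec: CategoricalKernelSpec, level, target) -> float:
    """Aitchison-Aitken weight of ``level`` when estimating at ``target``."""
    return float(spec.weight(np.asarray(level == target)))


@dataclass
class GroupSample:
    """One group's responses and covariates.

    Parameters
    ----------
    X : (n, p) array
        Response matrix; the downstream comparison theory assumes each
        column has been standardized to zero mean and unit variance.
    Ucont : (n, q) array
        Continuous covariates (a 1-D array is treated as a single column).
    Ucat : (n, r) array, optional
        Categorical covariates as integer or string labels.
    levels : tuple of tuples, optional
        Declared alphabet per categorical column; inferred from the data
        when omitted.
    """

    X: np.ndarray
    Ucont: np.ndarray
    Ucat: np.ndarray | None = None
    levels: tuple = field(default=())

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        U = np.asarray(self.Ucont, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        if X.ndim != 2 or U.ndim != 2:
            raise InvalidParameterError("X and Ucont must be 2-D arrays")
        if X.shape[0] != U.shape[0]:
            raise InvalidParameterError(
                f"X has {X.shape[0]} rows but Ucont has {U.shape[0]}"
            )
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(U))):
            raise InvalidParameterError("X and Ucont must be complete (no NaN/inf)")
        self.X, self.Ucont = X, U
        if self.Ucat is not None:
            C = np.asarray(self.Ucat)
            if C.ndim == 1:
                C = C[:, None]
            if C.shape[0] != X.shape[0]:
                raise InvalidParameterError("Ucat row count mismatch")
            self.Ucat = C
            if not self.levels:
                self.levels = tuple(
                    tuple(sorted(set(C[:, j].tolist()))) for j in range(C.shape[1])
                )
            else:
                self.levels = tuple(tuple(lv) for lv in self.levels)
                for j, lv in enumerate(self.levels):
                    extra = set(C[:, j].tolist()) - set(lv)
                    if extra:
                        raise InvalidParameterError(
                            f"categorical column {j} contains undeclared levels {extra}"
                        )
        else:
            self.levels = ()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Ucont.shape[1]

    @property
    def r(self) -> int:
        return 0 if self.Ucat is None else self.Ucat.shape[1]


@dataclass(frozen=True)
class MeanEstimate:
    """Estimated conditional mean vector at a covariate point."""

    u: np.ndarray
    m: np.ndarray
    estimator: Literal["local_constant", "local_linear"]


# ---------------------------------------------------------------------------
# weight machinery
# ---------------------------------------------------------------------------


def continuous_weights(
    Ucont: np.ndarray, u: np.ndarray, spec: KernelSpec
) -> np.ndarray:
    """Product-kernel weights of each observation at point ``u``.

    Returns the length-n vector ``prod_j Khj(Uij - uj)``.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    h = spec.h_vec
    if h.size == 1 and Ucont.shape[1] > 1:
        h = np.repeat(h, Ucont.shape[1])
    if h.size != Ucont.shape[1]:
        raise InvalidParameterError(
            f"{h.size} bandwidth(s) for {Ucont.shape[1]} continuous covariate(s)"
        )
    if u.size != Ucont.shape[1]:
        raise InvalidParameterError(
            f"point has {u.size} coordinate(s), expected {Ucont.shape[1]}"
        )
    kern = KERNEL_FAMILIES[spec.family]
    scaled = (Ucont - u[None, :]) / h[None, :]
    return np.prod(kern(scaled) / h[None, :], axis=1)


def categorical_weights(
    Ucat: np.ndarray | None,
    target_levels,
    levels: tuple,
    lam: float,
) -> np.ndarray | float:
    """Aitchison-Aitken weights for all categorical columns (product over r)."""
    if Ucat is None or Ucat.shape[1] == 0:
        return 1.0
    targets = np.atleast_1d(np.asarray(target_levels, dtype=object))
    if targets.size != Ucat.shape[1]:
        raise InvalidParameterError(
            f"{targets.size} target level(s) for {Ucat.shape[1]} categorical covariate(s)"
        )
    w = np.ones(Ucat.shape[0])
    for j in range(Ucat.shape[1]):
        spec = CategoricalKernelSpec(lam=lam, k=len(levels[j]))
        if targets[j] not in levels[j]:
            raise InvalidParameterError(
                f"target level {targets[j]!r} not in alphabet {levels[j]}"
            )
        w = w * spec.weight(Ucat[:, j] == targets[j])
    return w


def _check_total_weight(w: np.ndarray, n: int, u) -> None:
    if w.sum() < n * DEGENERACY_RTOL:
        raise ExtrapolationError(
            f"total kernel weight at u={u} is negligible; the point is outside "
            "the estimable range of the data"
        )


# ---------------------------------------------------------------------------
# mean estimators
# ---------------------------------------------------------------------------


def local_constant_mean(
    sample: GroupSample,
    u,
    spec: KernelSpec,
    lam: float = 1.0,
    target_levels=None,
) -> MeanEstimate:
    """Nadaraya-Watson (local constant) conditional mean at ``u``.

    The estimate is the kernel-weighted average of the response rows. As
    ``h`` grows it converges to the unweighted column means.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    w = continuous_weights(sample.Ucont, u, spec)
    if sample.Ucat is not None:
        if target_levels is None:
            raise InvalidParameterError("sample has categorical covariates; pass target_levels")
        w = w * categorical_weights(sample.Ucat, target_levels, sample.levels, lam)
    _check_total_weight(w, sample.n, u)
    m = w @ sample.X / w.sum()
    return MeanEstimate(u=u, m=m, estimator="local_constant")


def _ll_solve(Ucont: np.ndarray, X: np.ndarray, u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least squares fit of a local degree-1 polynomial; returns m(u)."""
    n, q = Ucont.shape
    Z = np.empty((n, q + 1))
    Z[:, 0] = 1.0
    Z[:, 1:] = Ucont - u[None, :]
    Zw = Z * w[:, None]
    G = Z.T @ Zw
    # scale-invariant rank check on the local Gram matrix
    diag = np.sqrt(np.clip(np.diag(G), 0.0, None))
    if np.any(diag <= 0):
        raise DegenerateNeighborhoodError(
            f"local design at u={u} is rank deficient (no covariate spread)"
        )
    Dn = np.diag(1.0 / diag)
    Gn = Dn @ G @ Dn
    if np.linalg.cond(Gn) > 1e12:
        raise DegenerateNeighborhoodError(
            f"local design at u={u} is numerically rank deficient"
        )
    beta = np.linalg.solve(G, Zw.T @ X)
    return beta[0]


def local_linear_mean(
    sample: GroupSample,
    u,
    spec: KernelSpec,
    lam: float = 1.0,
    target_levels=None,
) -> MeanEstimate:
    """Local linear conditional mean at ``u``.

    Fits a weighted degree-1 polynomial around ``u``; exactly reproduces
    affine functions of the covariates for any bandwidth and is less biased
    than the local constant fit near the boundary of the covariate range.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    w = continuous_weights(sample.Ucont, u, spec)
    if sample.Ucat is not None:
        if target_levels is None:
            raise InvalidParameterError("sample has categorical covariates; pass target_levels")
        w = w * categorical_weights(sample.Ucat, target_levels, sample.levels, lam)
    _check_total_weight(w, sample.n, u)
    m = _ll_solve(sample.Ucont, sample.X, u, w)
    return MeanEstimate(u=u, m=m, estimator="local_linear")


def fit_means(
    sample: GroupSample,
    spec: KernelSpec,
    estimator: Literal["local_constant", "local_linear"] = "local_linear",
    lam: float = 1.0,
    leave_one_out: bool = False,
) -> np.ndarray:
    """Fitted conditional means at every sample's own covariate point.

    Returns an (n, p) matrix with row i equal to the mean estimate at
    ``(Ucont[i], Ucat[i])``; with categorical covariates each row's own
    factor levels are the target. ``leave_one_out=True`` drops observation
    i from its own fit (used by bandwidth cross-validation).
    """
    n = sample.n
    W = _pairwise_weights(sample, spec, lam)
    if leave_one_out:
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    if estimator == "local_constant":
        tot = W.sum(axis=1)
        if np.any(tot < n * DEGENERACY_RTOL):
            raise ExtrapolationError("degenerate leave-one-out neighborhood in mean fit")
        return (W @ sample.X) / tot[:, None]
    if estimator != "local_linear":
        raise InvalidParameterError(f"unknown mean estimator {estimator!r}")
    if sample.q == 1:
        return _ll_fit_all_1d(sample.Ucont[:, 0], sample.X, W)
    out = np.empty((n, sample.p))
    for i in range(n):
        w = W[i]
        _check_total_weight(w, n, sample.Ucont[i])
        out[i] = _ll_solve(sample.Ucont, sample.X, sample.Ucont[i], w)
    return out


def _pairwise_weights(sample: GroupSample, spec: KernelSpec, lam: float) -> np.ndarray:
    """(n, n) matrix with W[i, j] = weight of observation j at point i."""
    h = spec.h_vec
    q = sample.q
    if h.size == 1 and q > 1:
        h = np.repeat(h, q)
    kern = KERNEL_FAMILIES[spec.family]
    W = np.ones((sample.n, sample.n))
    for j in range(q):
        D = (sample.Ucont[:, j][:, None] - sample.Ucont[:, j][None, :]) / h[j]
        W *= kern(D) / h[j]
    if sample.Ucat is not None:
        for c in range(sample.r):
            cs = CategoricalKernelSpec(lam=lam, k=len(sample.levels[c]))
            match = sample.Ucat[:, c][:, None] == sample.Ucat[:, c][None, :]
            W *= cs.weight(match)
    return W


def _ll_fit_all_1d(U: np.ndarray, X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Vectorized 1-D local linear fit at each row's own point given weights."""
    n = U.shape[0]
    D = U[None, :] - U[:, None]  # D[i, j] = Uj - Ui
    s0 = W.sum(axis=1)
    s1 = (W * D).sum(axis=1)
    s2 = (W * D * D).sum(axis=1)
    denom = s2 * s0 - s1 * s1
    scale = np.maximum(s0, 1e-300) * np.maximum(s2, 1e-300)
    bad = (s0 < n * DEGENERACY_RTOL) | (denom <= 1e-12 * scale)
    if np.any(bad):
        raise DegenerateNeighborhoodError(
            "local linear fit degenerate at one or more sample points"
        )
    Wll = (s2[:, None] - s1[:, None] * D) * W  # unnormalized local-linear weights
    return (Wll @ X) / denom[:, None]


def select_mean_bandwidth(
    sample: GroupSample,
    grid: Sequence[float] | None = None,
    estimator: Literal["local_constant", "local_linear"] = "local_linear",
    family: Literal["gaussian", "epanechnikov"] = "gaussian",
    lam: float = 1.0,
) -> float:
    """Leave-one-out squared-error bandwidth for the mean estimator.

    Scores every bandwidth in ``grid`` by the leave-one-out mean squared
    prediction error summed over the p responses and returns the smallest
    bandwidth attaining the minimum. The default grid is 25 log-spaced
    points between 0.05 and 2 times the (average, for q > 1) covariate
    standard deviation; for multivariate covariates the same scalar
    multiplies each dimension's standard deviation.
    """
    if sample.n < 3:
        raise InvalidParameterError("need n >= 3 for bandwidth selection")
    sds = sample.Ucont.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise InvalidParameterError("a continuous covariate is constant")
    if grid is None:
        candidates = [tuple(g * sds) for g in np.geomspace(0.05, 2.0, 25)]
    else:
        if len(grid) == 0:
            raise InvalidParameterError("empty bandwidth grid")
        candidates = []
        for g in grid:
            g = np.atleast_1d(np.asarray(g, dtype=float))
            if g.size == 1:
                g = np.repeat(g, sample.q)
            elif g.size != sample.q:
                raise InvalidParameterError(
                    f"bandwidth entry has {g.size} value(s) for q={sample.q}"
                )
            candidates.append(tuple(g))
    scores = []
    for cand in candidates:
        spec = KernelSpec(family=family, h=cand)
        try:
            pred = fit_means(sample, spec, estimator=estimator, lam=lam, leave_one_out=True)
            scores.append(float(np.mean((sample.X - pred) ** 2)))
        except (ExtrapolationError, DegenerateNeighborhoodError):
            scores.append(np.inf)
    scores = np.asarray(scores)
    if not np.any(np.isfinite(scores)):
        raise NoValidBandwidthError("every candidate mean bandwidth was degenerate")
    order = np.lexsort((np.asarray([c[0] for c in candidates]), scores))
    best = candidates[order[0]]
    return best[0] if sample.q == 1 else np.asarray(best)


def rule_of_thumb_bandwidth(Ucont: np.ndarray) -> np.ndarray:
    """Silverman-type reference bandwidth, 1.06 * sd * n^(-1/5) per dimension."""
    U = np.asarray(Ucont, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    n = U.shape[0]
    return 1.06 * U.std(axis=0, ddof=1) * n ** (-0.2)
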