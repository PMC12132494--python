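"""Nadaraya-Watson conditional covariance estimation.

The conditional covariance of a response vector x given covariates u,
Cov(x | u) = Sigma(u), is estimated by a kernel-weighted average of
residual outer products:

    Sigma_hat(u) = sum_i w_i(u) (x_i - m_hat(U_i)) (x_i - m_hat(U_i))'
                   / sum_i w_i(u)

where w_i(u) is a product of one scaled kernel per continuous covariate
and, for categorical covariates, an Aitchison-Aitken weight per factor.
Being a nonnegatively weighted sum of outer products, the estimate is
symmetric positive semi-definite by construction.

The covariance bandwidth is selected by minimizing the Gaussian
leave-one-out log-likelihood criterion

    CV(h) = (1/n) sum_i [ r_i' Sigma_hat_{(-i)}(U_i)^{-1} r_i
                          + log det Sigma_hat_{(-i)}(U_i) ]

with r_i = x_i - m_hat(U_i) and Sigma_hat_{(-i)} the estimate omitting
observation i. The residuals are computed once from a mean fit whose own
bandwidth is chosen beforehand (the criterion varies only the covariance
bandwidth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import smoothers
from .exceptions import (
    EmptyCellError,
    ExtrapolationError,
    InvalidParameterError,
    NoValidBandwidthError,
)
from .smoothers import (
    DEGENERACY_RTOL,
    GroupSample,
    KernelSpec,
    categorical_weights,
    continuous_weights,
)

#: condition-number cutoff above which a leave-one-out covariance is
#: treated as non-invertible inside the CV criterion
CV_COND_MAX = 1e12


@dataclass(frozen=True)
class BandwidthSpec:
    """Smoothing bandwidths for one group.

    Parameters
    ----------
    h : float or sequence of float
        Covariance bandwidth(s), one per continuous covariate.
    lam : float, optional
        Aitchison-Aitken weight for categorical covariates (default 1:
        stratified estimation, the setting used in practice).
    mean_h : float or sequence of float, optional
        Bandwidth(s) of the inner mean estimator; a Silverman-type rule of
        thumb is used when omitted.
    family : str
        Kernel family shared by mean and covariance smoothers.
    mean_estimator : {"local_linear", "local_constant"}
        Inner mean fit; local linear is preferred for its boundary behavior.
    """

    h: float | Sequence[float]
    lam: float = 1.0
    mean_h: float | Sequence[float] | None = None
    family: Literal["gaussian", "epanechnikov"] = "gaussian"
    mean_estimator: Literal["local_linear", "local_constant"] = "local_linear"

    def __post_init__(self):
        KernelSpec(family=self.family, h=self.h)  # validates
        if self.mean_h is not None:
            KernelSpec(family=self.family, h=self.mean_h)
        if not 0.0 < self.lam <= 1.0:
            raise InvalidParameterError(f"lambda must be in (0, 1], got {self.lam}")

    @property
    def h_vec(self) -> np.ndarray:
        return KernelSpec(family=self.family, h=self.h).h_vec

    def cov_kernel(self) -> KernelSpec:
        return KernelSpec(family=self.family, h=self.h)

    def mean_kernel(self, sample: GroupSample) -> KernelSpec:
        if self.mean_h is not None:
            return KernelSpec(family=self.family, h=self.mean_h)
        return KernelSpec(
            family=self.family, h=smoothers.rule_of_thumb_bandwidth(sample.Ucont)
        )


@dataclass
class CondCov:
    """An estimated conditional covariance matrix at one covariate point.

    ``total_weight`` is the sum of kernel weights that entered the estimate
    and ``ess = (sum w)^2 / sum w^2`` the effective number of observations;
    both are diagnostics of how local (and hence how noisy) the estimate
    is. ``flag`` is None for a successful estimate, otherwise a short
    reason (e.g. "extrapolation") and ``sigma`` is NaN.
    """

    u: np.ndarray
    sigma: np.ndarray | None
    total_weight: float = 0.0
    ess: float = 0.0
    target_levels: tuple | None = None
    flag: str | None = field(default=None)

    @property
    def ok(self) -> bool:
        return self.flag is None


def compute_means(sample: GroupSample, bw: BandwidthSpec) -> np.ndarray:
    """Mean fit at each observation's own covariates (used for residuals)."""
    return smoothers.fit_means(
        sample, bw.mean_kernel(sample), estimator=bw.mean_estimator, lam=bw.lam
    )


def _point_weights(
    sample: GroupSample, u, bw: BandwidthSpec, target_levels
) -> np.ndarray:
    w = continuous_weights(sample.Ucont, np.atleast_1d(np.asarray(u, dtype=float)),
                           bw.cov_kernel())
    if sample.Ucat is not None:
        if target_levels is None:
            raise InvalidParameterError(
                "sample has categorical covariates; pass target_levels"
            )
        wc = categorical_weights(sample.Ucat, target_levels, sample.levels, bw.lam)
        if bw.lam == 1.0 and np.sum(wc > 0) == 0:
            raise EmptyCellError(
                f"no observations with factor level(s) {target_levels!r}"
            )
        w = w * wc
    return w


def nw_cond_cov(
    sample: GroupSample,
    u,
    bw: BandwidthSpec,
    means: np.ndarray | None = None,
    target_levels=None,
) -> CondCov:
    """Nadaraya-Watson conditional covariance estimate at ``u``.

    Parameters
    ----------
    means : (n, p) array, optional
        Precomputed mean estimates at each observation's own covariate
        value. Computed with ``bw``'s inner mean estimator when omitted.
        Pass zeros when the rows of ``sample.X`` are already residuals.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if means is None:
        means = compute_means(sample, bw)
    w = _point_weights(sample, u, bw, target_levels)
    total = float(w.sum())
    if total < sample.n * DEGENERACY_RTOL:
        raise ExtrapolationError(
            f"total kernel weight at u={u} is negligible; refusing to extrapolate"
        )
    R = sample.X - means
    sigma = np.einsum("i,ij,ik->jk", w, R, R) / total
    sigma = 0.5 * (sigma + sigma.T)
    ess = total**2 / float((w * w).sum())
    return CondCov(
        u=u,
        sigma=sigma,
        total_weight=total,
        ess=ess,
        target_levels=None if target_levels is None else tuple(np.atleast_1d(target_levels)),
    )


def _loo_weight_matrix(sample: GroupSample, bw: BandwidthSpec) -> np.ndarray:
    """(n, n) leave-one-out weights: row i holds weights at U_i, diag zeroed."""
    W = smoothers._pairwise_weights(sample, bw.cov_kernel(), bw.lam)
    np.fill_diagonal(W, 0.0)
    return W


def cv_criterion(
    sample: GroupSample,
    bw: BandwidthSpec,
    means: np.ndarray,
    jitter: float = 0.0,
    subsample: int = 1,
) -> float:
    """Leave-one-out Gaussian log-likelihood CV score for one bandwidth.

    Returns +inf when any leave-one-out covariance is non-invertible
    (condition number above ``CV_COND_MAX``), has a nonpositive
    determinant, or a leave-one-out neighborhood is empty.
    ``subsample`` > 1 evaluates the criterion only at every k-th
    observation (a cheaper approximation for large n, off by default).
    """
    n, p = sample.n, sample.p
    R = sample.X - means
    W = _loo_weight_matrix(sample, bw)
    idx = np.arange(0, n, subsample)
    W = W[idx]
    denom = W.sum(axis=1)
    if np.any(denom < n * DEGENERACY_RTOL):
        return np.inf
    S = np.einsum("ij,jk,jl->ikl", W, R, R) / denom[:, None, None]
    S = 0.5 * (S + np.transpose(S, (0, 2, 1)))
    if jitter:
        S = S + jitter * np.eye(p)[None, :, :]
    eig = np.linalg.eigvalsh(S)
    if np.any(eig[:, 0] <= 0) or np.any(eig[:, -1] / eig[:, 0] > CV_COND_MAX):
        return np.inf
    sign, logdet = np.linalg.slogdet(S)
    if np.any(sign <= 0):
        return np.inf
    Ri = R[idx]
    quad = np.einsum("ij,ij->i", Ri, np.linalg.solve(S, Ri[:, :, None])[:, :, 0])
    return float(np.mean(quad + logdet))


def cv_cov_bandwidth(
    sample: GroupSample,
    grid: Sequence[BandwidthSpec] | Sequence[float],
    means: np.ndarray | None = None,
    jitter: float = 0.0,
    subsample: int = 1,
) -> BandwidthSpec:
    """Covariance bandwidth minimizing the leave-one-out likelihood criterion.

    ``grid`` may contain :class:`BandwidthSpec` objects or plain positive
    numbers (wrapped with default settings). The mean fit is computed once
    and its residuals are held fixed across candidates. Ties are broken
    toward the candidate with the smallest (first) bandwidth.
    """
    if len(grid) == 0:
        raise InvalidParameterError("empty bandwidth grid")
    if sample.n < sample.p + 2:
        raise InvalidParameterError("need n >= p + 2 for covariance CV")
    specs = [
        g if isinstance(g, BandwidthSpec) else BandwidthSpec(h=g) for g in grid
    ]
    if means is None:
        means = compute_means(sample, specs[0])
    scores = np.array(
        [cv_criterion(sample, s, means, jitter=jitter, subsample=subsample) for s in specs]
    )
    if not np.any(np.isfinite(scores)):
        raise NoValidBandwidthError(
            "every candidate covariance bandwidth was non-invertible somewhere"
        )
    first_h = np.array([s.h_vec[0] for s in specs])
    order = np.lexsort((first_h, scores))
    return specs[order[0]]


def cond_cov_curve(
    sample: GroupSample,
    grid_u: Sequence,
    bw: BandwidthSpec,
    means: np.ndarray | None = None,
    target_levels=None,
) -> list[CondCov]:
    """Conditional covariance estimates along a grid of covariate points.

    Points outside the observed covariate range (or with negligible total
    weight) produce flagged entries rather than raising, so one bad grid
    point does not abort a whole trace.
    """
    grid_u = list(grid_u)
    if len(grid_u) == 0:
        raise InvalidParameterError("empty evaluation grid")
    if means is None:
        means = compute_means(sample, bw)
    lo = sample.Ucont.min(axis=0)
    hi = sample.Ucont.max(axis=0)
    out: list[CondCov] = []
    for u in grid_u:
        ua = np.atleast_1d(np.asarray(u, dtype=float))
        if np.any(ua < lo) or np.any(ua > hi):
            out.append(CondCov(u=ua, sigma=None, flag="extrapolation",
                               target_levels=target_levels))
            continue
        try:
            out.append(nw_cond_cov(sample, ua, bw, means=means,
                                   target_levels=target_levels))
        except (ExtrapolationError, EmptyCellError) as exc:
            out.append(CondCov(u=ua, sigma=None, flag=type(exc).__name__,
                               target_levels=target_levels))
    return out
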