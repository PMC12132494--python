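"""Two-group conditional covariance comparison tests.

For a covariate point u with group covariance estimates S0(u), S1(u) and
group sizes n0, n1, all tests are built on the combined matrix

    Z(u) = (n0 S0(u) + n1 S1(u))^{-1} n1 S1(u)

whose eigenvalues lie in [0, 1] and measure the relative size of group 1's
covariance. Under H0: Sigma0(u) = Sigma1(u) with equal group sizes every
eigenvalue is 1/2. Three p-value routes are provided:

* ``tracy_widom_test`` - parametric: the logit of the leading eigenvalue,
  centered and scaled, is referred to the Tracy-Widom law of order 1
  (via a gamma approximation of its CDF).
* ``forkman_test`` - semi-parametric bootstrap: the observed top-eigenvalue
  share lambda1 / sum(lambda) is compared with the same statistic computed
  from standard-Gaussian reference samples of the same shapes.
* ``permutation_test`` - nonparametric: group labels of the mean-adjusted
  residuals are shuffled and the conditional covariances re-estimated with
  the original bandwidths.

All p-values are one-sided upper tail. The resampling tests use strict
``>`` in the numerator and divisor B, so their p-values live on the 1/B
lattice; an optional add-one correction is available to avoid exact zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _tw, condcov
from .condcov import BandwidthSpec, nw_cond_cov
from .exceptions import (
    DegenerateNeighborhoodError,
    EmptyCellError,
    ExtrapolationError,
    InvalidParameterError,
    LogitDomainError,
    SingularMatrixError,
)
from .smoothers import DEGENERACY_RTOL, GroupSample

Method = Literal["tracy_widom", "forkman", "permutation"]
METHODS: tuple[Method, ...] = ("tracy_widom", "forkman", "permutation")


@dataclass
class CombinedEigen:
    """The combined matrix Z and its eigenvalue spectrum (descending)."""

    Z: np.ndarray
    eigenvalues: np.ndarray
    n0: int
    n1: int

    @property
    def lambda1(self) -> float:
        return float(self.eigenvalues[0])


@dataclass(frozen=True)
class TWParams:
    """Centering/scaling of the logit largest-root statistic.

    gamma and phi are the angles defined by
    sin^2(gamma/2) = (min(p, n1) - 1/2) / (n0 + n1 - 1) and
    sin^2(phi/2)   = (max(p, n1) - 1/2) / (n0 + n1 - 1); then
    mu = 2 log tan((gamma + phi)/2) and
    sigma^3 = 16 / [(n0 + n1 - 1)^2 sin^2(gamma + phi) sin(gamma) sin(phi)].
    """

    gamma: float
    phi: float
    mu: float
    sigma: float


@dataclass
class EigenTestResult:
    """Outcome of one covariance-equality test at one covariate point."""

    method: Method
    u: np.ndarray | None
    statistic: float
    p_value: float
    B: int = 0
    seed: int | None = None
    lambda1: float | None = None
    flag: str | None = None
    boot: np.ndarray | None = None  # resampled statistics, when requested


def _as_psd(S: np.ndarray, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidParameterError(f"{name} must be a square matrix")
    if not np.allclose(S, S.T, atol=1e-10):
        raise InvalidParameterError(f"{name} must be symmetric")
    return 0.5 * (S + S.T)


def combined_matrix(S0, S1, n0: int, n1: int) -> CombinedEigen:
    """Combined matrix Z = (n0 S0 + n1 S1)^{-1} n1 S1 and its eigenvalues.

    The eigenvalues are computed from the symmetric generalized eigenproblem
    n1 S1 v = lambda (n0 S0 + n1 S1) v via Cholesky whitening of the
    combined denominator, which guarantees a real spectrum in [0, 1]; the
    explicit inverse is never formed for the spectrum.
    """
    if n0 < 1 or n1 < 1:
        raise InvalidParameterError("group sizes must be >= 1")
    S0 = _as_psd(S0, "S0")
    S1 = _as_psd(S1, "S1")
    A = n0 * S0 + n1 * S1
    B = n1 * S1
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "n0*S0 + n1*S1 is not positive definite"
        ) from exc
    M = np.linalg.solve(L, np.linalg.solve(L, B).T)
    eig = np.linalg.eigvalsh(0.5 * (M + M.T))[::-1]
    if eig[0] > 1 + 1e-8 or eig[-1] < -1e-8:
        raise SingularMatrixError("combined-matrix eigenvalues left [0, 1]")
    eig = np.clip(eig, 0.0, 1.0)
    Z = np.linalg.solve(A, B)
    return CombinedEigen(Z=Z, eigenvalues=eig, n0=int(n0), n1=int(n1))


def tw_centering_scaling(p: int, n0: int, n1: int) -> TWParams:
    """Tracy-Widom centering mu and scaling sigma for the logit statistic."""
    N = n0 + n1 - 1
    if n0 + n1 <= p + 1:
        raise InvalidParameterError("need n0 + n1 > p + 1")
    a = (min(p, n1) - 0.5) / N
    b = (max(p, n1) - 0.5) / N
    if not (0.0 < a < 1.0 and 0.0 < b < 1.0):
        raise InvalidParameterError(
            f"arcsin arguments out of (0,1): {a:.4g}, {b:.4g}"
        )
    gamma = 2.0 * math.asin(math.sqrt(a))
    phi = 2.0 * math.asin(math.sqrt(b))
    mu = 2.0 * math.log(math.tan((gamma + phi) / 2.0))
    sigma3 = 16.0 / (
        N**2 * math.sin(gamma + phi) ** 2 * math.sin(gamma) * math.sin(phi)
    )
    return TWParams(gamma=gamma, phi=phi, mu=mu, sigma=sigma3 ** (1.0 / 3.0))


def tw_statistic(lambda1: float, p: int, n0: int, n1: int) -> float:
    """Centered/scaled logit of the leading combined-matrix eigenvalue."""
    if not 0.0 < lambda1 < 1.0:
        raise LogitDomainError(
            f"leading eigenvalue {lambda1} is on the boundary; logit undefined"
        )
    params = tw_centering_scaling(p, n0, n1)
    return (math.log(lambda1 / (1.0 - lambda1)) - params.mu) / params.sigma


def tracy_widom_test(S0, S1, n0: int, n1: int, u=None) -> EigenTestResult:
    """Parametric covariance-equality test via the Tracy-Widom law."""
    ce = combined_matrix(S0, S1, n0, n1)
    p = ce.Z.shape[0]
    t = tw_statistic(ce.lambda1, p, n0, n1)
    pval = float(_tw.tw1_sf(t))
    return EigenTestResult(
        method="tracy_widom", u=u, statistic=t, p_value=pval, B=0,
        lambda1=ce.lambda1,
    )


def _centered_cov(X: np.ndarray) -> np.ndarray:
    """Sample covariance with divisor n (columns centered at their means)."""
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc / X.shape[0]


def _eigen_share(S0: np.ndarray, S1: np.ndarray, n0: int, n1: int) -> float:
    """Top-eigenvalue share lambda1 / sum(lambda) of the combined matrix."""
    A = n0 * S0 + n1 * S1
    B = n1 * S1
    L = np.linalg.cholesky(A)
    M = np.linalg.solve(L, np.linalg.solve(L, B).T)
    eig = np.linalg.eigvalsh(0.5 * (M + M.T))
    return float(eig[-1] / eig.sum())


def forkman_test(
    S0,
    S1,
    n0: int,
    n1: int,
    B: int = 1000,
    seed: int | None = None,
    u=None,
    add_one: bool = False,
) -> EigenTestResult:
    """Gaussian-reference bootstrap test of covariance equality.

    The observed statistic is the top-eigenvalue share of the combined
    matrix. Each bootstrap iteration draws fresh standard-Gaussian samples
    of shapes (n0, p) and (n1, p), forms their plain (divisor-n) sample
    covariances and the same statistic; the p-value is the fraction of
    bootstrap statistics strictly exceeding the observed one.
    """
    if B < 1:
        raise InvalidParameterError(f"B must be >= 1, got {B}")
    ce = combined_matrix(S0, S1, n0, n1)
    p = ce.Z.shape[0]
    if p < 2:
        raise InvalidParameterError("need p >= 2 responses")
    stat = float(ce.eigenvalues[0] / ce.eigenvalues.sum())
    children = np.random.SeedSequence(seed).spawn(B)
    exceed = 0
    for child in children:
        rng = np.random.default_rng(child)
        X0 = rng.standard_normal((n0, p))
        X1 = rng.standard_normal((n1, p))
        tb = _eigen_share(_centered_cov(X0), _centered_cov(X1), n0, n1)
        if tb > stat:
            exceed += 1
    pval = (exceed + 1) / (B + 1) if add_one else exceed / B
    return EigenTestResult(
        method="forkman", u=u, statistic=stat, p_value=float(pval), B=B,
        seed=seed, lambda1=ce.lambda1,
    )


def _residuals(sample: GroupSample, bw: BandwidthSpec) -> np.ndarray:
    return sample.X - condcov.compute_means(sample, bw)


def _weighted_cov(w: np.ndarray, R: np.ndarray) -> np.ndarray:
    S = np.einsum("i,ij,ik->jk", w, R, R) / w.sum()
    return 0.5 * (S + S.T)


def permutation_test(
    group0: GroupSample,
    group1: GroupSample,
    u,
    bw0: BandwidthSpec,
    bw1: BandwidthSpec,
    B: int = 1000,
    seed: int | None = None,
    residuals: tuple[np.ndarray, np.ndarray] | None = None,
    target_levels=None,
    add_one: bool = False,
    return_boot: bool = False,
) -> EigenTestResult:
    """Permutation test of conditional covariance equality at ``u``.

    Mean functions are fitted once per group on the original data; their
    residuals (paired with the covariates) are then pooled and the group
    labels permuted. Each iteration re-estimates both conditional
    covariances at ``u`` with the original bandwidths and recomputes the
    top-eigenvalue share. A permutation that leaves one pseudo-group with
    negligible kernel weight at ``u`` is redrawn (at most ``10 * B``
    redraws in total).

    ``residuals`` may carry precomputed mean-adjusted responses for both
    groups to avoid refitting the means.
    """
    if B < 1:
        raise InvalidParameterError(f"B must be >= 1, got {B}")
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if residuals is None:
        R0 = _residuals(group0, bw0)
        R1 = _residuals(group1, bw1)
    else:
        R0, R1 = residuals
    n0, n1 = group0.n, group1.n
    N = n0 + n1

    w0_own = condcov._point_weights(group0, u, bw0, target_levels)
    w1_own = condcov._point_weights(group1, u, bw1, target_levels)
    thr0 = N * DEGENERACY_RTOL
    if w0_own.sum() < thr0 or w1_own.sum() < thr0:
        raise ExtrapolationError(f"a group has negligible weight at u={u}")
    S0 = _weighted_cov(w0_own, R0)
    S1 = _weighted_cov(w1_own, R1)
    t_obs = _eigen_share(S0, S1, n0, n1)
    lam1 = float(
        combined_matrix(S0, S1, n0, n1).eigenvalues[0]
    )

    # pooled residuals / covariates; weights at u under each group's bandwidth
    Rpool = np.vstack([R0, R1])
    pooled_cont = np.vstack([group0.Ucont, group1.Ucont])
    pooled_cat = (
        np.vstack([group0.Ucat, group1.Ucat]) if group0.Ucat is not None else None
    )
    pooled_levels = tuple(
        tuple(sorted(set(a) | set(b)))
        for a, b in zip(group0.levels, group1.levels)
    )
    pooled0 = GroupSample(Rpool, pooled_cont, pooled_cat, levels=pooled_levels)
    a = condcov._point_weights(pooled0, u, bw0, target_levels)
    b = condcov._point_weights(pooled0, u, bw1, target_levels)
    O = Rpool[:, :, None] * Rpool[:, None, :]  # (N, p, p) outer products
    aO = a[:, None, None] * O
    bO = b[:, None, None] * O

    children = np.random.SeedSequence(seed).spawn(B)
    t_boot = np.empty(B)
    retries = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        while True:
            perm = rng.permutation(N)
            i0, i1 = perm[:n0], perm[n0:]
            sa, sb = a[i0].sum(), b[i1].sum()
            if sa >= thr0 and sb >= thr0:
                break
            retries += 1
            if retries > 10 * B:
                raise DegenerateNeighborhoodError(
                    "too many degenerate permutations at this point"
                )
        S0b = aO[i0].sum(axis=0) / sa
        S1b = bO[i1].sum(axis=0) / sb
        t_boot[i] = _eigen_share(S0b, S1b, n0, n1)
    exceed = int((t_boot > t_obs).sum())
    pval = (exceed + 1) / (B + 1) if add_one else exceed / B
    return EigenTestResult(
        method="permutation", u=u, statistic=t_obs, p_value=float(pval), B=B,
        seed=seed, lambda1=lam1, boot=t_boot if return_boot else None,
    )


def significance_trace(
    group0: GroupSample,
    group1: GroupSample,
    grid_u: Sequence,
    bw0: BandwidthSpec,
    bw1: BandwidthSpec,
    methods: Sequence[Method] = METHODS,
    B: int = 1000,
    seed: int | None = None,
    target_levels=None,
    add_one: bool = False,
) -> pd.DataFrame:
    """p-values of the requested tests along a grid of covariate points.

    Returns a tidy table with one row per (grid point, method). Grid points
    where either group's estimate is degenerate produce flagged rows with
    NaN statistics rather than aborting the trace. No multiplicity
    adjustment is applied across the grid.
    """
    grid_u = [np.atleast_1d(np.asarray(u, dtype=float)) for u in grid_u]
    if not grid_u:
        raise InvalidParameterError("empty evaluation grid")
    for m in methods:
        if m not in METHODS:
            raise InvalidParameterError(f"unknown method {m!r}")
    R0 = _residuals(group0, bw0)
    R1 = _residuals(group1, bw1)
    n0, n1 = group0.n, group1.n
    q = group0.q
    ucols = ["u"] if q == 1 else [f"u{j+1}" for j in range(q)]
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(len(grid_u) * len(methods)))
    rows = []
    for u in grid_u:
        try:
            w0 = condcov._point_weights(group0, u, bw0, target_levels)
            w1 = condcov._point_weights(group1, u, bw1, target_levels)
            thr = (n0 + n1) * DEGENERACY_RTOL
            if w0.sum() < thr or w1.sum() < thr:
                raise ExtrapolationError(f"negligible weight at u={u}")
            S0 = _weighted_cov(w0, R0)
            S1 = _weighted_cov(w1, R1)
        except (ExtrapolationError, EmptyCellError) as exc:
            reason = ("extrapolation" if isinstance(exc, ExtrapolationError)
                      else "empty_cell")
            for m in methods:
                next(children, None)
                rows.append(_trace_row(ucols, u, target_levels, m, np.nan, np.nan,
                                       0, reason))
            continue
        for m in methods:
            child = next(children)
            child_seed = int(child.generate_state(1)[0] % (2**31))
            try:
                if m == "tracy_widom":
                    res = tracy_widom_test(S0, S1, n0, n1, u=u)
                elif m == "forkman":
                    res = forkman_test(S0, S1, n0, n1, B=B, seed=child_seed,
                                       u=u, add_one=add_one)
                else:
                    res = permutation_test(
                        group0, group1, u, bw0, bw1, B=B, seed=child_seed,
                        residuals=(R0, R1), target_levels=target_levels,
                        add_one=add_one,
                    )
                rows.append(_trace_row(ucols, u, target_levels, m,
                                       res.statistic, res.p_value, res.B, None))
            except (LogitDomainError, SingularMatrixError,
                    DegenerateNeighborhoodError) as exc:
                rows.append(_trace_row(ucols, u, target_levels, m,
                                       np.nan, np.nan, 0, type(exc).__name__))
    return pd.DataFrame(rows)


def _trace_row(ucols, u, target_levels, method, statistic, p_value, B, flag):
    row = {c: float(v) for c, v in zip(ucols, u)}
    if target_levels is not None:
        for j, lv in enumerate(np.atleast_1d(np.asarray(target_levels, dtype=object))):
            row[f"level{j+1}"] = lv
    row.update(
        method=method, statistic=statistic, p_value=p_value, B=int(B), flag=flag
    )
    return row
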