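"""Synthetic-data lab: simulation designs and Monte-Carlo study harnesses.

Two bivariate-Gaussian designs are provided whose correlation is a known
function of uniform covariates:

* one continuous covariate: U ~ Uniform(-1, 1) and
  corr(x1, x2 | U) = theta * U for a group parameter theta in [0, 1];
* two continuous covariates: U1, U2 ~ Uniform(0, 1) independent and
  corr(x1, x2 | U1, U2) = theta * (U1 - U2).

Both groups share theta1 = 0.5 by convention; the second group's theta2
sweeps [0, 1]. The groups have identical conditional covariance exactly
when theta1 = theta2, or at u = 0 (resp. U1 = U2) for any thetas, so the
same designs yield both type-I-error and power experiments. Because the
true 2x2 conditional correlation matrices are known, the leading
eigenvalue of the true combined matrix is available in closed form and
serves as the accuracy benchmark for the estimated eigenvalue curve.

Default study sizes mirror the published experiments (n = 1000 per group
with 100 repetitions for type-I error and power; n = 5000 with 50
repetitions for eigenvalue accuracy); scaled-down presets (labeled "ci")
are provided for quick runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import cmptest, condcov
from .condcov import BandwidthSpec
from .exceptions import CovFunError, InvalidParameterError
from .smoothers import GroupSample, rule_of_thumb_bandwidth

logger = logging.getLogger(__name__)


def _rep_seed_sequence(seed: int | None, rep: int) -> np.random.SeedSequence:
    """Counter-based per-repetition stream: rep k is reproducible alone."""
    return np.random.SeedSequence(entropy=0 if seed is None else seed,
                                  spawn_key=(rep,))


def simulate_group_1d(n: int, theta: float, seed) -> GroupSample:
    """One group of the single-covariate design.

    U_i ~ Uniform(-1, 1); (x_i1, x_i2) bivariate normal with zero means,
    unit variances and correlation theta * U_i (drawn via the closed-form
    2x2 Cholesky factor).
    """
    if not 0.0 <= theta <= 1.0:
        raise InvalidParameterError(f"theta must be in [0, 1], got {theta}")
    rng = np.random.default_rng(seed)
    U = rng.uniform(-1.0, 1.0, size=n)
    rho = theta * U
    Z = rng.standard_normal((n, 2))
    X = np.column_stack([Z[:, 0], rho * Z[:, 0] + np.sqrt(1.0 - rho**2) * Z[:, 1]])
    return GroupSample(X=X, Ucont=U)


def simulate_group_2d(n: int, theta: float, seed) -> GroupSample:
    """One group of the two-covariate design.

    U_i1, U_i2 ~ Uniform(0, 1) independently; correlation
    theta * (U_i1 - U_i2), which vanishes on the diagonal U1 = U2.
    """
    if not 0.0 <= theta <= 1.0:
        raise InvalidParameterError(f"theta must be in [0, 1], got {theta}")
    rng = np.random.default_rng(seed)
    U = rng.uniform(0.0, 1.0, size=(n, 2))
    rho = theta * (U[:, 0] - U[:, 1])
    Z = rng.standard_normal((n, 2))
    X = np.column_stack([Z[:, 0], rho * Z[:, 0] + np.sqrt(1.0 - rho**2) * Z[:, 1]])
    return GroupSample(X=X, Ucont=U)


def true_combined_eigen_1d(
    theta1: float, theta2: float, u: float, n_ratio: float = 1.0
) -> float:
    """Largest eigenvalue of the true combined matrix in the 1-D design.

    With Sigma_j(u) = [[1, theta_j u], [theta_j u, 1]] and group-size ratio
    r = n2/n1, the eigenvalue of (Sigma_1 + r Sigma_2)^{-1} r Sigma_2 along
    the eigenvector (1, 1) is r(1 + b) / (1 + a + r(1 + b)) and along
    (1, -1) is r(1 - b) / (1 - a + r(1 - b)), with a = theta1 u,
    b = theta2 u (the two correlation matrices commute). Returns the larger
    of the two; equals 1/2 identically in u when theta1 = theta2 and r = 1.
    """
    a = theta1 * u
    b = theta2 * u
    if not (abs(a) < 1.0 and abs(b) < 1.0):
        raise InvalidParameterError("|theta * u| must be < 1")
    r = float(n_ratio)
    lam_plus = r * (1.0 + b) / (1.0 + a + r * (1.0 + b))
    lam_minus = r * (1.0 - b) / (1.0 - a + r * (1.0 - b))
    return max(lam_plus, lam_minus)


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one Monte-Carlo experiment.

    ``h_grid`` holds the covariance bandwidths swept (rejection studies) or
    cross-validated over (accuracy studies). ``mean_h`` fixes the inner
    mean-smoother bandwidth; a Silverman rule of thumb is used per group
    when None.
    """

    n: int = 1000
    theta1: float = 0.5
    theta2: float = 0.5
    dim: Literal[1, 2] = 1
    reps: int = 100
    seed: int = 0
    grid_u: tuple = (-1.0, -0.5, 0.0, 0.5, 1.0)
    h_grid: tuple = (0.2, 0.6, 1.0)
    alpha: float = 0.05
    B: int = 199
    mean_h: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.n < 10:
            raise InvalidParameterError("n must be >= 10")
        if self.reps < 1:
            raise InvalidParameterError("reps must be >= 1")
        for th in (self.theta1, self.theta2):
            if not 0.0 <= th <= 1.0:
                raise InvalidParameterError("theta must be in [0, 1]")
        if self.dim not in (1, 2):
            raise InvalidParameterError("dim must be 1 or 2")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError("alpha must be in (0, 1)")


#: named presets; "paper" follows the published study sizes, "ci" is a
#: scaled-down configuration for quick runs (labeled as such in outputs)
PRESETS: dict[str, SimDesign] = {
    "paper": SimDesign(n=1000, reps=100, label="paper"),
    "paper-n500": SimDesign(n=500, reps=100, label="paper-n500"),
    "ci": SimDesign(n=500, reps=25, label="ci"),
    "accuracy-paper": SimDesign(n=5000, reps=50, label="accuracy-paper",
                                h_grid=(0.2, 0.35, 0.6, 1.0, 1.7)),
    "accuracy-ci": SimDesign(n=1000, reps=10, label="accuracy-ci",
                             h_grid=(0.2, 0.35, 0.6, 1.0, 1.7)),
}


@dataclass
class SimResult:
    """Tidy Monte-Carlo study output.

    ``table`` has one row per aggregated cell (design parameters, covariate
    point, bandwidth, method/metric, value, repetition count, seed).
    """

    table: pd.DataFrame
    reps: int
    seed: int
    failures: int = 0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _simulate_pair(design: SimDesign, rep: int):
    ss = _rep_seed_sequence(design.seed, rep)
    s0, s1 = ss.spawn(2)
    if design.dim == 1:
        g0 = simulate_group_1d(design.n, design.theta1, s0)
        g1 = simulate_group_1d(design.n, design.theta2, s1)
    else:
        g0 = simulate_group_2d(design.n, design.theta1, s0)
        g1 = simulate_group_2d(design.n, design.theta2, s1)
    return g0, g1, ss


def _is_null_point(design: SimDesign, u: np.ndarray) -> bool:
    if design.theta1 == design.theta2:
        return True
    if design.dim == 1:
        return float(u[0]) == 0.0
    return float(u[0]) == float(u[1])


def run_rejection_study(
    design: SimDesign, method: cmptest.Method, add_one: bool = False
) -> SimResult:
    """Empirical rejection rates of one test across (u, h) cells.

    For each repetition the two groups are simulated, conditional
    covariances estimated at every grid point for every bandwidth in
    ``h_grid``, and the requested test run; rejections at ``design.alpha``
    are aggregated into rates. Cells at which the two groups truly share
    their covariance (theta1 = theta2, or u = 0 in the 1-D design, or
    U1 = U2 in the 2-D design) are labeled ``regime="null"`` - their rates
    estimate type-I error; other cells estimate power. Repetitions where
    estimation fails are dropped and counted; more than 5% failures aborts
    the study.
    """
    if method not in cmptest.METHODS:
        raise InvalidParameterError(f"unknown method {method!r}")
    grid = [np.atleast_1d(np.asarray(u, dtype=float)) for u in design.grid_u]
    cells = {(tuple(u), h): [] for u in grid for h in design.h_grid}
    failures = 0
    for rep in range(design.reps):
        try:
            g0, g1, ss = _simulate_pair(design, rep)
            mh0 = design.mean_h or rule_of_thumb_bandwidth(g0.Ucont)
            mh1 = design.mean_h or rule_of_thumb_bandwidth(g1.Ucont)
            R0 = g0.X - condcov.compute_means(g0, BandwidthSpec(h=1.0, mean_h=mh0))
            R1 = g1.X - condcov.compute_means(g1, BandwidthSpec(h=1.0, mean_h=mh1))
            test_seed = int(ss.spawn(3)[2].generate_state(1)[0] % 2**31)
            for h in design.h_grid:
                bw0 = BandwidthSpec(h=h, mean_h=mh0)
                bw1 = BandwidthSpec(h=h, mean_h=mh1)
                for u in grid:
                    w0 = condcov._point_weights(g0, u, bw0, None)
                    w1 = condcov._point_weights(g1, u, bw1, None)
                    S0 = cmptest._weighted_cov(w0, R0)
                    S1 = cmptest._weighted_cov(w1, R1)
                    if method == "tracy_widom":
                        res = cmptest.tracy_widom_test(S0, S1, g0.n, g1.n, u=u)
                    elif method == "forkman":
                        res = cmptest.forkman_test(
                            S0, S1, g0.n, g1.n, B=design.B, seed=test_seed,
                            u=u, add_one=add_one,
                        )
                    else:
                        res = cmptest.permutation_test(
                            g0, g1, u, bw0, bw1, B=design.B, seed=test_seed,
                            residuals=(R0, R1), add_one=add_one,
                        )
                    cells[(tuple(u), h)].append(res.p_value <= design.alpha)
        except CovFunError as exc:
            failures += 1
            logger.warning("rep %d failed: %s", rep, exc)
            if failures > 0.05 * design.reps:
                raise CovFunError(
                    f"{failures} of {design.reps} repetitions failed"
                ) from exc
    rows = []
    for (u, h), flags in cells.items():
        rows.append(
            {
                **_design_cols(design),
                **_u_cols(design, u),
                "h": h,
                "method": method,
                "metric": "rejection_rate",
                "regime": "null" if _is_null_point(design, np.asarray(u)) else "alternative",
                "value": float(np.mean(flags)) if flags else np.nan,
                "rep_count": len(flags),
                "seed": design.seed,
            }
        )
    return SimResult(table=pd.DataFrame(rows), reps=design.reps,
                     seed=design.seed, failures=failures)


def run_eigen_accuracy(design: SimDesign) -> SimResult:
    """Accuracy of the estimated leading combined-matrix eigenvalue.

    Per repetition both groups are simulated, each group's covariance
    bandwidth is selected by the leave-one-out likelihood criterion over
    ``design.h_grid``, and the leading eigenvalue of the estimated combined
    matrix is recorded at every grid point. The aggregated table reports
    the Monte-Carlo mean and standard deviation of the estimate alongside
    the closed-form true eigenvalue (1-D design only).
    """
    if design.dim != 1:
        raise InvalidParameterError("eigenvalue accuracy is defined for the 1-D design")
    grid = [float(np.atleast_1d(u)[0]) for u in design.grid_u]
    lam_hat = np.full((design.reps, len(grid)), np.nan)
    failures = 0
    for rep in range(design.reps):
        try:
            g0, g1, _ = _simulate_pair(design, rep)
            mh0 = design.mean_h or rule_of_thumb_bandwidth(g0.Ucont)
            mh1 = design.mean_h or rule_of_thumb_bandwidth(g1.Ucont)
            grid0 = [BandwidthSpec(h=h, mean_h=mh0) for h in design.h_grid]
            grid1 = [BandwidthSpec(h=h, mean_h=mh1) for h in design.h_grid]
            m0 = condcov.compute_means(g0, grid0[0])
            m1 = condcov.compute_means(g1, grid1[0])
            bw0 = condcov.cv_cov_bandwidth(g0, grid0, means=m0)
            bw1 = condcov.cv_cov_bandwidth(g1, grid1, means=m1)
            for j, u in enumerate(grid):
                S0 = condcov.nw_cond_cov(g0, u, bw0, means=m0).sigma
                S1 = condcov.nw_cond_cov(g1, u, bw1, means=m1).sigma
                ce = cmptest.combined_matrix(S0, S1, g0.n, g1.n)
                lam_hat[rep, j] = ce.lambda1
        except CovFunError as exc:
            failures += 1
            logger.warning("rep %d failed: %s", rep, exc)
            if failures > 0.05 * design.reps:
                raise CovFunError(
                    f"{failures} of {design.reps} repetitions failed"
                ) from exc
    rows = []
    for j, u in enumerate(grid):
        vals = lam_hat[:, j]
        vals = vals[np.isfinite(vals)]
        truth = true_combined_eigen_1d(design.theta1, design.theta2, u)
        rows.append(
            {
                **_design_cols(design),
                "u": u,
                "h": "cv",
                "method": "eigen_accuracy",
                "metric": "lambda1",
                "regime": "null" if _is_null_point(design, np.asarray([u])) else "alternative",
                "value": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "truth": truth,
                "abs_error": float(abs(vals.mean() - truth)),
                "rep_count": int(vals.size),
                "seed": design.seed,
            }
        )
    return SimResult(table=pd.DataFrame(rows), reps=design.reps,
                     seed=design.seed, failures=failures)


def _design_cols(design: SimDesign) -> dict:
    return {
        "dim": design.dim,
        "n": design.n,
        "theta1": design.theta1,
        "theta2": design.theta2,
        "alpha": design.alpha,
        "B": design.B,
        "label": design.label,
    }


def _u_cols(design: SimDesign, u: tuple) -> dict:
    if design.dim == 1:
        return {"u": float(u[0])}
    return {"u1": float(u[0]), "u2": float(u[1])}


def preset(name: str, **overrides) -> SimDesign:
    """Look up a named study preset, optionally overriding fields."""
    if name not in PRESETS:
        raise InvalidParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    design = PRESETS[name]
    return replace(design, **overrides) if overrides else design
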