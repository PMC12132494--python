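"""statsmodels-style model interface for two-group covariance comparison.

:class:`CovarianceComparison` wraps the estimation pipeline: it is built
from two :class:`~covfun.smoothers.GroupSample` objects (or a tidy
DataFrame via :meth:`CovarianceComparison.from_dataframe`), and ``fit()``
selects bandwidths, estimates both conditional covariance functions and
computes a significance trace, returning a
:class:`CovarianceComparisonResults` that carries the table, the selected
bandwidths and a ``summary()``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import cmptest, condcov, smoothers
from .condcov import BandwidthSpec, CondCov
from .exceptions import InvalidParameterError
from .smoothers import GroupSample


class CovarianceComparison:
    """Two-group conditional covariance comparison model.

    Parameters
    ----------
    group0, group1 : GroupSample
        The reference and comparison groups. Responses are assumed
        standardized within each group (``from_dataframe`` standardizes
        for you).
    names : sequence of str, optional
        Labels for the two groups (used in the summary).

    Examples
    --------
    >>> from covfun import simlab
    >>> from covfun.model import CovarianceComparison
    >>> g0 = simlab.simulate_group_1d(400, 0.5, seed=1)
    >>> g1 = simlab.simulate_group_1d(400, 1.0, seed=2)
    >>> res = CovarianceComparison(g0, g1).fit(
    ...     bandwidths=0.6, grid=[-0.5, 0.0, 0.5], B=199, seed=0)
    >>> res.trace.shape[0]
    9
    """

    def __init__(self, group0: GroupSample, group1: GroupSample, names=("group0", "group1")):
        if group0.p != group1.p:
            raise InvalidParameterError("groups must share the response dimension p")
        if group0.q != group1.q or group0.r != group1.r:
            raise InvalidParameterError("groups must share the covariate layout")
        if group0.p < 2:
            raise InvalidParameterError("need p >= 2 responses to compare covariances")
        self.group0 = group0
        self.group1 = group1
        self.names = tuple(names)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group: str,
        responses: Sequence[str],
        covariates: Sequence[str],
        categorical: Sequence[str] = (),
        levels: tuple | None = None,
        standardize: bool = True,
    ) -> "CovarianceComparison":
        """Build the model from a tidy subject-level DataFrame.

        ``group`` must be a column with exactly two levels (sorted order
        decides which is group 0 unless ``levels`` is given). Response
        columns are standardized within each group when ``standardize``.
        """
        if levels is None:
            found = sorted(pd.unique(df[group]).tolist())
            if len(found) != 2:
                raise InvalidParameterError(
                    f"group column {group!r} must have exactly 2 levels, found {found}"
                )
            levels = tuple(found)
        samples = []
        for lv in levels:
            g = df[df[group] == lv]
            X = g[list(responses)].to_numpy(dtype=float)
            if standardize:
                X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
            samples.append(
                GroupSample(
                    X=X,
                    Ucont=g[list(covariates)].to_numpy(dtype=float),
                    Ucat=g[list(categorical)].to_numpy(dtype=object)
                    if categorical
                    else None,
                )
            )
        return cls(samples[0], samples[1], names=tuple(str(lv) for lv in levels))

    # -- fitting -----------------------------------------------------------

    def _resolve_bandwidths(self, bandwidths, h_grid, lam):
        if bandwidths == "cv":
            out = []
            for g in (self.group0, self.group1):
                mean_h = smoothers.select_mean_bandwidth(g, lam=lam)
                sds = g.Ucont.std(axis=0, ddof=1)
                grid = h_grid if h_grid is not None else [
                    s * sds for s in np.geomspace(0.1, 2.0, 10)
                ]
                cands = [BandwidthSpec(h=h, lam=lam, mean_h=mean_h) for h in grid]
                out.append(condcov.cv_cov_bandwidth(g, cands))
            return tuple(out)
        if isinstance(bandwidths, BandwidthSpec):
            return bandwidths, bandwidths
        if isinstance(bandwidths, (int, float, np.ndarray)):
            bw = BandwidthSpec(h=bandwidths, lam=lam)
            return bw, bw
        bw0, bw1 = bandwidths
        if not isinstance(bw0, BandwidthSpec):
            bw0 = BandwidthSpec(h=bw0, lam=lam)
        if not isinstance(bw1, BandwidthSpec):
            bw1 = BandwidthSpec(h=bw1, lam=lam)
        return bw0, bw1

    def fit(
        self,
        bandwidths="cv",
        grid=None,
        methods: Sequence[cmptest.Method] = cmptest.METHODS,
        B: int = 1000,
        alpha: float = 0.05,
        seed: int | None = None,
        h_grid=None,
        lam: float = 1.0,
        target_levels=None,
    ) -> "CovarianceComparisonResults":
        """Estimate bandwidths and the significance trace.

        Parameters
        ----------
        bandwidths : "cv", number, BandwidthSpec or pair
            "cv" selects per-group bandwidths (leave-one-out MSE for the
            mean, leave-one-out Gaussian likelihood for the covariance);
            anything else is used as given (a single value is shared).
        grid : sequence of covariate points, optional
            Defaults to 25 points spanning the intersection of the two
            groups' observed ranges (1-D covariate only).
        """
        bw0, bw1 = self._resolve_bandwidths(bandwidths, h_grid, lam)
        if grid is None:
            if self.group0.q != 1:
                raise InvalidParameterError("pass an explicit grid when q > 1")
            lo = max(self.group0.Ucont.min(), self.group1.Ucont.min())
            hi = min(self.group0.Ucont.max(), self.group1.Ucont.max())
            grid = np.linspace(lo, hi, 25)
        trace = cmptest.significance_trace(
            self.group0, self.group1, grid, bw0, bw1, methods=methods, B=B,
            seed=seed, target_levels=target_levels,
        )
        return CovarianceComparisonResults(
            model=self, trace=trace, bandwidths=(bw0, bw1), alpha=alpha,
            B=B, seed=seed, methods=tuple(methods),
        )


class CovarianceComparisonResults:
    """Fitted results: significance trace, bandwidths and diagnostics."""

    def __init__(self, model, trace, bandwidths, alpha, B, seed, methods):
        self.model = model
        self.trace = trace
        self.bandwidths = bandwidths
        self.alpha = alpha
        self.B = B
        self.seed = seed
        self.methods = methods

    @property
    def pvalues(self) -> pd.DataFrame:
        """p-values pivoted to one column per method."""
        ucols = [c for c in self.trace.columns if c.startswith("u")]
        return self.trace.pivot_table(
            index=ucols, columns="method", values="p_value"
        ).reset_index()

    def cond_cov(self, which: int, u, target_levels=None) -> CondCov:
        """Conditional covariance estimate of group ``which`` at ``u``."""
        g = (self.model.group0, self.model.group1)[which]
        return condcov.nw_cond_cov(
            g, u, self.bandwidths[which], target_levels=target_levels
        )

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        """Rows of the trace with p-value at or below ``alpha``."""
        a = self.alpha if alpha is None else alpha
        return self.trace[self.trace["p_value"] <= a]

    def summary(self):
        """Human-readable summary (a statsmodels SimpleTable stack)."""
        from statsmodels.iolib.table import SimpleTable

        m = self.model
        info = [
            ("groups", f"{m.names[0]} (n={m.group0.n}), {m.names[1]} (n={m.group1.n})"),
            ("responses p", str(m.group0.p)),
            ("covariates q (+r categorical)", f"{m.group0.q} (+{m.group0.r})"),
            ("bandwidth h (group 0)", _fmt(self.bandwidths[0].h_vec)),
            ("bandwidth h (group 1)", _fmt(self.bandwidths[1].h_vec)),
            ("resampling B", str(self.B)),
            ("alpha", str(self.alpha)),
        ]
        head = SimpleTable(
            [[v] for _, v in info],
            headers=["Conditional covariance comparison"],
            stubs=[k for k, _ in info],
        )
        frac = (
            self.trace.dropna(subset=["p_value"])
            .groupby("method")["p_value"]
            .agg(points="size", min_p="min",
                 frac_significant=lambda s: float(np.mean(s <= self.alpha)))
            .reset_index()
        )
        body = SimpleTable(
            [
                [r["method"], f"{int(r['points'])}", f"{r['min_p']:.4g}",
                 f"{r['frac_significant']:.3f}"]
                for _, r in frac.iterrows()
            ],
            headers=["method", "grid points", "min p", "frac p<=alpha"],
        )

        class _Summary:
            def __init__(self, tables):
                self.tables = tables

            def __str__(self):
                return "\n".join(str(t) for t in self.tables)

            def _repr_html_(self):
                return "\n".join(t.as_html() for t in self.tables)

        return _Summary([head, body])

    def plot_trace(self, ax=None, logy: bool = True):
        """Significance-trace plot: p-value against the covariate, per method."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ucols = [c for c in self.trace.columns if c.startswith("u")]
        if len(ucols) != 1:
            raise InvalidParameterError("trace plotting supports one continuous covariate")
        for method, sub in self.trace.groupby("method"):
            sub = sub.sort_values(ucols[0])
            ax.plot(sub[ucols[0]], sub["p_value"], marker=".", label=method)
        ax.axhline(self.alpha, color="k", ls="--", lw=0.8,
                   label=f"alpha = {self.alpha}")
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel(ucols[0])
        ax.set_ylabel("p-value")
        ax.legend()
        return ax


def _fmt(arr) -> str:
    return ", ".join(f"{v:.4g}" for v in np.atleast_1d(arr))
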