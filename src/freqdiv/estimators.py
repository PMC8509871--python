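"""Scikit-learn-style estimators wrapping the variance scan.

``ExcessVarianceScan`` is the headline analysis: fit it to a two-timepoint
:class:`~freqdiv.table.FrequencyTable` (or an equivalent DataFrame) and it
computes the binned variance-coefficient profile, the excess variance
between the intermediate and reference cohorts, the lower bound on
sigma^2(s_bar | p), and block-bootstrap confidence intervals for both.
``ExcessTrajectory`` does the same across three or more timepoints and
fits the log-log growth exponent of the excess variance, which separates
temporally sustained selection (slope ~ 2) from uncorrelated fluctuating
selection (slope ~ 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import scan as _scan
from .bootstrap import block_bootstrap, make_blocks
from .scan import BinningScheme, polarize_major
from .table import FrequencyTable

__all__ = ["ExcessVarianceScan", "ExcessTrajectory"]


def _as_table(X) -> FrequencyTable:
    if isinstance(X, FrequencyTable):
        return X
    if isinstance(X, pd.DataFrame):
        return FrequencyTable.from_dataframe(X)
    raise TypeError(
        "X must be a FrequencyTable or a DataFrame with chrom/pos/freq_* columns"
    )


class ExcessVarianceScan(BaseEstimator):
    """Excess allele-frequency variance scan with a selection-variance bound.

    Parameters
    ----------
    t0, t1 : str, optional
        Timepoint labels to contrast (default: first and second).
    t_gens : float
        Generations separating t0 and t1.
    bin_width, min_loci : binning of initial major-allele frequency.
    p_bin, p_star_bin : (lo, hi)
        Cohort and high-frequency reference bins.
    block_size : int
        Block-bootstrap window in bp.
    n_boot : int
        Bootstrap replicates; 0 disables confidence intervals.
    alpha : float
        CI level is 1 - alpha.
    random_state : int, optional
        Root seed for the bootstrap.

    Attributes
    ----------
    profile_ : VarianceProfile
        Binned C_t(p) with locus counts.
    excess_ : float
        C_t(p) - C_t(p*).
    excess_ci_ : (float, float) or None
    sigma2_bound_ : float
        Lower bound on sigma^2(s_bar | p), per generation squared.
    sigma2_ci_ : (float, float) or None
    result_ : ExcessVarianceResult
    n_loci_ : int
    """

    def __init__(
        self,
        t0=None,
        t1=None,
        t_gens=10.0,
        bin_width=0.025,
        min_loci=100,
        p_bin=_scan.DEFAULT_P_BIN,
        p_star_bin=_scan.DEFAULT_P_STAR_BIN,
        block_size=1_000_000,
        n_boot=1000,
        alpha=0.05,
        random_state=None,
    ):
        self.t0 = t0
        self.t1 = t1
        self.t_gens = t_gens
        self.bin_width = bin_width
        self.min_loci = min_loci
        self.p_bin = p_bin
        self.p_star_bin = p_star_bin
        self.block_size = block_size
        self.n_boot = n_boot
        self.alpha = alpha
        self.random_state = random_state

    def _pair_scheme(self) -> BinningScheme:
        """Binning matched to the cohort pair (its own width, not bin_width)."""
        w = self.p_bin[1] - self.p_bin[0]
        w_star = self.p_star_bin[1] - self.p_star_bin[0]
        if abs(w - w_star) > 1e-9:
            raise ValueError("p_bin and p_star_bin must have equal widths")
        return BinningScheme(bin_width=w, min_loci=self.min_loci)

    # a single-table statistic, reused on every bootstrap replicate
    def _excess_of(self, table: FrequencyTable) -> _scan.ExcessVarianceResult:
        pol = polarize_major(table, self.t0)
        prof = _scan.variance_coefficient(
            pol, t0=self.t0, t1=self.t1, t_gens=self.t_gens,
            scheme=self._pair_scheme(),
        )
        return _scan.excess_variance(prof, self.p_bin, self.p_star_bin)

    def fit(self, X, y=None):
        """Run the scan on a two(+)-timepoint frequency table."""
        table = _as_table(X).drop_missing()
        if table.n_loci == 0:
            raise ValueError("no complete loci to scan")
        scheme = BinningScheme(bin_width=self.bin_width, min_loci=self.min_loci)
        pol = polarize_major(table, self.t0)
        self.profile_ = _scan.variance_coefficient(
            pol, t0=self.t0, t1=self.t1, t_gens=self.t_gens, scheme=scheme
        )
        res = self._excess_of(table)
        self.n_loci_ = table.n_loci
        if self.n_boot and self.n_boot > 0:
            blocks = make_blocks(table, self.block_size)
            boot = block_bootstrap(
                lambda t: self._excess_of(t).excess,
                table,
                blocks=blocks,
                B=int(self.n_boot),
                alpha=self.alpha,
                seed=self.random_state,
            )
            res.ci_lo, res.ci_hi = boot.ci_lo, boot.ci_hi
            self.excess_ci_ = (boot.ci_lo, boot.ci_hi)
        else:
            self.excess_ci_ = None
        self.result_ = res
        self.excess_ = res.excess
        bound = _scan.sigma2_lower_bound(res)
        denom = res.t_gens**2 * res.p_bar * (1.0 - res.p_bar)
        if self.excess_ci_ is not None:
            bound.ci_lo = self.excess_ci_[0] / denom
            bound.ci_hi = self.excess_ci_[1] / denom
            self.sigma2_ci_ = (bound.ci_lo, bound.ci_hi)
        else:
            self.sigma2_ci_ = None
        self.bound_ = bound
        self.sigma2_bound_ = bound.sigma2_bound
        return self

    def summary(self) -> dict:
        """Headline numbers as a plain dict (JSON-serializable)."""
        r = self.result_
        return {
            "t_gens": r.t_gens,
            "p_bin": list(r.p_bin),
            "p_star_bin": list(r.p_star_bin),
            "n": r.n,
            "n_star": r.n_star,
            "C_p": r.C_p,
            "C_p_star": r.C_p_star,
            "excess_variance": r.excess,
            "excess_ci": list(self.excess_ci_) if self.excess_ci_ else None,
            "sigma2_lower_bound": self.sigma2_bound_,
            "sigma2_ci": list(self.sigma2_ci_) if self.sigma2_ci_ else None,
            "n_loci": self.n_loci_,
        }


class ExcessTrajectory(BaseEstimator):
    """Accumulation of excess variance across >= 3 timepoints.

    Cohorts are fixed by the major-allele frequency at ``t0``; for each
    later timepoint the excess variance is computed within those cohorts.
    A log-log regression of positive excess values on elapsed generations
    gives the growth exponent ``slope_``.

    Attributes
    ----------
    trajectory_ : DataFrame with t_gens, excess, C_p, C_p_star (+ CI columns
        when bootstrapping).
    results_ : list of ExcessVarianceResult
    slope_ : float
        Log-log growth exponent of the excess variance over time.
    """

    def __init__(
        self,
        t0=None,
        t_gens=None,
        p_bin=_scan.DEFAULT_P_BIN,
        p_star_bin=_scan.DEFAULT_P_STAR_BIN,
        min_loci=100,
        block_size=1_000_000,
        n_boot=0,
        alpha=0.05,
        random_state=None,
    ):
        self.t0 = t0
        self.t_gens = t_gens
        self.p_bin = p_bin
        self.p_star_bin = p_star_bin
        self.min_loci = min_loci
        self.block_size = block_size
        self.n_boot = n_boot
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y=None):
        table = _as_table(X).drop_missing()
        results = _scan.excess_trajectory(
            table,
            t0=self.t0,
            p_bin=self.p_bin,
            p_star_bin=self.p_star_bin,
            t_gens=self.t_gens,
            min_loci=self.min_loci,
        )
        rows = []
        for k, r in enumerate(results):
            row = {
                "t_gens": r.t_gens,
                "excess": r.excess,
                "C_p": r.C_p,
                "C_p_star": r.C_p_star,
                "n": r.n,
                "n_star": r.n_star,
            }
            rows.append(row)
        if self.n_boot and self.n_boot > 0:
            blocks = make_blocks(table, self.block_size)
            for k, r in enumerate(results):

                def stat(t, _k=k):
                    return _scan.excess_trajectory(
                        t,
                        t0=self.t0,
                        p_bin=self.p_bin,
                        p_star_bin=self.p_star_bin,
                        t_gens=self.t_gens,
                        min_loci=2,
                    )[_k].excess

                boot = block_bootstrap(
                    stat, table, blocks=blocks, B=int(self.n_boot),
                    alpha=self.alpha, seed=self.random_state,
                )
                r.ci_lo, r.ci_hi = boot.ci_lo, boot.ci_hi
                rows[k]["ci_lo"] = boot.ci_lo
                rows[k]["ci_hi"] = boot.ci_hi
        self.results_ = results
        self.trajectory_ = pd.DataFrame(rows)
        t = self.trajectory_["t_gens"].to_numpy(dtype=float)
        e = self.trajectory_["excess"].to_numpy(dtype=float)
        pos = (e > 0) & (t > 0)
        if pos.sum() >= 2:
            self.slope_ = float(
                np.polyfit(np.log(t[pos]), np.log(e[pos]), 1)[0]
            )
        else:
            self.slope_ = np.nan
        return self
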