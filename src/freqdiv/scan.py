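"""Frequency-binned variance coefficients, excess variance and the
selection-variance lower bound.

The scan asks whether temporal allele-frequency divergence is binomial.
For a cohort of SNPs with initial (major-allele) frequency p, the variance
coefficient

    C_t(p) = Var(dp | p) / p(1-p),    dp = p(t1) - p(t0),

is frequency-independent under neutral exchangeable drift (and under
binomial pool-seq measurement error), but is elevated at intermediate p by
among-locus variation in total selection coefficients, whose contribution
scales as [p(1-p)]^2. The "excess variance" C_t(p) - C_t(p*) between an
intermediate bin p and a high-frequency reference bin p* cancels the
frequency-independent drift and measurement terms and yields the lower
bound

    sigma^2(s_bar | p) > (C_t(p) - C_t(p*)) / (t^2 p(1-p))

on the among-locus variance of the time-averaged total selection
coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import FrequencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "BinningScheme",
    "VarianceProfile",
    "ExcessVarianceResult",
    "SelectionVarianceBound",
    "polarize_major",
    "bin_by_frequency",
    "variance_coefficient",
    "normalize_min",
    "excess_variance",
    "excess_trajectory",
    "sigma2_lower_bound",
    "DEFAULT_P_BIN",
    "DEFAULT_P_STAR_BIN",
]

#: default cohort bins: intermediate 0.5 <= p < 0.55, reference 0.9 <= p* < 0.95
DEFAULT_P_BIN = (0.5, 0.55)
DEFAULT_P_STAR_BIN = (0.9, 0.95)


@dataclass(frozen=True)
class BinningScheme:
    """Half-open major-allele frequency bins [lo, lo + width) on [start, stop)."""

    bin_width: float = 0.025
    start: float = 0.5
    stop: float = 1.0
    min_loci: int = 100

    def __post_init__(self):
        if not 0 < self.bin_width <= 0.5:
            raise ValueError("bin_width must lie in (0, 0.5]")
        if not self.start < self.stop <= 1.0 + 1e-12:
            raise ValueError("need start < stop <= 1")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.stop - self.start) / self.bin_width - 1e-9))

    @property
    def edges(self) -> np.ndarray:
        return self.start + self.bin_width * np.arange(self.n_bins + 1)


@dataclass
class VarianceProfile:
    """Per-bin variance coefficients C_t(p); NaN marks undefined bins."""

    bin_lo: np.ndarray
    bin_hi: np.ndarray
    p_bar: np.ndarray
    C: np.ndarray
    n: np.ndarray
    t_gens: float

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.C)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_lo,
                "bin_hi": self.bin_hi,
                "p_bar": self.p_bar,
                "C": self.C,
                "n": self.n,
            }
        )

    def bin_index(self, bin_spec) -> int:
        """Index of the bin whose [lo, hi) matches ``bin_spec`` (lo or (lo, hi))."""
        if np.ndim(bin_spec):
            lo, hi = float(bin_spec[0]), float(bin_spec[1])
        else:
            lo, hi = float(bin_spec), None
        i = int(np.argmin(np.abs(self.bin_lo - lo)))
        if abs(self.bin_lo[i] - lo) > 1e-9:
            raise KeyError(f"no bin with lower edge {lo}")
        if hi is not None and abs(self.bin_hi[i] - hi) > 1e-9:
            raise KeyError(
                f"bin [{lo}, {hi}) does not match the profile's bin width "
                f"{self.bin_hi[i] - self.bin_lo[i]:.4g}; rebin the profile"
            )
        return i


@dataclass
class ExcessVarianceResult:
    """C_t(p) - C_t(p*) for one cohort/reference bin pair."""

    excess: float
    p_bin: tuple
    p_star_bin: tuple
    t_gens: float
    p_bar: float
    p_star_bar: float
    n: int
    n_star: int
    C_p: float
    C_p_star: float
    ci_lo: float | None = None
    ci_hi: float | None = None


@dataclass
class SelectionVarianceBound:
    """Lower bound on sigma^2(s_bar | p), per generation squared."""

    sigma2_bound: float
    t_gens: float
    p_bar: float
    negative: bool = field(init=False)
    ci_lo: float | None = None
    ci_hi: float | None = None

    def __post_init__(self):
        self.negative = bool(self.sigma2_bound < 0)


# ---------------------------------------------------------------------------


def polarize_major(
    table: FrequencyTable, ref_timepoint=None, return_flips: bool = False
):
    """Re-express every locus by its major allele at a reference timepoint.

    A locus whose frequency at ``ref_timepoint`` is below 0.5 has all its
    frequencies complemented (p -> 1-p), so the reported allele is the major
    allele at the reference timepoint. Exact ties at 0.5 keep their
    orientation, making the operation idempotent.
    """
    k = 0 if ref_timepoint is None else table.label_index(ref_timepoint)
    with np.errstate(invalid="ignore"):
        flips = table.freq[:, k] < 0.5
    freq = np.where(flips[:, None], 1.0 - table.freq, table.freq)
    out = FrequencyTable(
        chrom=table.chrom,
        pos=table.pos,
        freq=freq,
        t_labels=table.t_labels,
        depth=table.depth,
        validate=False,
    )
    if return_flips:
        return out, flips
    return out


def bin_by_frequency(p0: np.ndarray, scheme: BinningScheme) -> np.ndarray:
    """Assign initial major-allele frequencies to half-open bins.

    Returns per-locus bin indices; -1 marks unassigned loci (outside
    [start, stop), including fixed loci at p0 = 1, and NaN).
    """
    p0 = np.asarray(p0, dtype=np.float64)
    finite = ~np.isnan(p0)
    if (p0[finite] < scheme.start - 1e-12).any():
        raise ValueError(
            f"frequencies below {scheme.start} encountered; polarize to the "
            "major allele before binning"
        )
    # small relative nudge so p0 landing exactly on an edge joins the bin
    # it is the left edge of (half-open convention), despite float error
    x = (np.nan_to_num(p0, nan=scheme.start) - scheme.start) / scheme.bin_width
    idx = np.floor(x + 1e-9).astype(np.int64)
    bad = ~finite | (p0 >= scheme.stop) | (p0 < scheme.start)
    idx[bad] = -1
    idx[idx >= scheme.n_bins] = -1
    return idx


def variance_coefficient(
    table: FrequencyTable,
    t0=None,
    t1=None,
    t_gens: float = 1.0,
    scheme: BinningScheme | None = None,
) -> VarianceProfile:
    """Binned variance coefficient C_t(p) between two timepoints.

    The table must already be polarized to the major allele at ``t0``.
    Per bin, C = sample variance (ddof=1) of dp = p(t1) - p(t0) across loci,
    divided by p_bar(1 - p_bar), with p_bar the bin's mean initial
    frequency. Bins with fewer than ``scheme.min_loci`` loci are undefined
    (NaN).
    """
    scheme = scheme or BinningScheme()
    if t_gens <= 0:
        raise ValueError("t_gens must be positive")
    i0 = 0 if t0 is None else table.label_index(t0)
    i1 = (1 if t1 is None else table.label_index(t1))
    p0 = table.freq[:, i0]
    dp = table.freq[:, i1] - p0
    ok = ~np.isnan(p0) & ~np.isnan(dp)
    idx = bin_by_frequency(np.where(ok, p0, np.nan), scheme)
    nb = scheme.n_bins
    edges = scheme.edges
    C = np.full(nb, np.nan)
    p_bar = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=np.int64)
    for b in range(nb):
        sel = idx == b
        n[b] = int(sel.sum())
        if n[b] == 0:
            continue
        pb = float(p0[sel].mean())
        p_bar[b] = pb
        if n[b] >= max(scheme.min_loci, 2):
            C[b] = float(np.var(dp[sel], ddof=1)) / (pb * (1.0 - pb))
    if not np.isfinite(C).any():
        raise ValueError(
            f"no bin reaches min_loci={scheme.min_loci}; "
            "reduce min_loci or supply more loci"
        )
    return VarianceProfile(
        bin_lo=edges[:-1].copy(),
        bin_hi=edges[1:].copy(),
        p_bar=p_bar,
        C=C,
        n=n,
        t_gens=float(t_gens),
    )


def normalize_min(profile: VarianceProfile) -> VarianceProfile:
    """Shift C by -min over defined bins, so the minimum becomes 0.

    Used for display across replicates; the excess variance is invariant to
    this shift.
    """
    d = profile.defined()
    if not d.any():
        raise ValueError("profile has no defined bins")
    shift = np.nanmin(profile.C)
    return VarianceProfile(
        bin_lo=profile.bin_lo,
        bin_hi=profile.bin_hi,
        p_bar=profile.p_bar,
        C=profile.C - shift,
        n=profile.n,
        t_gens=profile.t_gens,
    )


def excess_variance(
    profile: VarianceProfile,
    p_bin=DEFAULT_P_BIN,
    p_star_bin=DEFAULT_P_STAR_BIN,
) -> ExcessVarianceResult:
    """Excess variance C_t(p) - C_t(p*) between two bins of a profile."""
    i = profile.bin_index(p_bin)
    j = profile.bin_index(p_star_bin)
    for name, k in (("p_bin", i), ("p_star_bin", j)):
        if np.isnan(profile.C[k]):
            raise ValueError(
                f"{name} [{profile.bin_lo[k]:.3f}, {profile.bin_hi[k]:.3f}) "
                f"is undefined (n={profile.n[k]})"
            )
    return ExcessVarianceResult(
        excess=float(profile.C[i] - profile.C[j]),
        p_bin=(float(profile.bin_lo[i]), float(profile.bin_hi[i])),
        p_star_bin=(float(profile.bin_lo[j]), float(profile.bin_hi[j])),
        t_gens=profile.t_gens,
        p_bar=float(profile.p_bar[i]),
        p_star_bar=float(profile.p_bar[j]),
        n=int(profile.n[i]),
        n_star=int(profile.n[j]),
        C_p=float(profile.C[i]),
        C_p_star=float(profile.C[j]),
    )


def excess_trajectory(
    table: FrequencyTable,
    t0=None,
    p_bin=DEFAULT_P_BIN,
    p_star_bin=DEFAULT_P_STAR_BIN,
    t_gens=None,
    min_loci: int = 100,
) -> list[ExcessVarianceResult]:
    """Excess-variance accumulation across >=3 timepoints.

    Cohort membership in both bins is fixed by the (polarized) frequency at
    ``t0``; for each later timepoint k the excess is computed from
    dp = p(tk) - p(t0) within those fixed cohorts.

    ``t_gens`` gives the generations separating each later timepoint from
    t0 (defaults to 1, 2, ...).
    """
    if table.n_timepoints < 3:
        raise ValueError(
            "excess_trajectory needs >=3 timepoints; use excess_variance for 2"
        )
    i0 = 0 if t0 is None else table.label_index(t0)
    pol = polarize_major(table, table.t_labels[i0])
    p0 = pol.freq[:, i0]
    later = [k for k in range(table.n_timepoints) if k != i0]
    if t_gens is None:
        t_gens = list(range(1, len(later) + 1))
    if len(t_gens) != len(later):
        raise ValueError("t_gens must give one value per non-reference timepoint")

    def cohort(bounds):
        lo, hi = bounds
        sel = (p0 >= lo) & (p0 < hi)
        if int(sel.sum()) < max(min_loci, 2):
            raise ValueError(
                f"cohort [{lo}, {hi}) has only {int(sel.sum())} loci"
            )
        return np.flatnonzero(sel)

    a = cohort(p_bin)
    b = cohort(p_star_bin)
    pa = float(p0[a].mean())
    pb = float(p0[b].mean())
    out = []
    for k, t in zip(later, t_gens):
        dpa = pol.freq[a, k] - p0[a]
        dpb = pol.freq[b, k] - p0[b]
        va = ~np.isnan(dpa)
        vb = ~np.isnan(dpb)
        C_p = float(np.var(dpa[va], ddof=1)) / (pa * (1 - pa))
        C_ps = float(np.var(dpb[vb], ddof=1)) / (pb * (1 - pb))
        out.append(
            ExcessVarianceResult(
                excess=C_p - C_ps,
                p_bin=tuple(p_bin),
                p_star_bin=tuple(p_star_bin),
                t_gens=float(t),
                p_bar=pa,
                p_star_bar=pb,
                n=int(va.sum()),
                n_star=int(vb.sum()),
                C_p=C_p,
                C_p_star=C_ps,
            )
        )
    return out


def sigma2_lower_bound(
    excess: ExcessVarianceResult | float,
    t_gens: float | None = None,
    p_bar: float | None = None,
) -> SelectionVarianceBound:
    """Lower bound on sigma^2(s_bar | p) from an excess-variance estimate.

    ``sigma2 > excess / (t^2 p_bar (1 - p_bar))``. A negative excess gives a
    negative (uninformative) bound, reported as-is with ``negative=True``.
    """
    if isinstance(excess, ExcessVarianceResult):
        t_gens = excess.t_gens if t_gens is None else t_gens
        p_bar = excess.p_bar if p_bar is None else p_bar
        value = excess.excess
    else:
        value = float(excess)
    if t_gens is None or t_gens <= 0:
        raise ValueError("t_gens must be positive")
    if p_bar is None or not 0.0 < p_bar < 1.0:
        raise ValueError("p_bar must lie strictly between 0 and 1")
    return SelectionVarianceBound(
        sigma2_bound=value / (t_gens**2 * p_bar * (1.0 - p_bar)),
        t_gens=float(t_gens),
        p_bar=float(p_bar),
    )
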