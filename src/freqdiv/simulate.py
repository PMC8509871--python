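"""Forward Wright-Fisher simulation with recombination and linked selection,
plus fast linkage-free generators of synthetic allele-frequency data.

The individual-based simulator maintains a diploid population of 2N
haplotypes over a linear genome, with a steady influx of neutral mutations
(markers) and of non-neutral mutations at a fixed selection coefficient.
Each generation: diploid fitness is evaluated (within-locus dominance h,
multiplicative across loci), 2N parents are drawn proportionally to
fitness, each transmits one Poisson-crossover recombinant gamete, and new
mutations are added. After a burn-in of ``10 N`` generations, allele
frequencies are recorded at two snapshots ``t_interval`` generations apart
and the *total* selection coefficient of every segregating locus --
``s = (wF - wNF) / wbar``, the fitness contrast between carriers and
non-carriers of the focal allele including all linked selection -- is
computed from the genotypes at the first snapshot.

The fast cohort sampler realizes the same variance structure without
linkage (each locus evolves independently with a prescribed total selection
coefficient model, compounding drift, and optional two-stage pool-seq
binomial noise); it is orders of magnitude faster and is used wherever
linkage itself is not the object under study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .scan import BinningScheme
from .table import FrequencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "SimState",
    "TotalSelectionTable",
    "REGIMES",
    "regime_params",
    "run_regime",
    "run_structured",
    "total_selection_coefficients",
    "sigma2_by_frequency",
    "pool_seq_noise",
    "fast_cohort_sampler",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class SimParams:
    """Forward-simulation parameters.

    Defaults are a desk-scale preset that preserves the per-gamete totals of
    the classic evolve-and-resequence regime they emulate: a 5 Mb genome
    over 5 freely recombining chromosomes (Drosophila-arm-like), with
    r = mu_neutral = 2e-7 per bp per generation, giving a within-chromosome
    map length of 1 Morgan in total and 1 neutral mutation per gamete per
    generation (the same totals as 100 Mb at 1e-8). Non-neutral mutations
    enter at rate U per gamete per generation, all with selection
    coefficient ``s_sel``.
    """

    N: int = 200
    genome_length: int = 5_000_000
    n_chrom: int = 5
    r: float = 2e-7
    mu_neutral: float = 2e-7
    U: float = 0.0
    s_sel: float = 0.0
    h: float = 0.5
    init: str = "coalescent"  # or "empty"
    burn_in: int | None = None  # default 3 N (coalescent init) or 10 N (empty)
    t_interval: int = 10
    n_demes: int = 1
    m: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if min(self.r, self.mu_neutral, self.U) < 0:
            raise ValueError("rates must be nonnegative")
        if abs(self.s_sel) >= 1:
            raise ValueError("|s_sel| must be < 1")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must lie in [0, 1]")
        if self.n_demes not in (1, 2):
            raise ValueError("n_demes must be 1 or 2")
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if self.init not in ("coalescent", "empty"):
            raise ValueError("init must be 'coalescent' or 'empty'")

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chrom

    @property
    def effective_burn_in(self) -> int:
        """Forward generations before the first snapshot.

        With coalescent initialization the neutral standing variation
        already sits at mutation-drift equilibrium, so the forward burn-in
        only has to equilibrate the non-neutral influx and its linkage
        structure: 3 N generations (a few selected-sojourn times). From an
        empty population the conventional 10 N generations are run.
        """
        if self.burn_in is not None:
            return int(self.burn_in)
        return 3 * self.N if self.init == "coalescent" else 10 * self.N


#: archetypal selection regimes (mutation rate / selection coefficient of
#: the non-neutral influx)
REGIMES = {
    "neutral": dict(U=0.0, s_sel=0.0),
    "negative": dict(U=1.0, s_sel=-0.05),
    "positive": dict(U=0.1, s_sel=0.02),
    "structured": dict(U=0.0, s_sel=0.0, n_demes=2, m=0.01),
}


def regime_params(name: str, **overrides) -> SimParams:
    """A :class:`SimParams` preset for one of the named regimes."""
    if name not in REGIMES:
        raise KeyError(f"unknown regime {name!r}; choose from {sorted(REGIMES)}")
    kw = dict(REGIMES[name])
    kw.update(overrides)
    return SimParams(**kw)


def rescaled_params(name: str, N_base: int = 1000, N: int = 200,
                    **overrides) -> SimParams:
    """A rescaled desk version of a named regime.

    Classic population-rescaling: the reference configuration (``N_base``
    diploids, 1 Morgan of map, 1 neutral and U non-neutral mutations per
    gamete per generation, snapshots 10 generations apart) is mapped to a
    population of ``N`` diploids evolving Q = N_base/N times faster,
    preserving the dimensionless products 2Ns, 4NU, 4N mu and 4N r and
    hence the variance coefficient C_t and the shape of the
    frequency-binned statistics: s -> Q s, U -> Q U, mu -> Q mu, r -> Q r,
    t -> t/Q. Q must divide the 10-generation reference interval.
    """
    if name not in REGIMES:
        raise KeyError(f"unknown regime {name!r}; choose from {sorted(REGIMES)}")
    base = REGIMES[name]
    Q = N_base / N
    t = 10 / Q
    if abs(t - round(t)) > 1e-9 or t < 1:
        raise ValueError(
            f"N_base/N = {Q} does not divide the 10-generation interval"
        )
    kw = dict(
        N=N,
        genome_length=5_000_000,
        n_chrom=5,
        r=2e-7 * Q,
        mu_neutral=2e-7 * Q,
        U=base.get("U", 0.0) * Q,
        s_sel=base.get("s_sel", 0.0) * Q,
        t_interval=int(round(t)),
        n_demes=base.get("n_demes", 1),
        m=min(base.get("m", 0.0) * Q, 1.0),
    )
    kw.update(overrides)
    return SimParams(**kw)


# ---------------------------------------------------------------------------
# numba kernel: one round of reproduction


@njit(cache=True)
def _offspring_kernel(H_old, H_new, parents, start_hap, bp_cut, bp_off):
    # columns are kept sorted by genomic position, so each crossover mosaic
    # is a handful of contiguous segment copies; bp_cut holds the column
    # index of each breakpoint (pre-computed with searchsorted)
    n_gam = H_new.shape[0]
    ncol = H_new.shape[1]
    for g in range(n_gam):
        a = 2 * parents[g]
        k = start_hap[g]
        prev = 0
        for j in range(bp_off[g], bp_off[g + 1]):
            cut = bp_cut[j]
            if cut > prev:
                H_new[g, prev:cut] = H_old[a + k, prev:cut]
                prev = cut
            k ^= 1
        H_new[g, prev:ncol] = H_old[a + k, prev:ncol]
    return


# ---------------------------------------------------------------------------
# population state


class SimState:
    """Diploid haplotype population with a mutation registry.

    Haplotypes are rows of a dense presence/absence matrix over mutation
    slots; the registry maps each active slot to (position, selection
    coefficient, origin generation, id). Individual i owns haplotypes
    2i and 2i+1; with two demes, individuals [0, N/2) form deme 0.
    """

    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.N = params.N
        self.generation = 0
        self.set_columns(
            np.zeros((2 * self.N, 0), dtype=np.uint8),
            np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.float64),
        )
        self._next_id = 0
        if params.n_demes == 2:
            half = self.N // 2
            self.deme = np.repeat(np.array([0, 1]), [half, self.N - half])
        else:
            self.deme = None
        if params.init == "coalescent":
            self._init_coalescent()

    def set_columns(self, H, pos, s, ids=None, origin=None):
        """Install a mutation-column set (columns must be position-sorted)."""
        pos = np.asarray(pos, dtype=np.int64)
        if pos.size > 1 and (np.diff(pos) < 0).any():
            raise ValueError("columns must be sorted by position")
        self.H = np.ascontiguousarray(H, dtype=np.uint8)
        self.pos = pos
        self.s = np.asarray(s, dtype=np.float64)
        n = pos.size
        self.ids = np.arange(n) if ids is None else np.asarray(ids, np.int64)
        self.origin = (
            np.zeros(n, dtype=np.int64) if origin is None
            else np.asarray(origin, np.int64)
        )
        self.tracked = np.zeros(n, dtype=bool)
        self.fixed_flag = np.zeros(n, dtype=bool)

    def _init_coalescent(self):
        """Seed the population with equilibrium neutral standing variation.

        Each chromosome is drawn from an independent coalescent sample of
        2N haplotypes (with the population's recombination and neutral
        mutation rates, and its two-deme migration structure when
        present), so the forward phase starts at mutation-drift
        equilibrium with realistic linkage disequilibrium. Non-neutral
        variation enters only through the forward influx.
        """
        import msprime

        p = self.params
        rng = self.rng
        cols = []
        if p.n_demes == 2:
            half = self.N // 2
            demography = msprime.Demography()
            demography.add_population(name="d0", initial_size=half)
            demography.add_population(name="d1", initial_size=self.N - half)
            demography.set_symmetric_migration_rate(["d0", "d1"], max(p.m, 1e-9))
            samples = {"d0": half, "d1": self.N - half}
            anc_kw = dict(samples=samples, demography=demography)
        else:
            anc_kw = dict(samples=self.N, population_size=self.N)
        for c in range(p.n_chrom):
            ts = msprime.sim_ancestry(
                sequence_length=p.chrom_length,
                recombination_rate=p.r,
                random_seed=int(rng.integers(1, 2**31 - 1)),
                **anc_kw,
            )
            mts = msprime.sim_mutations(
                ts,
                rate=p.mu_neutral,
                random_seed=int(rng.integers(1, 2**31 - 1)),
                discrete_genome=True,
            )
            G = mts.genotype_matrix()  # sites x haplotypes
            if G.size == 0:
                continue
            # fold multiallelic states to presence/absence of the derived allele
            G = (G > 0).astype(np.uint8)
            site_pos = np.array(
                [int(s.position) for s in mts.sites()], dtype=np.int64
            ) + 1 + c * p.chrom_length
            seg = (G.sum(axis=1) > 0) & (G.sum(axis=1) < 2 * self.N)
            cols.append((site_pos[seg], G[seg]))
        if not cols:
            return
        pos = np.concatenate([c[0] for c in cols])
        G = np.vstack([c[1] for c in cols])  # sites x 2N
        self.set_columns(G.T, pos, np.zeros(pos.size))
        self._next_id = pos.size

    # -- per-generation pieces ----------------------------------------------

    @property
    def n_columns(self) -> int:
        return self.pos.size

    def fitness(self) -> np.ndarray | None:
        """Multiplicative diploid fitness per individual; None if uniform."""
        sel = np.flatnonzero(self.s != 0.0)
        if sel.size == 0:
            return None
        D = self.H[0::2][:, sel].astype(np.int64) + self.H[1::2][:, sel]
        s = self.s[sel]
        h = self.params.h
        factor = 1.0 + s * ((D == 2) + h * (D == 1))
        return factor.prod(axis=1)

    def _sample_parents(self, w) -> np.ndarray:
        rng = self.rng
        n_gam = 2 * self.N
        if self.deme is None:
            if w is None:
                return rng.integers(0, self.N, size=n_gam)
            return rng.choice(self.N, size=n_gam, p=w / w.sum())
        # two demes: offspring keep their parent's deme slot; each gamete's
        # parent comes from the other deme with probability m
        par = np.empty(n_gam, dtype=np.int64)
        off_deme = np.repeat(self.deme, 2)
        mig = rng.random(n_gam) < self.params.m
        src = np.where(mig, 1 - off_deme, off_deme)
        for d in (0, 1):
            members = np.flatnonzero(self.deme == d)
            take = np.flatnonzero(src == d)
            if take.size == 0:
                continue
            if w is None:
                par[take] = rng.choice(members, size=take.size)
            else:
                wd = w[members]
                par[take] = rng.choice(members, size=take.size, p=wd / wd.sum())
        return par

    def step(self):
        """Advance one generation: selection, reproduction, mutation, pruning."""
        p = self.params
        rng = self.rng
        n_gam = 2 * self.N
        w = self.fitness()
        parents = self._sample_parents(w)
        # breakpoints: Poisson crossovers within chromosomes plus free
        # reassortment (probability-1/2 breakpoints) at chromosome boundaries
        n_bp = rng.poisson(p.r * p.genome_length, size=n_gam)
        gam_idx = np.repeat(np.arange(n_gam), n_bp)
        vals = rng.integers(1, p.genome_length + 1, size=gam_idx.size)
        if p.n_chrom > 1:
            bmask = rng.random((n_gam, p.n_chrom - 1)) < 0.5
            bg, bb = np.nonzero(bmask)
            gam_idx = np.concatenate([gam_idx, bg])
            vals = np.concatenate([vals, (bb + 1) * p.chrom_length])
            n_bp = n_bp + bmask.sum(axis=1)
        order = np.lexsort((vals, gam_idx))
        bp_cut = np.searchsorted(self.pos, vals[order]).astype(np.int64)
        bp_off = np.zeros(n_gam + 1, dtype=np.int64)
        np.cumsum(n_bp, out=bp_off[1:])
        start_hap = rng.integers(0, 2, size=n_gam).astype(np.uint8)
        H_new = np.empty_like(self.H)
        _offspring_kernel(self.H, H_new, parents, start_hap, bp_cut, bp_off)
        # fates after reproduction
        cnt = H_new.sum(axis=0, dtype=np.int64)
        lost = cnt == 0
        fixed = cnt == n_gam
        keep = ~(lost | fixed) | self.tracked
        fixed_kept = fixed & keep
        if fixed_kept.any():
            H_new[:, fixed_kept] = 0
        new_fixed_flag = self.fixed_flag[keep] | fixed_kept[keep]
        # mutation influx (sorted by position, then merged with survivors)
        n_neut = int(rng.poisson(n_gam * p.mu_neutral * p.genome_length))
        n_sel = int(rng.poisson(n_gam * p.U)) if p.U > 0 else 0
        n_new = n_neut + n_sel
        if n_new:
            newpos = rng.integers(1, p.genome_length + 1, size=n_new)
            news = np.concatenate(
                [np.zeros(n_neut), np.full(n_sel, p.s_sel)]
            )
            gam = rng.integers(0, n_gam, size=n_new)
            newids = np.arange(self._next_id, self._next_id + n_new)
            self._next_id += n_new
            o = np.argsort(newpos, kind="stable")
            newpos, news, gam, newids = newpos[o], news[o], gam[o], newids[o]
        pos_k = self.pos[keep]
        n_keep = int(pos_k.size)
        L2 = n_keep + n_new
        H2 = np.zeros((n_gam, L2), dtype=np.uint8)
        if n_new:
            # stable merge: survivors precede same-position newcomers
            old_dest = (
                np.arange(n_keep)
                + np.searchsorted(newpos, pos_k, side="left")
            )
            new_dest = (
                np.arange(n_new)
                + np.searchsorted(pos_k, newpos, side="right")
            )
            H2[:, old_dest] = H_new[:, keep]
            H2[gam, new_dest] = 1
            pos2 = np.empty(L2, dtype=np.int64)
            pos2[old_dest] = pos_k
            pos2[new_dest] = newpos

            def merge(old, new):
                out = np.empty(L2, dtype=old.dtype)
                out[old_dest] = old
                out[new_dest] = new
                return out

            self.pos = pos2
            self.s = merge(self.s[keep], news)
            self.ids = merge(self.ids[keep], newids)
            self.origin = merge(
                self.origin[keep], np.full(n_new, self.generation)
            )
            self.tracked = merge(
                self.tracked[keep], np.zeros(n_new, dtype=bool)
            )
            self.fixed_flag = merge(
                new_fixed_flag, np.zeros(n_new, dtype=bool)
            )
        else:
            H2[:, :] = H_new[:, keep]
            self.pos = pos_k
            self.s = self.s[keep]
            self.ids = self.ids[keep]
            self.origin = self.origin[keep]
            self.tracked = self.tracked[keep]
            self.fixed_flag = new_fixed_flag
        self.H = H2
        self.generation += 1

    def run(self, generations: int):
        for _ in range(int(generations)):
            self.step()
        return self

    # -- snapshots -----------------------------------------------------------

    def counts(self) -> np.ndarray:
        return self.H.sum(axis=0, dtype=np.int64)

    def segregating(self) -> np.ndarray:
        """Column indices of currently segregating mutations."""
        cnt = self.counts()
        return np.flatnonzero((cnt > 0) & (cnt < 2 * self.N))

    def start_tracking(self, cols: np.ndarray):
        """Keep the given columns addressable across generations.

        Tracked columns survive pruning even when lost (all-zero) or fixed
        (zeroed with a fixation flag), so their frequencies can be read at
        a later snapshot in the same position-sorted order.
        """
        self.tracked[:] = False
        self.tracked[cols] = True
        self.fixed_flag[:] = False

    def tracked_columns(self) -> np.ndarray:
        return np.flatnonzero(self.tracked)

    def tracked_frequencies(self) -> np.ndarray:
        """Frequencies of tracked columns (1.0 for loci that fixed)."""
        cols = self.tracked_columns()
        f = self.H[:, cols].sum(axis=0, dtype=np.int64) / (2.0 * self.N)
        f[self.fixed_flag[cols]] = 1.0
        return f

    def stop_tracking(self):
        self.tracked[:] = False


# ---------------------------------------------------------------------------
# total selection coefficients


@dataclass
class TotalSelectionTable:
    """Per-locus total selection coefficients at a snapshot.

    ``s_total`` is the fitness contrast (wF - wNF)/wbar between carriers and
    non-carriers of the focal allele (dosage-weighted), which captures
    direct plus linked selection. ``s_bar_method`` records whether s_bar
    over the measurement interval was tracked per generation or
    approximated by the snapshot value (constancy approximation).
    """

    pos: np.ndarray
    p: np.ndarray
    s_total: np.ndarray
    is_selected: np.ndarray
    s_bar_method: str = "snapshot"
    s_bar: np.ndarray | None = None

    def __post_init__(self):
        if self.s_bar is None:
            self.s_bar = self.s_total

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pos": self.pos,
                "p": self.p,
                "s_total": self.s_total,
                "s_bar": self.s_bar,
                "is_selected": self.is_selected,
            }
        )


def total_selection_coefficients(state: SimState, slots=None) -> TotalSelectionTable:
    """Total selection coefficient of every segregating locus.

    For each locus, ``s = (wF - wNF) / wbar`` where wF is the dosage-weighted
    mean fitness of individuals over copies of the focal allele (an
    individual with two copies counts twice), wNF the same over non-focal
    copies, and wbar the population mean fitness. With no fitness variation
    the coefficients are identically zero.
    """
    if slots is None:
        slots = state.segregating()
    w = state.fitness()
    n_ind = state.N
    D = state.H[0::2][:, slots].astype(np.float64) + state.H[1::2][:, slots]
    cnt = D.sum(axis=0)
    p = cnt / (2.0 * n_ind)
    if w is None:
        s_total = np.zeros(slots.size)
    else:
        wbar = w.mean()
        num_f = w @ D
        num_nf = w.sum() * 2.0 - num_f
        with np.errstate(invalid="ignore", divide="ignore"):
            wF = num_f / cnt
            wNF = num_nf / (2.0 * n_ind - cnt)
            s_total = (wF - wNF) / wbar
        s_total[(cnt == 0) | (cnt == 2 * n_ind)] = np.nan
    return TotalSelectionTable(
        pos=state.pos[slots].copy(),
        p=p,
        s_total=s_total,
        is_selected=state.s[slots] != 0.0,
    )


def sigma2_by_frequency(
    table: TotalSelectionTable,
    scheme: BinningScheme | None = None,
    t_interval: float | None = None,
) -> pd.DataFrame:
    """Among-locus variance of the time-averaged total selection coefficient,
    binned by major-allele frequency.

    Loci are polarized to the major allele (p -> 1-p flips the sign of s);
    per bin the variance of s_bar and its product with p_bar(1 - p_bar) are
    reported. These are the simulation-truth counterparts of the selective
    divergence that the variance scan estimates; bins below
    ``scheme.min_loci`` are NaN.
    """
    scheme = scheme or BinningScheme()
    flip = table.p < 0.5
    p = np.where(flip, 1.0 - table.p, table.p)
    s = np.where(flip, -table.s_bar, table.s_bar)
    ok = ~np.isnan(s)
    nb = scheme.n_bins
    edges = scheme.edges
    idx = np.floor((p - scheme.start) / scheme.bin_width).astype(np.int64)
    idx[(p < scheme.start) | (p >= scheme.stop) | ~ok] = -1
    idx[idx >= nb] = -1
    rows = []
    for b in range(nb):
        sel = idx == b
        n = int(sel.sum())
        if n >= max(scheme.min_loci, 2):
            pb = float(p[sel].mean())
            v = float(np.var(s[sel], ddof=1))
            rows.append((edges[b], edges[b + 1], pb, v, pb * (1 - pb) * v, n))
        else:
            rows.append((edges[b], edges[b + 1], np.nan, np.nan, np.nan, n))
    return pd.DataFrame(
        rows,
        columns=["bin_lo", "bin_hi", "p_bar", "sigma2_sbar", "pq_sigma2", "n"],
    )


# ---------------------------------------------------------------------------
# regime runner


def _export_snapshot(params, pos, f0, f1, t_labels):
    """Build a per-chromosome FrequencyTable from globally sorted loci.

    Independent uniform draws can collide on position; only the first
    locus at a duplicated position is kept.
    """
    keep = np.ones(pos.size, dtype=bool)
    keep[1:] = np.diff(pos) > 0
    if not keep.all():
        logger.info("dropping %d loci at duplicated positions", int((~keep).sum()))
    order = np.flatnonzero(keep)
    gpos = pos[order]
    ci = np.minimum((gpos - 1) // params.chrom_length, params.n_chrom - 1)
    table = FrequencyTable(
        chrom=np.array([f"chr{c + 1}" for c in ci], dtype=object),
        pos=gpos - ci * params.chrom_length,
        freq=np.column_stack([f0[order], f1[order]]),
        t_labels=t_labels,
    )
    return table, order


def run_regime(
    params: SimParams, record_s_per_gen: bool = False
) -> tuple[FrequencyTable, TotalSelectionTable]:
    """Burn in, then record two frequency snapshots ``t_interval`` apart.

    Returns the two-timepoint :class:`FrequencyTable` of all loci
    segregating at the first snapshot (loci that fix or are lost during the
    interval appear at frequency 1 or 0) and the
    :class:`TotalSelectionTable` computed at the first snapshot. With
    ``record_s_per_gen`` the total selection coefficient of each tracked
    locus is recomputed every generation of the interval and averaged
    (absorbed loci contribute 0 thereafter); by default the snapshot value
    stands in for s_bar (constancy approximation).
    """
    rng = np.random.default_rng(params.seed)
    state = SimState(params, rng)
    state.run(params.effective_burn_in)
    cols = state.segregating()
    if cols.size == 0:
        raise RuntimeError("no segregating variation at the first snapshot")
    tst = total_selection_coefficients(state, cols)
    pos0 = state.pos[cols].copy()
    f0 = state.counts()[cols] / (2.0 * state.N)
    state.start_tracking(cols)
    if record_s_per_gen:
        s_acc = np.where(np.isnan(tst.s_total), 0.0, tst.s_total).copy()
        for _ in range(params.t_interval):
            state.step()
            si = total_selection_coefficients(
                state, state.tracked_columns()
            ).s_total
            s_acc += np.where(np.isnan(si), 0.0, si)
        s_bar = s_acc / (params.t_interval + 1)
        method = "per-generation"
    else:
        state.run(params.t_interval)
        s_bar = None
        method = "snapshot"
    f1 = state.tracked_frequencies()
    state.stop_tracking()
    table, order = _export_snapshot(params, pos0, f0, f1, ("t0", "t1"))
    tst = TotalSelectionTable(
        pos=tst.pos[order],
        p=tst.p[order],
        s_total=tst.s_total[order],
        is_selected=tst.is_selected[order],
        s_bar_method=method,
        s_bar=None if s_bar is None else s_bar[order],
    )
    return table, tst


def run_structured(params: SimParams) -> tuple[FrequencyTable, TotalSelectionTable]:
    """Two-deme run with symmetric migration at fraction m per generation.

    Output frequencies are deme-size-weighted means (demes are equal, so
    this is the global allele frequency). ``m = 0`` gives two independent
    populations; large m approaches panmixia.
    """
    if params.n_demes != 2:
        params = replace(params, n_demes=2)
    return run_regime(params)


# ---------------------------------------------------------------------------
# measurement noise


def pool_seq_noise(
    table: FrequencyTable, n_individuals: int, depth: int, seed=None
) -> FrequencyTable:
    """Two-stage pooled-sequencing binomial noise.

    Per locus and timepoint: 2n chromosomes are drawn binomially from the
    population frequency, then ``depth`` reads are drawn binomially from
    the sampled pool frequency. Both stages are binomial, so the added
    variance is frequency-independent on the C scale:
    ``Var(p_hat) = p(1-p) (1/2n + 1/depth - 1/(2n depth))``.
    """
    if n_individuals < 1 or depth < 1:
        raise ValueError("n_individuals and depth must be >= 1")
    rng = np.random.default_rng(seed)
    f = table.freq
    out = np.full_like(f, np.nan)
    ok = ~np.isnan(f)
    two_n = 2 * int(n_individuals)
    pool = rng.binomial(two_n, f[ok]) / two_n
    reads = rng.binomial(int(depth), pool)
    out[ok] = reads / float(depth)
    d = np.where(ok, float(depth), np.nan)
    return FrequencyTable(
        chrom=table.chrom,
        pos=table.pos,
        freq=out,
        t_labels=table.t_labels,
        depth=d,
        validate=False,
    )


# ---------------------------------------------------------------------------
# fast cohort sampler


def fast_cohort_sampler(
    n_loci: int | None = None,
    p0=0.5,
    s_model: str = "none",
    sigma_s=0.0,
    s_mean=0.0,
    t_gens: int = 10,
    drift_c_per_gen: float = 0.0,
    n_pool: int | None = None,
    depth: int | None = None,
    record_at=None,
    n_chrom: int = 5,
    chrom_length: int = 24_000_000,
    seed=None,
    return_s: bool = False,
):
    """Linkage-free generator of allele-frequency time series.

    Each locus starts at frequency ``p0`` (scalar or per-locus array) and
    iterates ``p <- p + s_g p(1-p) + drift`` for ``t_gens`` generations,
    where the drift increment is binomial with per-generation variance
    ``drift_c_per_gen * p(1-p)`` and the total selection coefficient s_g is

    * ``"none"``      -- s_g = s_mean every generation (0 by default);
    * ``"constant"``  -- s_g drawn once per locus from N(s_mean, sigma_s^2)
                         and held fixed (perfect temporal covariance, the
                         quadratic-growth regime);
    * ``"iid"``       -- s_g redrawn per locus per generation (no temporal
                         covariance, the linear-growth regime).

    ``sigma_s`` and ``s_mean`` may be scalars or per-locus arrays (e.g. a
    selected cohort and a neutral reference cohort in one table).
    Frequencies escaping [0, 1] are clipped and counted
    (``table.n_clipped``). Loci are placed evenly along ``n_chrom``
    chromosomes so 1 Mb block bootstrapping applies. ``record_at`` lists
    generations to record (default: 0 and t_gens); with pool-seq noise
    parameters the recorded frequencies are noisy read-based estimates.
    """
    rng = np.random.default_rng(seed)
    p0 = np.atleast_1d(np.asarray(p0, dtype=np.float64))
    if n_loci is None:
        n_loci = max(p0.size, np.size(sigma_s), np.size(s_mean))
    if p0.size == 1:
        p0 = np.full(n_loci, p0[0])
    if p0.size != n_loci:
        raise ValueError("p0 must be scalar or length n_loci")
    if s_model not in ("none", "constant", "iid"):
        raise ValueError("s_model must be 'none', 'constant' or 'iid'")
    sigma_s = np.broadcast_to(np.asarray(sigma_s, dtype=np.float64), (n_loci,))
    s_mean = np.broadcast_to(np.asarray(s_mean, dtype=np.float64), (n_loci,))
    if (sigma_s < 0).any():
        raise ValueError("sigma_s must be >= 0")
    if drift_c_per_gen < 0 or drift_c_per_gen >= 1:
        raise ValueError("drift_c_per_gen must lie in [0, 1)")
    record_at = sorted({0, int(t_gens)} if record_at is None
                       else {int(g) for g in record_at} | {0})
    n_eff = int(round(1.0 / drift_c_per_gen)) if drift_c_per_gen > 0 else 0

    if s_model == "constant":
        s_fixed = rng.normal(s_mean, sigma_s)
    elif s_model == "none":
        s_fixed = s_mean.copy()
    else:
        s_fixed = None

    p = p0.copy()
    snaps = {0: p0.copy()}
    n_clipped = 0
    for g in range(1, int(t_gens) + 1):
        s_g = rng.normal(s_mean, sigma_s) if s_model == "iid" else s_fixed
        p = p + s_g * p * (1.0 - p)
        below, above = p < 0.0, p > 1.0
        n_clipped += int(below.sum() + above.sum())
        np.clip(p, 0.0, 1.0, out=p)
        if n_eff:
            p = rng.binomial(n_eff, p) / n_eff
        if g in record_at:
            snaps[g] = p.copy()
    if n_clipped:
        logger.info("fast_cohort_sampler clipped %d boundary escapes", n_clipped)

    # even spacing over a synthetic multi-chromosome genome
    per = np.full(n_chrom, n_loci // n_chrom)
    per[: n_loci % n_chrom] += 1
    chrom = np.concatenate(
        [np.repeat(f"chr{i + 1}", k) for i, k in enumerate(per)]
    ).astype(object)
    pos = np.concatenate(
        [
            (np.arange(k) * (chrom_length / max(k, 1)) + chrom_length / (2 * max(k, 1)))
            .astype(np.int64) + 1
            for k in per
        ]
    )
    labels = tuple(f"g{g}" for g in record_at)
    freq = np.column_stack([snaps[g] for g in record_at])
    table = FrequencyTable(chrom=chrom, pos=pos, freq=freq, t_labels=labels,
                           validate=False)
    if n_pool is not None or depth is not None:
        if n_pool is None or depth is None:
            raise ValueError("give both n_pool and depth for pool-seq noise")
        table = pool_seq_noise(table, n_pool, depth,
                               seed=rng.integers(0, 2**31 - 1))
    table.n_clipped = n_clipped
    if return_s:
        true_s = s_fixed if s_fixed is not None else None
        return table, true_s
    return table
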