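"""Forward simulator: parameter validation, determinism, total selection
coefficients (two-locus oracle), pool-seq noise, and the fast cohort
sampler's variance structure."""

import numpy as np
import pytest

from freqdiv.scan import BinningScheme
from freqdiv.simulate import (
    SimParams,
    SimState,
    fast_cohort_sampler,
    pool_seq_noise,
    regime_params,
    run_regime,
    run_structured,
    sigma2_by_frequency,
    total_selection_coefficients,
)
from freqdiv.table import FrequencyTable

SMALL = dict(N=60, genome_length=500_000, n_chrom=2, r=2e-6, mu_neutral=2e-6,
             burn_in=40, t_interval=5)


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(N=1),
            dict(r=-1e-8),
            dict(U=-0.1),
            dict(s_sel=1.5),
            dict(m=1.5),
            dict(n_demes=3),
            dict(init="bogus"),
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SimParams(**kw)

    def test_burn_in_defaults(self):
        assert SimParams(N=100).effective_burn_in == 300
        assert SimParams(N=100, init="empty").effective_burn_in == 1000
        assert SimParams(N=100, burn_in=7).effective_burn_in == 7

    def test_regime_presets(self):
        p = regime_params("negative")
        assert p.U == 1.0 and p.s_sel == -0.05
        with pytest.raises(KeyError):
            regime_params("bogus")


class TestRunRegime:
    def test_deterministic_given_seed(self):
        a_ft, a_tst = run_regime(SimParams(seed=5, **SMALL))
        b_ft, b_tst = run_regime(SimParams(seed=5, **SMALL))
        assert a_ft.equals(b_ft)
        assert np.array_equal(a_tst.s_total, b_tst.s_total, equal_nan=True)
        c_ft, _ = run_regime(SimParams(seed=6, **SMALL))
        assert not a_ft.equals(c_ft)

    def test_neutral_has_zero_total_selection(self):
        _, tst = run_regime(SimParams(seed=1, **SMALL))
        assert np.all(tst.s_total == 0.0)
        assert not tst.is_selected.any()

    def test_output_structure(self):
        ft, tst = run_regime(SimParams(seed=2, **SMALL))
        assert ft.t_labels == ("t0", "t1")
        assert ft.n_loci == tst.p.size
        # tracked loci segregate at the first snapshot
        assert np.all((ft.freq[:, 0] > 0) & (ft.freq[:, 0] < 1))
        # coordinates valid per chromosome
        ft._check()

    def test_selected_regime_registers_selected_loci(self):
        p = regime_params("negative", seed=3, **SMALL)
        _, tst = run_regime(p)
        assert tst.is_selected.any()
        assert np.nanstd(tst.s_total) > 0

    def test_per_generation_s_recording(self):
        p = regime_params("positive", seed=4, **SMALL)
        _, tst = run_regime(p, record_s_per_gen=True)
        assert tst.s_bar_method == "per-generation"
        assert tst.s_bar is not None and tst.s_bar.shape == tst.s_total.shape


class TestTotalSelection:
    def _two_locus_state(self, n_AB, n_aB, n_Ab, n_ab, s_b):
        """Haploid-equivalent two-locus population.

        Every individual is homozygous for one haplotype, so its diploid
        fitness (homozygote 1 + s) equals the haploid fitness of that
        haplotype and the dosage-weighted means reduce to haplotype means.
        """
        N = n_AB + n_aB + n_Ab + n_ab
        params = SimParams(N=N, genome_length=1000, n_chrom=1, r=0.0,
                           mu_neutral=0.0, init="empty", burn_in=0,
                           s_sel=s_b)
        state = SimState(params, np.random.default_rng(0))
        # columns: 0 = neutral focal allele A, 1 = selected allele B
        hapA = [1] * n_AB + [0] * n_aB + [1] * n_Ab + [0] * n_ab
        hapB = [1] * n_AB + [1] * n_aB + [0] * n_Ab + [0] * n_ab
        H = np.zeros((2 * N, 2), dtype=np.uint8)
        for i in range(N):
            H[2 * i, 0] = H[2 * i + 1, 0] = hapA[i]
            H[2 * i, 1] = H[2 * i + 1, 1] = hapB[i]
        state.set_columns(H, np.array([100, 200]), np.array([0.0, s_b]))
        return state

    def test_two_locus_oracle(self):
        # p = q = 0.5 with D = 0.1: haplotypes AB 0.35, Ab 0.15, aB 0.15, ab 0.35
        state = self._two_locus_state(140, 60, 60, 140, s_b=0.05)
        tst = total_selection_coefficients(state)
        i = int(np.flatnonzero(tst.pos == 100)[0])
        # closed form s_b D / (p(1-p) (1 + s_b q))
        assert tst.s_total[i] == pytest.approx(
            0.05 * 0.1 / (0.25 * 1.025), abs=1e-12
        )
        assert tst.s_total[i] == pytest.approx(0.019512195, abs=5e-10)

    def test_linkage_equilibrium_gives_zero(self):
        # D = 0: the neutral allele is exchangeable across backgrounds
        state = self._two_locus_state(100, 100, 100, 100, s_b=0.05)
        tst = total_selection_coefficients(state)
        i = int(np.flatnonzero(tst.pos == 100)[0])
        assert tst.s_total[i] == pytest.approx(0.0, abs=1e-14)

    def test_no_fitness_variation_gives_exact_zero(self):
        state = self._two_locus_state(140, 60, 60, 140, s_b=0.0)
        tst = total_selection_coefficients(state)
        assert np.all(tst.s_total == 0.0)


class TestSigma2ByFrequency:
    def test_all_neutral_gives_zero_bins(self):
        _, tst = run_regime(SimParams(seed=9, **SMALL))
        df = sigma2_by_frequency(tst, BinningScheme(bin_width=0.25, min_loci=2))
        d = df.dropna()
        assert len(d) > 0
        assert np.allclose(d.sigma2_sbar, 0.0)
        assert np.allclose(d.pq_sigma2, 0.0)

    def test_sparse_bins_undefined(self):
        _, tst = run_regime(SimParams(seed=9, **SMALL))
        df = sigma2_by_frequency(tst, BinningScheme(bin_width=0.025, min_loci=10**6))
        assert df.sigma2_sbar.isna().all()


class TestPoolSeqNoise:
    def test_compound_binomial_variance(self, rng):
        # Var = p(1-p) (1/2n + 1/depth - 1/(2n depth)) at p=0.5, n=depth=100
        t = FrequencyTable(
            chrom=np.repeat("c", 100_000).astype(object),
            pos=np.arange(1, 100_001),
            freq=np.full((100_000, 2), 0.5),
            t_labels=("a", "b"),
        )
        noisy = pool_seq_noise(t, n_individuals=100, depth=100, seed=11)
        expected = 0.25 * (1 / 200 + 1 / 100 - 1 / 20_000)
        assert expected == pytest.approx(0.0037375)
        observed = noisy.freq[:, 0].var()
        se = expected * np.sqrt(2 / 100_000)
        assert abs(observed - expected) < 3 * se

    def test_infinite_depth_limit(self):
        t = FrequencyTable(
            chrom=np.repeat("c", 50_000).astype(object),
            pos=np.arange(1, 50_001),
            freq=np.full((50_000, 2), 0.3),
            t_labels=("a", "b"),
        )
        noisy = pool_seq_noise(t, n_individuals=50, depth=10**6, seed=12)
        expected = 0.3 * 0.7 / 100
        assert noisy.freq[:, 0].var() == pytest.approx(expected, rel=0.05)

    def test_absorbing_frequencies_are_noise_free(self):
        t = FrequencyTable(
            chrom=np.repeat("c", 10).astype(object),
            pos=np.arange(1, 11),
            freq=np.column_stack([np.zeros(10), np.ones(10)]),
            t_labels=("a", "b"),
        )
        noisy = pool_seq_noise(t, 100, 100, seed=13)
        assert np.all(noisy.freq[:, 0] == 0.0)
        assert np.all(noisy.freq[:, 1] == 1.0)

    def test_invalid_params(self, rng):
        t = FrequencyTable(
            chrom=np.array(["c"], dtype=object), pos=np.array([1]),
            freq=np.array([[0.5, 0.5]]), t_labels=("a", "b"),
        )
        with pytest.raises(ValueError):
            pool_seq_noise(t, 0, 100)


class TestFastCohortSampler:
    def test_constant_s_quadratic_variance(self):
        # among-locus Var(dp) ~ [p(1-p)]^2 t^2 sigma_s^2
        tab = fast_cohort_sampler(
            n_loci=150_000, p0=0.5, s_model="constant", sigma_s=0.01,
            t_gens=10, seed=21,
        )
        dp = tab.freq[:, 1] - tab.freq[:, 0]
        assert dp.var() == pytest.approx(6.25e-4, rel=0.05)

    def test_iid_s_linear_variance(self):
        tab = fast_cohort_sampler(
            n_loci=150_000, p0=0.5, s_model="iid", sigma_s=0.01,
            t_gens=10, seed=22,
        )
        dp = tab.freq[:, 1] - tab.freq[:, 0]
        assert dp.var() == pytest.approx(6.25e-5, rel=0.05)

    def test_drift_only_compound(self):
        tab = fast_cohort_sampler(
            n_loci=100_000, p0=0.5, t_gens=10, drift_c_per_gen=1e-3, seed=23
        )
        dp = tab.freq[:, 1] - tab.freq[:, 0]
        expected = (1 - (1 - 1e-3) ** 10) * 0.25
        assert dp.var() == pytest.approx(expected, rel=0.05)

    def test_boundary_clipping_flagged(self):
        tab = fast_cohort_sampler(
            n_loci=2_000, p0=0.98, s_model="constant", sigma_s=0.5,
            t_gens=5, seed=24,
        )
        assert tab.n_clipped > 0
        assert np.all((tab.freq >= 0) & (tab.freq <= 1))

    def test_recording_and_labels(self):
        tab = fast_cohort_sampler(
            n_loci=10, p0=0.5, t_gens=6, record_at=[0, 3, 6], seed=25
        )
        assert tab.t_labels == ("g0", "g3", "g6")
        assert tab.freq.shape == (10, 3)

    def test_positions_span_chromosomes(self):
        tab = fast_cohort_sampler(n_loci=1000, p0=0.5, t_gens=1, n_chrom=5, seed=26)
        assert len(set(tab.chrom)) == 5
        tab._check()

    def test_per_locus_sigma_broadcast(self):
        sig = np.concatenate([np.full(5_000, 0.02), np.zeros(5_000)])
        tab = fast_cohort_sampler(
            p0=0.5, s_model="constant", sigma_s=sig, t_gens=10, seed=27
        )
        dp = tab.freq[:, 1] - tab.freq[:, 0]
        assert dp[:5_000].var() > 20 * dp[5_000:].var()

    def test_pool_seq_noise_integration(self):
        tab = fast_cohort_sampler(
            n_loci=100, p0=0.5, t_gens=2, n_pool=100, depth=80, seed=28
        )
        assert tab.depth is not None
        assert np.all(tab.depth == 80)

    @pytest.mark.parametrize("bad", [dict(s_model="x"), dict(sigma_s=-1.0),
                                     dict(drift_c_per_gen=1.5)])
    def test_invalid_params(self, bad):
        with pytest.raises(ValueError):
            fast_cohort_sampler(n_loci=10, p0=0.5, **bad)


class TestStructured:
    def test_runs_and_exports(self):
        p = SimParams(seed=31, n_demes=2, m=0.05, **SMALL)
        ft, tst = run_structured(p)
        assert ft.n_loci > 0
        ft._check()

    def test_weak_migration_creates_intermediate_frequency_deficit(self):
        """Differentiated demes depress variance at intermediate relative
        to high major-allele frequencies (negative excess), the opposite
        signature to selection."""
        from freqdiv.scan import BinningScheme
        from freqdiv.scan import excess_variance, polarize_major, variance_coefficient

        signs = []
        for seed in (17000, 17001, 17002):
            ft, _ = run_structured(
                SimParams(N=200, n_demes=2, m=0.002, t_interval=10, seed=seed)
            )
            prof = variance_coefficient(
                polarize_major(ft), t_gens=10,
                scheme=BinningScheme(bin_width=0.05, min_loci=30),
            )
            signs.append(excess_variance(prof).excess < 0)
        assert sum(signs) >= 2

    def test_zero_migration_two_independent_populations(self):
        # with m=0 and empty init the demes never exchange migrants, so a
        # mutation can only segregate within one deme: deme-restricted
        # frequencies are multiples of 1/deme-size at the global scale
        p = SimParams(N=40, genome_length=200_000, n_chrom=1, r=1e-6,
                      mu_neutral=5e-6, burn_in=60, t_interval=2,
                      n_demes=2, m=0.0, init="empty", seed=32)
        rng = np.random.default_rng(p.seed)
        state = SimState(p, rng)
        state.run(p.effective_burn_in)
        slots = state.segregating()
        half = p.N // 2
        in_d0 = state.H[: 2 * half, slots].sum(axis=0)
        in_d1 = state.H[2 * half:, slots].sum(axis=0)
        # every mutation is private to one deme
        assert np.all((in_d0 == 0) | (in_d1 == 0))
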