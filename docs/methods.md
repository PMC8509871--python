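# Methods

## The statistic

For a cohort of SNPs with initial major-allele frequency p, the
among-locus variance of the t-generation frequency change defines the
variance coefficient

    C_t(p) = Var(Δ_t p | p) / p(1 − p).

Under neutral, exchangeable drift — Wright–Fisher and the broader Cannings
family, and equally under binomial pool-seq measurement error — C_t is
frequency-independent (for Wright–Fisher, C_t = 1 − (1 − 1/2N)^t).
Selection breaks exchangeability: if the total selection coefficient s
(direct plus all linked selection, s = (w̄F − w̄NF)/w̄) varies among loci
with among-locus variance σ²(s|p), the expected per-generation change
s·p(1−p) contributes a selective divergence [p(1−p)]²·σ²(Σᵢsᵢ) to
Var(Δ_t p), i.e. an extra p(1−p)·σ²(Σᵢsᵢ) term in C_t(p) that is largest
at intermediate frequencies. The decomposition used throughout is

    C_t(p) = D_t + D_t·c·(1−2p)·E[Σᵢsᵢ|p] + p(1−p)·σ²(Σᵢsᵢ|p),

with D_t the frequency-independent drift term, the middle term a small
drift perturbation from a mean selective displacement (c an order-1
constant), and the last term the signal.

The **excess variance** C_t(p) − C_t(p*) between an intermediate cohort
(default 0.50 ≤ p < 0.55) and a high-frequency reference cohort
(default 0.90 ≤ p* < 0.95) cancels D_t and the measurement term M exactly
— both are frequency-independent — and, because the reference cohort's own
selective divergence is subtracted too, yields only a lower bound

    σ²(s̄|p) > (C_t(p) − C_t(p*)) / (t² p(1−p)),

where s̄ is the per-generation time-average of s over the interval.

## Estimator conventions

Choices the statistic's definition leaves open:

* per-bin sample variance with denominator n − 1; bins are half-open
  [lo, lo + w) on the major-allele scale, polarized at the first (or a
  chosen reference) timepoint; exact ties at p = 0.5 keep orientation.
* the p(1−p) denominator uses the bin's mean initial frequency p̄, not the
  midpoint or per-locus values; with 2.5% bins the difference is below
  0.1% and the bin mean is what the bound needs.
* bins with fewer than `min_loci` (default 100) loci are undefined (NaN)
  rather than noisy; near p → 1 variance estimates are dominated by
  sampling error.
* for trajectories across ≥3 timepoints, cohort membership in both bins is
  fixed by the frequency at the first timepoint and polarization is done
  once, there.
* loci with a missing frequency (zero depth) at any required timepoint are
  excluded, with a log record.
* `normalize_min` (subtracting min_p C_t(p), used for cross-replicate
  display) never affects the excess: the shift cancels in the difference,
  and a test asserts this exactly.

Uncertainty comes from a percentile block bootstrap: chromosomes are tiled
into 1 Mb windows (~120 for a Drosophila-scale genome), whole windows are
resampled with replacement, and the entire statistic — polarization,
binning, variances — is recomputed per replicate, because C_t(p) is a
ratio statistic. B = 1000 replicates by default, percentile method with no
bias correction, one root seed spawning per-replicate streams. Replicates
on which the statistic is undefined (an empty bin after resampling) are
dropped and counted, with a warning past 20%.

## Forward simulator

An individual-based diploid Wright–Fisher model with selection,
recombination and a steady mutational influx validates the method end to
end. Each generation: multiplicative fitness across loci with dominance h
(heterozygote 1 + hs, homozygote 1 + s; h = 0.5 by default — the common
simulator default, chosen here because the fitness combination rule is
otherwise unconstrained), fitness-proportional parent sampling, one
Poisson-crossover recombinant gamete per parent, then new mutations:
neutral markers at rate `mu_neutral` per bp and non-neutral mutations at
rate U per gamete per generation, all with the same coefficient `s_sel`.
The genome is `n_chrom` freely reassorting chromosomes (default 5,
Drosophila-arm-like); within chromosomes crossovers fall uniformly.
Haplotypes are rows of a dense presence/absence matrix whose mutation
columns are kept position-sorted, so recombination is a handful of
contiguous segment copies per gamete and each generation ends with one
merge pass that drops lost/fixed columns and inserts new mutations in
position order.

The total selection coefficient of every segregating locus is computed
from genotypes as the dosage-weighted fitness contrast
s = (w̄F − w̄NF)/w̄ (an individual carrying two focal copies counts
twice); with no fitness variation it is identically zero, and a two-locus
hand-worked oracle (s_b D / (p(1−p)(1 + s_b q)) in a haploid-equivalent
homozygote population) pins the implementation to 9 decimals. By default
s̄ over the snapshot interval is approximated by the first-snapshot value
(the constancy approximation, flagged in the output); per-generation
tracking and averaging is available at extra cost.

**Initialization.** The neutral standing variation is seeded from a
coalescent sample (msprime) of 2N haplotypes per chromosome at the
population's mutation and recombination rates — equilibrium SFS and LD
from the start — followed by a forward burn-in of 3N generations to
equilibrate the non-neutral influx (a few selected-sojourn times). From an
empty population the conventional 10N burn-in is used instead. The
calibration tests do not depend on this choice; it sets the runtime.

**Scale.** The reference configuration mirrors a classic
evolve-and-resequence design: N = 1000 diploids, a genome of ~1 Morgan
and 1 neutral mutation per gamete per generation, snapshots t = 10
generations apart, regimes (U, s) ∈ {neutral; 1, −0.05; 0.1, +0.02}. Two
desk-scale forms are used:

* *direct*: N = 200–1000 with the per-gamete totals kept (5 Mb at
  r = μ = 2e-7), burn-in as above — used for the neutral calibration,
  where C_t = 1 − (1 − 1/2N)^t must hold at the simulated N and t = 10;
* *rescaled* (`rescaled_params`): the classic Q-fold speedup, Q = 5 —
  N → N/Q, s → Qs, U → QU, μ → Qμ, r → Qr, t → t/Q — preserving 2Ns, 4NU,
  4Nμ, 4Nr and hence C_t and the frequency-binned statistics, at roughly
  1/Q² the cost. Used for the positive regime (Q·s = 0.1 keeps the
  small-s regime); the negative regime's s = −0.05 influx cannot be
  rescaled without leaving it (Q·|s| ≥ 0.25), so that regime runs at its
  literal parameters with thinned neutral markers and a short burn-in
  (see below).

**What the simulator shows — and what it does not.** At desk scale the
per-replicate excess-variance estimate carries substantial noise from
linkage: loci sharing a chromosome co-fluctuate, so the effective number
of independent observations per replicate is set by the genome's map
length (roughly the number of ~0.1-Morgan blocks times interval length),
not by the SNP count. The positive-selection regime elevates the excess
on average and in the majority of replicates, and the negative-selection
regime shows the compensating frequency profile of σ²(s̄|p) (strong
selection concentrated at extreme frequencies, p(1−p)σ²(s̄|p) roughly
flat); single desk-scale replicates are individually significant only in
part. Pooling replicates (each entering the block bootstrap as its own
pseudo-chromosome set) is the supported way to reach the precision of a
full-scale experiment.

## Fast cohort sampler

Where linkage itself is not under study, `fast_cohort_sampler` iterates
p ← p + s_g·p(1−p) + drift per locus independently: drift is a binomial
increment with per-generation variance `drift_c_per_gen`·p(1−p)
(n_eff = 1/drift_c), and s_g is 0, constant per locus, or i.i.d. per
generation, drawn from Normal(s_mean, σ_s²) with per-locus σ_s allowed.
Boundary escapes are clipped and counted. Optional two-stage pool-seq
noise draws 2n chromosomes then `depth` reads binomially; its variance
p(1−p)(1/2n + 1/depth − 1/(2n·depth)) is frequency-proportional, hence a
frequency-independent contribution to C that the excess cancels. Loci are
placed evenly along a synthetic multi-chromosome genome so 1 Mb block
bootstrapping applies.

Synthetic initial frequencies for estimator validation are drawn from a
folded-SFS-like density ∝ 1/(p(1−p)) on [0.5, 0.98). This matters: with
measurement noise, binning is by the *observed* initial frequency, and
the conditional spread of the true frequency given the observed bin is
frequency-proportional (hence cancelling) only when the underlying
frequency distribution is continuous — as real SFS data are. A synthetic
design in which the selective field switches off exactly at a bin edge
reintroduces an edge artifact and attenuates the recovered bound; the
recovery experiment therefore applies selection on a band (σ_s = 0.01 for
p0 < 0.7, zero above) that covers the intermediate cohort and vanishes
well before the reference cohort, exactly matching the construction the
bound assumes (a selection-free reference).

## Closed forms

`theory` collects the pieces used for planning and cross-checks: the
Wright–Fisher C_t; the selective divergence [p(1−p)]²·σ²·K(t) with
K = t² (constant s), t (i.i.d. s) or the geometric-decay interpolation
Σ ρ^|i−j| (two-locus LD decay picture; ρ is phenomenological, not derived
from a map); the drift perturbation D_t·c·(1−2p)·E[Σs] with c exposed and
defaulting to 1; the migration divergence m²·Var(p*−p|p); the sampling
error SE(C) = √(2/L)·C (Gaussian Δp, large L); and the detection limit
L = 2·(n_se·C/(t²p(1−p)σ²))², the number of independent loci at which the
signal equals n_se standard errors (n_se = 1 by default). At C = 10⁻²,
σ² = 10⁻⁴, p = 0.5, t = 1 this gives L = 3.2×10⁵ — detecting 1% selection
coefficients in one generation takes a few hundred thousand independent
SNPs even at high noise.

## Numerical choices and degenerate inputs

* Frequencies are float64 throughout; missing measurements are NaN and
  excluded locus-wise.
* Bin assignment adds a 1e-9 relative nudge before flooring so exact bin
  edges land in the bin they open despite float representation.
* p0 = 1 (fixed at the reference timepoint) is never binned.
* A negative excess (sampling noise) propagates to a negative, flagged
  σ² bound rather than being clipped.
* Duplicate simulator positions (uniform draws colliding) are dropped at
  export, keeping the first.
* Sync parsing requires exactly two pooled-count alleles; the focal allele
  is the alphabetically first, and zero two-allele depth at a timepoint is
  a missing measurement, not a zero frequency.

## Problem sizes

The shipped tests and the acceptance script run the neutral calibration
at N = 200, t = 10 with 50 (tests) or 12 (script) replicates pooled; the
positive regime at the Q = 5 rescale with 12 replicates; the negative
regime at its literal parameters (N = 1000, U = 1, s = −0.05, t = 10)
with thinned markers, a 200-generation burn-in atop the
coalescent-equilibrium start (the deleterious pool turns over within ~10
generations and marker–deleterious LD is set at mutation origin) and 3/2
replicates; estimator recovery over five datasets of 10⁵ noisy loci;
growth laws at 10⁵ loci; bootstrap coverage with 40-block data,
B ∈ {500, 1000} and 150–200 repetitions. These sizes put most checks'
Monte-Carlo error well inside their assertion tolerances while keeping a
full run on a single CPU in the tens of minutes. The exceptions, noted
above, are the per-replicate sign statistics of the measured excess under
the selection regimes, whose noise is linkage-limited and comparable to
the desk-scale signal; the σ²-profile contrasts carry the regime
distinction robustly.

## Known limitations

* The bound is a lower bound twice over: reference-cohort selection and
  temporal decorrelation of s both push it down; it is not an estimator of
  σ²(s|p) itself.
* The simulator's fitness model is multiplicative with a single fixed s
  per regime; distributions of fitness effects, epistasis, dominance
  sweeps (h ≠ ½) and overlapping generations are out of scope.
* The fast sampler has no linkage by construction; it cannot generate the
  among-locus correlations that set desk-scale replicate noise in the
  forward simulator.
* Population structure and migration enter only through the two-deme
  symmetric-migration mode and the m²·Var(p*−p|p) closed form;
  structured-population variance deficits are demonstrated, not modelled.
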