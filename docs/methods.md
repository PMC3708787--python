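# Methods

`sweepscan` implements a four-stage scan for natural selection on phased
biallelic haplotype panels: (1) Weir–Cockerham pairwise F_ST with
chromosome-wide empirical ranking, (2) an island-model F_ST-outlier (FDIST
style) neutrality test, (3) Gabriel-rule haplotype blocks from D′ confidence
intervals, and (4) the long-range-haplotype (EHH/REHH) test with
frequency-binned empirical significance.  A synthetic-data module generates
every statistical structure the pipeline assumes, so the whole analysis can
be exercised and validated without any external download.  This note records
the models, the parameter choices that matter, and the limits of what the
synthetic validation demonstrates.

## Data model

All stages consume a `HaplotypePanel`: a chromosome × site matrix of allele
indices in {0, 1} over biallelic SNPs, two rows per individual (only paired,
fully phased chromosomes are analysed), one population label per row.
Loading is strict — multiallelic sites and sites with missing genotypes are
dropped and counted, while an unphased genotype in a phased VCF is treated as
a format error, since silently dropping it would hide a phasing problem.
Genetic positions come from a HapMap-format map (position, rate in cM/Mb,
cumulative cM), interpolated linearly between map points with the terminal
interval's rate extended beyond the ends.

## Weir–Cockerham F_ST on chromosomes

Because the sampling unit is a phased chromosome, the estimator is the
haploid variance-components form of Weir and Cockerham's theta.  With r
populations, n_i chromosomes and allele frequency p_i:

    n_bar = Σ n_i / r                   p_bar = Σ n_i p_i / Σ n_i
    n_c   = (Σ n_i − Σ n_i² / Σ n_i) / (r − 1)
    s²    = Σ n_i (p_i − p_bar)² / ((r − 1) n_bar)
    b     = n_bar/(n_bar − 1) · (p_bar(1 − p_bar) − s²(r − 1)/r)
    a     = n_bar/n_c · (s² − b/n_bar)
    θ     = a / (a + b)

This is algebraically identical to the one-way ANOVA estimator
(MSP − MSG)/(MSP + (n_c − 1)·MSG) on the 0/1 allele indicators, which the
test suite uses as an independent oracle.  Negative θ is reported as
computed; multi-SNP values combine components as Σa / Σ(a+b).  A diploid
variant using observed heterozygosity is intentionally out of scope: phased
chromosome data carry no within-individual component.  For this reason,
published genotype-level values computed on the same frequencies reproduce
only to about ±0.02.

Empirical significance is a midrank percentile (ties get half weight)
against the chromosome-wide distribution of per-site θ for the same
population pair, with values at or above the 95th percentile flagged.

## FDIST-style outlier test

The neutral null is Wright's island model with d = 100 demes (the classic
FDIST setting), observed through the r sampled populations.  Each neutral
locus is simulated by a structured coalescent on the sampled chromosomes:
within-deme pair coalescence at rate 1 (time in 2N-deme units), per-lineage
migration at rate M/2 with uniform destination among the other d − 1 demes,
and infinite-alleles mutation at rate θ_mut/2 per lineage.  Under infinite
alleles only the most recent mutation above each sample matters, so a
mutation labels its lineage's samples and removes the lineage from the
simulation; no tree is stored, and the whole simulation is an embedded jump
chain (no waiting times are needed).  Allelic classes are collapsed to
biallelic — most frequent allele versus the rest — and He (pooled 2p̄(1−p̄))
and haploid Weir–Cockerham F_ST are computed on the sampled counts.
Monomorphic draws are rejected and redrawn.

Numerical choices:

* **Mutation rate.** θ_mut defaults to 0.02, the low-mutation SNP limit in
  which essentially every accepted locus segregates exactly one mutation —
  the way a SNP arises.  At higher rates many loci are multi-allelic and the
  biallelic collapse pools differentiated alleles, which bends the
  conditional F_ST | He null downward at high He, opposite to the behaviour
  of SNP data; we measured this directly as an inflated two-sided outlier
  rate.  A (low, high) log-uniform range per locus is available for
  microsatellite-like data.
* **Strong-migration shortcut.** For M ≥ 500 the structured event loop is
  replaced by its panmictic limit (pair coalescence rate 1/d, no migration
  events).  At that M the equilibrium F_ST is below ~2·10⁻³ — under the
  calibration tolerance — while the exact loop would spend millions of
  migration events per locus.
* **Calibration.** M is found by bisection on log₁₀ M so that the *median*
  of the simulated F_ST matches the central-90% trimmed mean of the observed
  per-locus values to ±0.005 (common random numbers across evaluations keep
  the objective monotone).  Matching robust locations on both sides is what
  keeps the envelope centred: the simulated per-locus F_ST distribution is
  right-skewed, and matching its raw mean against a trimmed observed mean
  measurably shifts the envelope low and inflates the positive-outlier rate.
* **Conditioning.** P for an observed locus is the midrank fraction of
  simulated F_ST below the observed value among simulated loci with
  |He_sim − He_obs| ≤ 0.025, the bandwidth widening geometrically until at
  least 200 loci match (nearest-200 fallback).  Classifications: positive
  candidate at P ≥ 0.975, balancing candidate at P ≤ 0.025.

On a neutral Balding–Nichols panel (2,000 unlinked SNPs, target F_ST 0.10,
four populations of 50 chromosomes) the calibrated envelope flags ~5% of
loci (measured 4.9–5.4% across panel seeds), consistent with its nominal
two-sided 5% size.

## LD, D′ confidence intervals, and Gabriel blocks

Phased data make two-locus haplotype counts a direct 2×2 tabulation.  D′,
r² and the LOD score (log₁₀ likelihood ratio of the observed haplotype
frequencies against independence, with 0·log 0 = 0) follow the standard
definitions.  The 90% interval on |D′| is a normalized-likelihood
construction: the multinomial likelihood of the observed counts is evaluated
on a |D′| grid of step 0.001 with allele frequencies fixed at their observed
values and the sign of D fixed; the 5th and 95th cumulative-mass points are
the bounds.  The log-likelihood is concave in D′, so the production kernel
evaluates the grid outward from the mode and truncates 45 nats below it
(weights < 3·10⁻²⁰; results are identical to the full-grid reference, which
is kept and cross-checked in the tests).

Blocks follow the Gabriel rule with fixed thresholds: a pair is strong LD
iff CI = (ci_low ≥ 0.70, ci_high ≥ 0.98), strong recombination iff
ci_high < 0.90, else inconclusive; a candidate span must have a strong-LD
outermost pair and ≥ 95% strong-LD among its informative pairs; candidates
are accepted greedily by decreasing physical length without overlap.
Markers below MAF 0.05 are excluded from the analysed sequence.  Candidate
spans are bounded by `max_span_bp` (default 200 kb, disable with `None`):
the bound is computational — the search is otherwise quadratic in markers —
and sits about twice above the longest empirically reported Gabriel blocks
(~100 kb), so it does not constrain realistic blocks.  Haploview's
marker-count-dependent fraction adjustments are not reproduced.

## EHH and REHH

For a core haplotype (a distinct allele string over a contiguous core
region) with c ≥ 2 carriers, EHH at boundary x is the probability that two
random carriers are identical at every marker strictly between the core edge
and x inclusive: Σ_g C(e_g, 2) / C(c, 2) over the identity classes e_g.
REHH divides the target's EHH by the pooled homozygosity of all other
enumerated core haplotypes at the same locus,
Σ_j Σ_g C(e_gj, 2) / Σ_j C(c_j, 2), cancelling local recombination-rate
variation.  Evaluation is at the first marker whose genetic distance from
the core edge reaches the target (default 0.25 cM); if no marker reaches it
the record is undefined rather than truncated.  Core haplotypes below
frequency 0.05 are excluded and do not contribute to the "others" pool.

The chromosome-wide scan computes REHH in both directions for every core
haplotype of every block (plus any user-specified core regions, for loci
whose blocks do not span the markers of interest), assigns records to 20
frequency bins of width 0.05 (frequency 1.0 → top bin), and ranks log REHH
within each bin by midrank percentile, pooling directions.  Records at or
above the 95th percentile are flagged, the 99th highlighted.  Undefined and
infinite REHH values are reported but excluded from ranking.  For scanning a
candidate region against an external null — e.g. whole-chromosome bins, or
neutral simulations — `bin_reference`/`rank_against_reference` rank records
against reference bins built from another scan.

## Synthetic data

Two generators cover the pipeline's assumptions.

**Unlinked differentiated SNPs** (Balding–Nichols): per site, an ancestral
frequency p₀ ~ Uniform(0.05, 0.95); deme frequencies
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with F the target F_ST; chromosomes as
independent Bernoulli draws.  The multilocus ratio-of-sums θ lands within
±0.02 of the target at the default scale.  (The *median* of per-site θ
ratios sits below the target — the ratio distribution is right-skewed — so
calibration targets should use the mean or ratio-of-sums.)

**Planted sweeps**: a forward-time haploid Wright–Fisher simulation with
recombination.  The founding generation is a mosaic-copying process over 20
founder haplotypes with segment lengths ~ Exponential(mean 0.05 cM ≈ 50 kb
at 1 cM/Mb) and per-site founder allele frequencies ~ Uniform(0.05, 0.95):
the short segments put background haplotype sharing at the scale of
empirical LD blocks (tens of kb), and the broad founder spectrum gives the
panel a realistic site-frequency range, including the low-MAF sites that
populate the high-frequency core-haplotype bins.  Each generation samples
parents in proportion to fitness 1 + s (sweep-allele carriers, in the
selected deme only), recombines with crossovers placed as a Poisson process
on the genetic map, and exchanges migrant chromosomes pairwise between demes
(size-conserving, probability m per chromosome per generation).  The sweep
allele is seeded as a *single-origin* haplotype: all f₀N initial carriers
are copies of one chromosome, as for a young mutation that has escaped early
loss — this is what produces one long high-frequency haplotype under
selection; seeding on independent backgrounds produces none.  If the allele
is lost the simulation restarts with the next derived seed.  Defaults
(2 demes of N = 1,000 chromosomes, 2,000 sites over 5 Mb at 1 cM/Mb —
HapMap-like density of one SNP per 2.5 kb — m = 0.01, s = 0.1, f₀ = 0.05,
200 generations, 200 sampled chromosomes per deme) run in a few seconds.

**What the synthetic panels do and do not show.**  The panels reproduce the
statistical structures the methods rely on — island-model differentiation
with a tunable F_ST, block-like background LD, a genetic map, and a
hitchhiked high-frequency haplotype — but their genealogy is shallow: 20
founders plus 200 generations of drift at N = 1,000, versus ~4N_e ≈ 40,000
generations in a real panel.  Consequently small core haplotypes tend to be
recent clonal families with long shared flanks, and background EHH at
0.25 cM (~0.1–0.3) is higher than in human data.  Two practical
consequences, reflected in the validation protocol:

* With s = 0.1 over a 5 cM region, the hitchhiking footprint
  (roughly s/ln(2Ns) ≈ 2 cM) covers the entire simulated chromosome, so the
  sweep panel's own frequency bins contain mostly the swept haplotype itself
  and cannot serve as a neutral reference.  The validation therefore ranks
  the sweep core against bins built from matched neutral panels — the
  desk-scale stand-in for the whole-chromosome empirical reference a real
  scan uses.  The within-panel percentile remains the scan's semantics for
  real data, where the chromosome dwarfs any single sweep's footprint.
* After 200 generations the sweep is complete in the selected deme
  (frequency ≈ 1, leaving no "other" core haplotypes, hence no REHH), so
  recovery is assessed in the unselected deme, where the sweep arrives by
  migration and is still segregating — mirroring the empirical situation in
  which the long-haplotype signal is found in populations where the swept
  haplotype is at intermediate frequency.  Sweeps that happen to fix in both
  demes are genuinely undetectable by REHH; at the default parameters this
  affects roughly 2–3 replicates in 20.

## Determinism

Every stochastic component takes a single seed; batch and replicate streams
are derived with `numpy.random.SeedSequence`, and the coalescent kernel
seeds its own generator, so repeated runs with the same configuration
produce byte-identical outputs (the pipeline log contains no wall-clock
information).  The coalescent and the LD kernels are numba-compiled; their
results do not depend on compilation caching.

## Known limitations

* The FDIST stage models symmetric islands of equal size; bottlenecks,
  expansions and admixture (all present in real population panels) widen the
  true null beyond the simulated envelope, so P values on real data are
  approximate — the classifications, not the digits, are the robust output.
* The D′ confidence interval fixes allele frequencies at their observed
  values (profile rather than joint likelihood), the standard construction
  for block building but slightly anticonservative at small counts.
* EHH evaluation is at marker boundaries only; between-marker interpolation
  is not attempted.
* The forward simulator has no mutation during the simulated generations
  and haploid (genic) selection only.
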