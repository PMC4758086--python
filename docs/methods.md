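# Methods

## Scope and model

`poolscan` analyses pooled-sequencing (pool-seq) read counts for biallelic
SNPs across several populations, with one pool per population. Allele
frequencies are read-count ratios: for a pool with `ref` and `alt` reads at
a site, `p̂ = alt / (ref + alt)`. No genotype-likelihood model is used; the
read ratio is treated as a direct estimate of the pool's allele frequency.
This is appropriate for deep, equimolar pools and is the estimator whose
behavior the synthetic-data generator emulates.

### Site filters

Four rules define the analysis-ready set, mirroring standard pool-seq SNP
hygiene: a per-pool depth cap (default 200, against collapsed duplicated
regions; a union-depth cap mode is provided since either reading is
defensible), a minimum union depth over all pools (default 60), a minimum
number of variant-supporting reads in the union (default 10), and an
autosome whitelist (default "1".."29"/"chr1".."chr29", the goat autosomes;
anything else counts as X/unplaced). The surviving set is order-independent;
only the report's attribution of a removal to "the first failing rule"
depends on the documented rule order. A stricter subset — every pool at
depth ≥ 30 — feeds the differentiation scan, reducing frequency-estimation
noise at thin sites.

### Differentiation statistics

Per site, with per-population alternate frequencies `p_i`:

    Hs  = mean_i 2 p_i (1 - p_i)
    Ht  = 2 p̄ (1 - p̄),  p̄ = unweighted mean of p_i
    Fst = (Ht - Hs) / Ht        (undefined when Ht = 0)

Population means are unweighted and uncorrected for sample size: pool
frequencies are treated as parametric. The genome-wide mean Fst is the
per-site average over sites with Ht > 0; the ratio-of-means variant
`(ΣHt − ΣHs)/ΣHt` is also reported because the two differ (Jensen) and
which one a given study used is often unstated.

Per-population diversity is summarized by P, the fraction of sites with at
least one read supporting each allele in that pool (the support threshold is
configurable; one read is the weakest defensible definition), and H, the
mean of `2p(1−p)` over sites with a defined frequency (`2p(1−p)` is
symmetric in the allele labels, so using the major-allele frequency is
equivalent).

### Neutral null for Fst

The null asks how much per-site Fst pure drift would generate. A base
population segregates a biallelic locus at frequency `p0` and splits into
`s` subpopulations of effective size `Ne`; each drifts `t` generations,
resampling `2Ne` genes binomially per generation. The expected divergence
is `Fst(t) = 1 − (1 − 1/(2Ne))^t`; with the defaults `Ne = 2749, t = 300`
this is 0.0531, matching the empirical genome-wide mean the design targets.
`solve_generations` inverts the closed form for the smallest `t` reaching a
target.

After drift, `k` alleles are sampled from each subpopulation and per-locus
Fst is computed from the *sample* frequencies. The default `k` values are
twice the pooled sample sizes of the six-population design
(120, 136, 90, 116, 78, 120 alleles), so the null carries the same sampling
variance as data from pools of those sizes. This choice matters: with no
post-drift sampling the mean of per-locus Fst ratios is ≈ 0.044 at the
default parameters (mean-of-ratios lies below the ratio-of-means that the
closed form describes), and ≈ 67% of loci fall below 0.05; with study-sized
sampling the distribution has mean ≈ 0.051, ≈ 57% of loci below 0.05,
≈ 0.4–0.5% above 0.1723 and a maximum near 0.3 — the operating
characteristics the scan thresholds are calibrated against. `sampling=None`
and fixed-`k` modes are kept for sensitivity analysis. Loci monomorphic
across all samples (Ht = 0) are excluded from the distribution and counted.

The residual ≈ 0.002 gap between the simulated mean and the closed form is
the expected mean-of-ratios bias net of sampling inflation; it is a property
of averaging per-locus Fst ratios, not an implementation artifact (the
ratio-of-means of the same simulation recovers the closed form closely).

The observed-versus-null excess test is a one-sided binomial test of the
observed exceedance count at the null exceedance probability — a
reconstruction, labeled as such, since published excess tests are often
unnamed.

Top-quantile thresholding retains `ceil(n · fraction)` members; the cutoff
is the smallest retained value and ties at the cutoff are all retained (the
retained count is reported separately from the target count).

### Highland-versus-lowland scan

The di statistic standardizes each highland×lowland pairwise Fst by that
pair's genome-wide moments (s.d. with the n−1 denominator) and sums over all
pairs — eight for the 2×4 design. A pair with undefined Fst at a SNP
contributes zero and decrements the recorded pair count, rather than
discarding a SNP that is informative elsewhere. A per-focal-population
variant (`di_<pop>` columns) is available.

The chi-square test forms a per-SNP 2×2 table of allele counts, combined
highland group versus combined lowland group (Pearson, 1 df, no continuity
correction), with BH-FDR over SNPs. By default each population contributes
*effective alleles* — `round(p̂ · 2n)` of its `2n` pooled chromosomes — not
raw reads: reads pseudo-replicate chromosomes, so raw-read chi-squares grow
linearly with depth at a fixed frequency difference. The reads mode is
retained for comparison. Zero-margin tables score chi2 = 0, p = 1, flagged.

Outlier flags: `global_outlier` = top 2.5% of the empirical global-Fst
distribution; `di_outlier` = di > 13.5 (strict); `chi2_outlier` = q < 0.01
(strict, matching "FDR-adjusted p < 0.01"); the high-lowland set is the
di ∩ chi2 conjunction and `common` additionally intersects the global set.

### Trees

Population distances from allele frequencies: Nei's Da (default; bounded,
recommended for frequency data and close populations) or Nei's standard D.
Loci missing in either population are excluded pairwise. Trees are built by
canonical neighbor-joining, implemented here directly so the contracts are
explicit: Q-criterion ties break by lexicographic pair order, and negative
branch lengths are clamped to zero after construction (counted and logged,
not redistributed). On additive matrices the output reproduces the input
path lengths exactly; an independent NJ implementation is used as a
cross-check in the test suite.

### Annotation

SNP positions are 1-based; gene intervals are BED (0-based half-open). A
SNP at position P overlaps [start, end) iff start < P ≤ end. A SNP
overlapping several genes counts toward each; per-gene summaries therefore
sum to at least the number of genic SNPs. Placeholder gene symbols can be
excluded by an id list.

## Synthetic data generator

The generator produces the statistical structure the pipeline assumes, with
ground-truth labels:

- **Design**: six populations, two highland (pools of 60 and 68 diploids at
  4,700/4,500 m) and four lowland (45, 58, 39, 60 diploids), matching the
  study design the package is organized around.
- **Ancestral frequencies**: alternate-allele frequency drawn from a 1/q
  density truncated to [0.015, 0.5] — a folded neutral spectrum with an
  ascertainment floor — calibrated so the mean major-allele frequency is
  0.8619. A fixed starting frequency is supported but gives too little
  between-locus variance for realistic estimation-concordance behavior.
- **Drift and selection**: each population drifts independently
  (`Ne = 2749`, `t = 300` by default, expected Fst ≈ 0.053). A configured
  fraction of loci experiences genic selection in highland populations only,
  `q' = q(1+s)/(1+qs)` applied deterministically each generation before
  resampling, always favoring the alternate allele — an unambiguous truth
  label mirroring a derived allele enriched with altitude.
- **Sampling and reads**: pool frequency = frequency among `2n` sampled
  alleles; per-pool depth = Poisson(mean × gamma(shape 30) locus factor),
  mean 120× spanning roughly 80–160×; alternate reads binomial at the pool
  frequency.
- **Ascertainment**: loci with fewer than 10 alternate reads in the union of
  pools are dropped by default — a real count table only contains sites
  that were detectable as SNPs in these same pools. Disable with
  `ascertainment_min_alt_reads=0`. The returned table may hold fewer than
  `n_loci` records.
- **Determinism**: one `numpy` generator seeded from the config; draw order
  is ancestral frequencies → per-generation drift → pool sampling → depth →
  reads. Seeds are portable across platforms at the level of summary
  statistics.

What the generator does **not** model: linkage between loci, demographic
events (bottlenecks, migration, expansion), base-calling error, reference
bias, unequal individual contributions within a pool, or indels/multiallelic
sites. Tests passing on this generator therefore demonstrate correctness of
the statistics and the scan's operating characteristics under the stated
model — not robustness to those real-data complications.

## Problem sizes and numerical choices

The test suite simulates 20,000-locus datasets (a scale at which the
neutral-null summaries are stable to ±0.001 or better) and the acceptance
script runs the null at the full 57,948 loci; both complete in seconds
because drift is vectorized across loci (one binomial draw per population
per generation). Monomorphic sites propagate as NaN and are excluded from
means; per-site Fst requires at least two non-missing populations.
`expected_fst` inversion guards the log-space solution with an integer
scan so the returned `t` is exactly the smallest satisfying value. BH-FDR
uses the standard step-up with capping at 1. Chi-square p-values come from
the 1-df survival function; the statistic itself is the closed-form 2×2
expression, oracle-checked against a generic contingency-table routine.

## Known limitations

- Pool frequencies are maximum-likelihood read ratios without shrinkage;
  at low depth the Fst estimates are noisy, which is why the scan operates
  on the min-coverage subset.
- The neutral null assumes independent loci and equal `Ne` across
  subpopulations with no migration or mutation during drift.
- The di and chi-square analyses share the same underlying frequencies, so
  their conjunction is not an independent replication, only a robustness
  filter — the global-Fst gate is what bounds the false-positive rate.
- Gene annotation is interval overlap only; consequence classes
  (exon/intron/UTR) require a transcript model and are out of scope.
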