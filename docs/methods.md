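# Methods

## The scan statistic

For a window of L callable sites the scan computes

- theta = (Σ 2 p_i (1 − p_i)) / L · n/(n − 1), with p_i the
  alternate-allele frequency among the 2F chromosomes of the F focal
  diploids (n = 2F). Per site this equals 2k(n − k)/(n(n − 1)) for k
  derived alleles — the unbiased mean pairwise difference, so windowed
  theta estimates nucleotide diversity π.
- D = (Σ X_i + 0.5 Y_i) / L for the designated divergence sample, where
  X_i indicates a homozygous-derived genotype and Y_i a heterozygous one.
  X_i is a per-site indicator (homozygous-derived contributes 1, not 2),
  which keeps D a per-site probability on the same [0, 1] scale as theta;
  a `divergence_mode="alleles"` switch makes homozygotes count 2 for users
  who prefer the allele-count reading.
- ratio = theta/D, undefined when D = 0. Zero-divergence windows are the
  anti-sweep extreme: they are reported with a `zero_divergence` flag but
  excluded from ranking, since the candidate set is the low tail only.

The reference allele is treated as ancestral for both p and D. This is the
working polarization when a focal cohort is mapped to an outgroup
reference genome; it is wrong at sites where the reference lineage itself
derived, a known limitation of reference-polarized scans.

Empirical p-values are lower-tail ranks: p_i = #{j : ratio_j ≤ ratio_i}/N
over the N windows with a defined ratio. Ties share a p; the denominator
is N (not N + 1), so the minimum attainable p is 1/N — with fewer than 100
ranked windows a threshold of p < 0.01 is unreachable by construction.

## Windows

Windows are [s, s + W) for s = 0, step, 2·step, … and are emitted only
when they fit on the chromosome; partial trailing windows are dropped so L
is comparable across windows and the minimum-callable rule is meaningful.
The default is W = step = 100 kb (non-overlapping); any 0 < step ≤ W is
supported, and window length is fully configurable (the demonstration
analyses use 10–25 kb windows where a finer grain helps). Windows with
L < 10 kb callable are discarded.

## The filter stack

A site is callable only if, for every relevant sample (focal cohort plus
divergence sample): the genotype is present; depth is ≥ 3 and ≤ that
sample's ceiling; GQ ≥ 20; and, for variant records only, QUAL ≥ 50 and
the record is biallelic. Checks run in that order and the first violated
rule is tallied, so filter exercise is auditable per class. Monomorphic
records in an all-sites VCF typically carry no QUAL, so the QUAL rule is
restricted to variant records — otherwise an all-sites scan would discard
every invariant position. Multi-allelic records are excluded whole, not
decomposed. Indel and symbolic-allele records are skipped at read time
with a count.

The depth ceiling is per-sample: the nearest-rank 95th percentile
(⌈qN⌉-th order statistic) of that sample's genome-wide depth distribution,
computed in a first pass over the VCF. Per-sample ceilings generalize a
single dataset-wide cutoff conservatively, since coverage differs between
libraries; the method and the computed ceilings are recorded in the run
manifest.

GC filtering is window-level: each window's reference GC fraction
(N bases excluded) is compared against the nearest-rank quantile (default
0.95) of the GC values across windows, and windows strictly above the
cutoff are flagged `high_gc` and dropped. No per-site GC rule exists
because GC-driven artifact (mapping and calling bias in GC-rich repeats)
is a regional property; the quantile is configurable and the realized
cutoff is logged. Note the quantile definition means roughly the top 5%
of windows are always removed once GC varies; set the quantile to 1 − ε
or omit the reference to disable the filter.

A variant-only VCF plus a callable-mask BED is accepted as an alternative
to an all-sites VCF: masked positions without a variant record are
synthesized as homozygous-reference sites that bypass the stack (the mask
asserts callability).

## Synthetic cohorts

The generator emulates a reference-mapped cohort of F focal diploids
(default 4) plus a separate divergence sample, per site and independently:

- A position is segregating with probability s = π₀·H_{n−1}
  (π₀ = `pi_background`, default 10⁻³; H the harmonic number), with
  derived-allele count k drawn from the neutral spectrum P(k) ∝ 1/k and
  the k alleles assigned uniformly to the 2F chromosomes (fixed pairing:
  chromosomes 2i, 2i+1 form individual i). Since the mean of
  2k(n−k)/(n(n−1)) under the 1/k spectrum is exactly 1/H_{n−1}, windowed
  theta is an unbiased estimator of π₀ — the closed form behind the
  parameter-recovery tests.
- Otherwise the divergence sample is derived with probability
  `divergence_rate` (default 2×10⁻³), heterozygous with probability
  `het_fraction_of_divergence` (default 0.2, mimicking segregating
  variation in the divergence lineage), giving E[D] = d·(1 − 0.5·h).
  Divergence sites are disjoint from segregating sites (segregating wins
  on collision, a relative bias in E[D] of s ≈ 0.3% at defaults, well
  inside test tolerances). The divergence sample is a separate genome
  rather than one of the focal samples: placing heterozygous divergence
  inside the cohort would force 0 < p < 1 at those sites and bias theta
  upward by ~d·h/4, destroying the exact oracles the tests rely on. The
  scan itself accepts any divergence sample, including a focal one.
- Sweeps are intervals in which s is multiplied by a diversity factor in
  [0, 1] — the footprint of linked selection without modelling haplotypes.
- Artifact sites (rates per class, default 0) are constructed to fail
  exactly one filter: a sample at depth < 3, a GQ < 20, a variant with
  QUAL < 50, a missing genotype, or a triallelic record.
- Clean depths are Poisson(20) clipped to [3, 27]; 27 is the nearest-rank
  95th percentile of Poisson(20), so the ceiling computed from the
  simulated distribution is 27 and depth failures come only from injected
  artifacts, keeping the filter tally interpretable.
- The reference is i.i.d. with 40% GC, optionally with a high-GC tract.

Sites are independent — no linkage, no coalescent trees. The statistic is
a per-site sum, so LD does not affect its correctness, and independence
yields closed-form expectations; but this means passing tests say nothing
about the variance inflation and window-to-window autocorrelation real
linkage produces, about reference bias, mapping error, or indels. One
integer seed fixes all output byte-for-byte; the reference, the site
draws, the artifact payloads and the depth/quality streams use separate
child seeds so lazy generation cannot reorder draws.

Large simulations are scanned through a vectorized path over the sparse
site arrays (`scan_positions`), proven equal to the record-by-record path
on mixed fixtures to 10⁻¹² in the test suite. Test and acceptance scales —
10 Mb backgrounds, 100-replicate power runs, 2 Mb unit fixtures — were
chosen so the statistical checks have the window counts they need (100 to
1,000 windows) while the whole suite stays fast.

## Annotation

A gene is a candidate if its interval overlaps (≥ 1 bp, half-open) any
window with empirical p < α (default 0.01). Any-overlap rather than
containment: genes longer than the window could never be contained.
Flanking divergence counts whole homozygous-derived sites (no 0.5
weighting) among callable sites of an explicit region — an integer count
of fixed differences, the quantity used to judge whether a candidate
region is compatible with recent shared ancestry. The flank width is a
parameter, not a default.

## Demographic utilities

Neutral loci are dropped when strictly more than 10% of genotypes are
missing (boundary loci retained). Missingness percentages round half-up
to one decimal. Calibration: Ne = θ/(4μ), years = (τ/μ)·g, total
migration = m × band duration, flagged "major" strictly above 0.05, with
μ = 4×10⁻⁹ per site per generation and g = 3 years as defaults.
Posterior tables are summarized as means with equal-tailed 95% intervals
(2.5/97.5 percentiles); highest-posterior-density intervals are not
implemented. The coalescent sampler itself is out of scope — traces
arrive as headered TSVs.

## Numerical notes

- Internal coordinates are 0-based half-open everywhere; conversion
  happens only at the VCF (1-based) and GFF3 (1-based inclusive) borders.
- Window tables serialize floats with `repr` so round-trips are exact;
  missing values are "NA".
- The Spearman diagnostic returns 0 with a warning when ratio or L is
  constant (rank correlation is undefined there), and refuses fewer than
  three points.
- Depth percentile, GC quantile and empirical p all use nearest-rank
  definitions — no interpolation — so results are reproducible integers
  or exact ratios.
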