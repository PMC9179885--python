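# Methods

## Genotype representation and I/O

Genotypes are dosage-coded: for each biallelic SNP a *counted allele*
is fixed and every genotype stores the number of its copies (0/1/2),
with a reserved sentinel (−1) for missing calls so a missing genotype
can never be confused with an other-allele homozygote. PLINK text
(PED/MAP) and PLINK 1.9 binary (BED/BIM/FAM, SNP-major) are read and
written natively. The PED format carries no allele metadata, so the
reader fixes the counted allele as the first non-missing allele in
file order; `harmonize_counted_alleles` recodes a re-read dataset
onto a reference coding when exact round-tripping matters. Positions
are 1-based as in MAP/BIM. Half-called genotypes ("A 0") are treated
as missing, following PLINK.

When merging datasets from different chip versions, only shared
markers are kept. Counted/other allele swaps are reconciled by
recoding dosages g → 2 − g; A/T and C/G markers whose allele pairs
are not written identically in both datasets are dropped, because a
swap cannot be distinguished from a strand flip for those pairs; any
other disagreement drops the marker as irreconcilable. No strand
flipping is ever attempted — this is the conservative convention used
by most merging pipelines. Every decision is recorded in a TSV merge
report.

## Quality control

Three filters run in a fixed order: samples with call rate below
0.95, then SNPs with call rate below 0.95 (recomputed on retained
samples), then SNPs departing from Hardy–Weinberg equilibrium. The
HWE test is the two-sided exact conditional test on the heterozygote
count (no mid-p), computed by the standard stable recurrence around
the distribution's mode; a chi-square variant is available as a
configuration alternative. The Bonferroni denominator is the number
of SNPs actually tested at stage three, i.e. after the call-rate
filters — the natural choice when the testing family is defined by
the surviving markers. The HWE scope defaults to all samples but is
normally restricted to the focal population (the one genotyped fresh
on the newer chip), since pooling differentiated populations induces
Wahlund-effect heterozygote deficits that would discard exactly the
most informative markers. No minor-allele-frequency filter exists:
rare and near-private alleles are retained deliberately.

Numerical note: the exact test sums all heterozygote configurations
whose conditional probability is ≤ the observed one; a relative guard
of 1e−9 on that comparison makes the inclusion decision robust to
floating-point rounding of exactly tied configurations. The
implementation agrees with an exact rational-arithmetic enumeration
to < 1e−12 over every configuration with up to 30 individuals.

## Frequencies, delta, IBS and MDS

Per-population counted-allele frequencies are computed from dosages
with missing calls excluded from numerator and denominator; a
population with zero observations at a marker gets an explicit
undefined (NaN) frequency, never a silent zero. The delta statistic
for a pair of populations is |p_i − p_j|; tables are sorted by delta
descending with ties broken by ascending marker name, which makes
every ranking — and therefore every selected panel — reproducible
across platforms. Delta is invariant to which allele is counted.

Identity-by-state similarity between two individuals is the mean of
(2 − |g_a − g_b|)/2 over markers non-missing in both. The distance
transform for embedding is D = 1 − IBS, and classical (Torgerson)
MDS double-centers D² and eigendecomposes; negative eigenvalues are
truncated and, if fewer than the requested dimensions are positive,
fewer columns are returned with a warning. IBS is unweighted (no
frequency weighting). MDS output is used for inspection and for
identifying near-clustering pairs; tests compare inter-point
distances and group separation only, since the embedding is defined
up to sign and rotation.

## Panel selection

A selection scheme is an ordered list of (pair, slot-count) entries.
Pairs are processed in order; each takes its top-delta markers,
skipping markers already selected so that a marker fills exactly one
slot and the panel size always equals the scheme total. The default
core scheme is 3 + 3 + 2 + 1 slots for the focal breed against LR,
LW, WB and DU respectively — fewer slots for the comparisons that MDS
shows to be easy. "MDS-guided" slots are operationalized as delta
ranking pooled over the near-clustering pairs (default LR–LW, 3
slots); the augmentation stage appends 8 between-breed slots, by
default weighted toward LR–LW (3) with one slot for each of the five
remaining non-focal pairs. The augmentation weighting was a genuinely
open design point; weighting the hardest pair most heavily follows
the observation that assignment errors concentrate there. All three
stages are fully configurable.

## Cohort simulation

Purebred genotypes are drawn as Binomial(2, p_pop) per locus; F1
hybrids as the sum of one Bernoulli(p_A) and one Bernoulli(p_B)
allele. Frequency-parametric draws are used rather than resampling a
finite observed allele pool: resampling **with replacement** from a
pool with empirical frequency p̂ is distributionally identical to
Bernoulli(p̂), so a separate pool-resampling mode would add a flag
without adding behaviour. Loci are independent (linkage
equilibrium), justified for reduced panels whose markers are spread
across many chromosomes; this is also why simulated cohorts carry no
missing calls. The crossing plan defaults to all 10 pairs of the five
populations with 20 F1s per crossing for training and 10 for
validation, and 40 simulated purebreds per breed — yielding 200
training hybrids, 100 validation hybrids and 200 validation
purebreds. All randomness flows from one integer seed through a
splittable seed sequence; per-cohort seeds are recorded in the
provenance table.

## Discriminant assignment

The classifier is classical multi-class linear discriminant analysis:
class means, pooled within-class covariance S_W (divisor n − c),
priors proportional to training class frequencies by default (an
equal-priors mode exists because the hybrid training class is much
larger than any single breed), and posteriors from the
shared-covariance Gaussian rule computed in log space with a Cholesky
solve. Canonical axes solve the generalized eigenproblem of the
between- versus within-class scatter and are kept for plotting;
classification uses the full Gaussian rule, which is equivalent to
projecting on all c − 1 canonical axes. Posterior ties break toward
the lexicographically smallest class label. A singular S_W (e.g. a
panel marker that is monomorphic in a small synthetic run) raises an
error advising the relative ridge option, which adds
ridge × mean(diag S_W) to the diagonal.

The hybrid threshold rule reassigns any individual whose maximum
posterior falls below τ (default 0.65) to the hybrid class HY;
individuals already called HY are untouched, so raising τ can only
move individuals into HY — hybrid recall is monotonically
non-decreasing in τ by construction. Summaries report, per true
class, correct counts and rates before and after thresholding, the
mean and minimum posterior on the true class (the posterior on the
*assigned* class is in the per-individual table; the two notions
differ for misassigned individuals and are labeled distinctly), and
the destinations of wrong calls.

## Synthetic studies

The generator emulates the motivating study's shape: five
populations of sizes {NS: 93, LW: 44, LR: 37, DU: 44, WB: 88} (306
individuals), biallelic SNPs with ancestral frequencies uniform on
[0.05, 0.95], Balding–Nichols population frequencies
p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.2 by default
(optionally per-population, e.g. larger for wild boar), genotypes in
Hardy–Weinberg and linkage equilibrium, and 1.5% MCAR missing calls
(≈ 98.5% mean call rate). F = 0 is handled exactly as p_pop = p. The
default marker count is 5,000 — enough for the delta ranking to find
near-fixed differences at F = 0.2 while keeping a full pipeline run
in seconds; chip scale (~43,700 markers) is a configuration change,
not a code change.

What the generator does *not* emulate: linkage disequilibrium and
realistic recombination maps, ascertainment bias of chip design
(which depresses informativeness for breeds absent from the SNP
discovery panel), relatedness structure within breeds, and
non-random missingness. Consequently, passing end-to-end tests shows
the pipeline's statistical machinery is correct under its stated
model, not that a particular real breed is separable with 20 markers
at any particular accuracy; with real data the delta ranking operates
on correlated markers and biased frequency estimates, and panel
performance must be validated on held-out genotypes.

## Problem sizes used in the test suite

The shipped tests run the full pipeline at 306 × 5,000 markers
(F = 0.2, fixed seed), oracle comparisons at 200-marker/5-population
scale, Monte-Carlo checks at n = 10,000 draws, and the
Balding–Nichols variance recovery at 20,000 markers. At those sizes
the whole suite completes in well under a minute. The acceptance
script selects panels on a 500-marker study; panel sizes are
scale-free (they equal the scheme totals whenever enough distinct
informative markers exist, which holds from a few dozen markers up).

## Known limitations

- Only biallelic autosomal-style markers; no VCF, no multi-allelic
  support, no imputation, no assembly liftover.
- Merging never strand-flips; discordant ambiguous markers are lost
  rather than rescued.
- The discriminant model is linear with a shared covariance;
  admixture proportions beyond the binary purebred/F1 distinction
  (backcrosses, F2) are out of scope and would be misassigned to the
  nearest class.
- The threshold rule calibrates confidence against a single fallback
  class; with several hybrid types it cannot say *which* crossing
  produced a low-confidence individual (the provenance tables can,
  for simulated data).
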