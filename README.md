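# breedtrace

Reduced SNP panels and discriminant assignment for livestock breed
traceability.

Meat products from local breeds command premium prices and are easy
targets for substitution or mislabeling, and physical labels do not
survive carcass processing. DNA does. `breedtrace` implements a
complete workflow for turning medium-density SNP-chip genotypes of a
focal local breed and its likely admixture partners (cosmopolitan
breeds, wild boar) into a small, cheap diagnostic marker panel, and
for assigning individuals — including first-generation hybrids — to
their breed of origin. The motivating design is the Nero Siciliano
pig (NS) against Large White (LW), Landrace (LR), Duroc (DU) and wild
boar (WB), but every population label, slot count and threshold is
configurable.

## The method

1. **Quality control.** Samples and SNPs with call rate < 95% are
   removed, then SNPs departing from Hardy–Weinberg equilibrium
   (two-sided exact test on the heterozygote count, *p* < 0.01
   Bonferroni-corrected over the SNPs tested). Rare alleles are kept:
   near-private alleles are the most diagnostic markers.
2. **Marker informativeness.** For each breed pair (i, j) and marker,
   the delta statistic is the absolute counted-allele frequency
   difference, Δ = |p_i − p_j| ∈ [0, 1]; Δ = 1 is a fixed difference.
3. **Panel selection.** A selection scheme assigns each pairwise
   comparison a number of slots filled by its top-Δ markers (a marker
   can fill only one slot; later pairs substitute their next-ranked
   marker). The default scheme takes 3 + 3 + 2 + 1 markers for the
   focal breed's four comparisons, 3 more for the near-clustering
   pair flagged by IBS/MDS (the 12-SNP core), then 8 between-breed
   markers (the 20-SNP final panel).
4. **Cohort simulation.** Purebreds are drawn as dosage ~
   Binomial(2, p_pop); F1 hybrids draw one Bernoulli(p_A) and one
   Bernoulli(p_B) allele per locus. Four cohorts mirror the study
   design: real purebreds with complete panel genotypes (PTP), PTP
   plus 200 simulated hybrids (HTP), 200 simulated purebreds (PVP),
   PVP plus 100 simulated hybrids (HVP).
5. **Assignment.** Canonical discriminant analysis with a shared
   within-class covariance: P(k | x) ∝ π_k exp(−½ (x−μ_k)ᵀ Σ⁻¹ (x−μ_k)).
   A posterior threshold (default 0.65) reassigns low-confidence
   breed calls to the hybrid class HY.

Because real chip genotypes of this kind are rarely public, the
package ships a first-class synthetic-data module: five populations
of sizes {93, 44, 37, 44, 88}, Balding–Nichols differentiation
(p_pop ~ Beta with mean p and variance F·p(1−p)), Hardy–Weinberg and
linkage equilibrium within populations, and MCAR missing calls.

## Worked example

```python
import numpy as np
from breedtrace import *

cfg = SyntheticStudyConfig(n_snps=5000, fst=0.2, seed=2024)
ds, _ = generate_study(cfg)                      # 306 samples x 5000 SNPs
ds_qc, _ = apply_qc(ds, hwe_population="NS")
aft = allele_frequencies(ds_qc)

core = build_core_panel(aft, focal_core_scheme(), [("LR", "LW")], 3)
full = augment_panel(core, aft, default_augmentation_scheme())
print(len(core), len(full))                      # 12 20

plan = paper_crossing_plan(seed=2024)
pops = build_study_populations(ds_qc, aft, plan, full)
model = fit_cda(pops.ptp)
res = predict(model, pops.pvp)
print(np.mean([p == t for p, t in zip(res.predicted, pops.pvp.populations)]))
# 1.0
```

With this seed the 20-SNP panel assigns 100% of the 200 simulated
purebred validation individuals to the correct breed (the 12-SNP core
reaches 98.5%); on the 300-individual hybrid validation cohort the
overall rate is 93.7%, and the 0.65 posterior threshold raises hybrid
recall from 0.86 to 0.89. The selected markers' deltas all exceed
0.87 at F = 0.2.

The same workflow is available from the shell:

```sh
breedtrace pipeline --seed 1 --out run/
```

which writes QC reports, frequency/delta tables, both panels, MDS
coordinates, per-cohort assignment TSVs and an 8-cell (4 cohorts x 2
panels) assignment-rate table, plus a manifest with the config hash
and seed.

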