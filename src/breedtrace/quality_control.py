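"""Genotype quality control: call-rate filters and the exact
Hardy-Weinberg equilibrium test with Bonferroni correction.

The QC chain applies, in order: (1) removal of samples with a call
rate below threshold, (2) removal of SNPs with a call rate below
threshold (recomputed on the retained samples), (3) removal of SNPs
departing from Hardy-Weinberg equilibrium at a Bonferroni-corrected
significance level.  No minor-allele-frequency filter is applied:
rare alleles are deliberately retained, since near-private alleles
are exactly the markers most useful for breed traceability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeDataset, GenotypeError


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds of the three-stage QC chain.

    ``hwe_alpha`` is the nominal significance level; the per-SNP
    threshold after Bonferroni correction is ``hwe_alpha / n_tested``.
    """

    min_sample_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    hwe_alpha: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "min_sample_call_rate",
            "min_snp_call_rate",
            "hwe_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Record of every removal made by :func:`apply_qc`."""

    removed_samples: list[tuple[str, float]] = field(default_factory=list)
    removed_snps: list[tuple[str, str, float]] = field(default_factory=list)
    n_tests_hwe: int = 0
    hwe_threshold_effective: float = float("nan")
    filter_order: tuple[str, ...] = ("sample_call_rate", "snp_call_rate", "hwe")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sample", sid, "call_rate", value)
            for sid, value in self.removed_samples
        ] + [
            ("snp", sid, reason, value)
            for sid, reason, value in self.removed_snps
        ]
        return pd.DataFrame(rows, columns=["entity", "id", "reason", "value"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def call_rates(
    ds: GenotypeDataset, axis: Literal["samples", "snps"] = "samples"
) -> pd.Series:
    """Fraction of non-missing genotypes per sample or per SNP."""
    if axis not in ("samples", "snps"):
        raise ValueError(f"axis must be 'samples' or 'snps', got {axis!r}")
    observed = ds.dosage != MISSING
    if axis == "samples":
        if ds.n_snps == 0:
            raise GenotypeError("cannot compute sample call rates with 0 SNPs")
        return pd.Series(observed.mean(axis=1), index=ds.sample_ids, name="call_rate")
    if ds.n_samples == 0:
        raise GenotypeError("cannot compute SNP call rates with 0 samples")
    return pd.Series(observed.mean(axis=0), index=ds.snp_ids, name="call_rate")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on the heterozygote count.

    Conditional on the observed allele counts, sums the probabilities
    of every heterozygote configuration whose probability does not
    exceed that of the observed one (no mid-p adjustment).  Monomorphic
    configurations return 1.0.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_AA + n_Aa  # copies of one allele
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    probs = _het_count_distribution(n, rare)
    obs = probs.get(n_Aa)
    if obs is None:  # parity violation cannot occur with valid counts
        raise ValueError(f"inconsistent genotype configuration {counts}")
    p = sum(v for v in probs.values() if v <= obs * (1.0 + 1e-9))
    return min(p, 1.0)


def _het_count_distribution(n: int, rare: int) -> dict[int, float]:
    """P(heterozygote count | n diploids, `rare` copies of the rarer
    allele), by the stable two-sided recurrence around the mode."""
    common = 2 * n - rare
    mid = rare * common // (2 * n)
    if (mid - rare) % 2 != 0:
        mid += 1
    probs = {mid: 1.0}
    # downward: h -> h - 2 trades one het pair for a hom-rare + hom-common
    h = mid
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (
            (rare - h + 2) * (common - h + 2)
        )
        h -= 2
    # upward: h -> h + 2
    h = mid
    while h <= rare - 2:
        hom_r = (rare - h) / 2
        hom_c = (common - h) / 2
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 1) * (h + 2))
        h += 2
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit HWE test (config alternative)."""
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    chi2 = float(((np.array(counts) - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def genotype_counts(
    ds: GenotypeDataset, sample_rows: np.ndarray | None = None
) -> np.ndarray:
    """Per-SNP genotype counts (n_hom_counted, n_het, n_hom_other)."""
    dosage = ds.dosage if sample_rows is None else ds.dosage[sample_rows]
    return np.stack(
        [(dosage == 2).sum(axis=0), (dosage == 1).sum(axis=0), (dosage == 0).sum(axis=0)],
        axis=1,
    )


def apply_qc(
    ds: GenotypeDataset,
    thr: QCThresholds = QCThresholds(),
    hwe_population: str | None = None,
    hwe_method: Literal["exact", "chi2"] = "exact",
) -> tuple[GenotypeDataset, QCReport]:
    """Run the three-stage QC chain and report every removal.

    ``hwe_population`` restricts the HWE test to one population's
    samples (the usual choice: the focal breed genotyped on the newer
    chip); by default all samples are pooled.
    """
    if ds.n_samples == 0 or ds.n_snps == 0:
        raise GenotypeError("cannot QC an empty dataset")
    if hwe_population is not None and hwe_population not in ds.population_labels:
        raise KeyError(f"unknown population {hwe_population!r}")
    test = hwe_exact_test if hwe_method == "exact" else hwe_chi2_test
    report = QCReport()

    # stage 1: sample call rate
    cr_samples = call_rates(ds, "samples")
    keep_samples = [
        sid for sid in ds.sample_ids if cr_samples[sid] >= thr.min_sample_call_rate
    ]
    report.removed_samples = [
        (sid, float(cr_samples[sid]))
        for sid in ds.sample_ids
        if sid not in set(keep_samples)
    ]
    if not keep_samples:
        raise GenotypeError("sample call-rate filter removed every sample")
    ds = ds.subset(sample_ids=keep_samples)

    # stage 2: SNP call rate, recomputed on the retained samples
    cr_snps = call_rates(ds, "snps")
    keep_snps = [
        sid for sid in ds.snp_ids if cr_snps[sid] >= thr.min_snp_call_rate
    ]
    dropped = set(ds.snp_ids) - set(keep_snps)
    report.removed_snps += [
        (sid, "call_rate", float(cr_snps[sid])) for sid in ds.snp_ids if sid in dropped
    ]
    ds = ds.subset(snp_ids=keep_snps)

    # stage 3: HWE with Bonferroni over the SNPs actually tested
    if hwe_population is None:
        rows = None
    else:
        rows = np.array(
            [i for i, s in enumerate(ds.samples) if s.population == hwe_population],
            dtype=np.intp,
        )
    counts = genotype_counts(ds, rows)
    testable = counts.sum(axis=1) >= 1
    n_tests = int(testable.sum())
    report.n_tests_hwe = n_tests
    if n_tests > 0:
        threshold = thr.hwe_alpha / n_tests
        report.hwe_threshold_effective = threshold
        keep_snps = []
        for j, sid in enumerate(ds.snp_ids):
            if not testable[j]:
                keep_snps.append(sid)
                continue
            p = test(*map(int, counts[j]))
            if p < threshold:
                report.removed_snps.append((sid, "hwe", float(p)))
            else:
                keep_snps.append(sid)
        ds = ds.subset(snp_ids=keep_snps)
    return ds, report


def drop_incomplete_samples(ds: GenotypeDataset, panel) -> GenotypeDataset:
    """Keep only samples with zero missing calls across the panel SNPs.

    ``panel`` may be a :class:`~breedtrace.panel_selection.SNPPanel` or a
    plain list of SNP ids; all must exist in ``ds``.
    """
    snp_ids = list(getattr(panel, "snp_ids", panel))
    cols = ds.snp_index(snp_ids)
    complete = (ds.dosage[:, cols] != MISSING).all(axis=1)
    keep = [sid for sid, ok in zip(ds.sample_ids, complete) if ok]
    return ds.subset(sample_ids=keep)
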