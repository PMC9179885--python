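"""Simulation of purebred and first-generation (F1) hybrid genotypes
from population allele frequencies, and assembly of the four
training/validation cohorts used to benchmark breed assignment.

A purebred draws both alleles from its own population's gene pool
(dosage ~ Binomial(2, p)); an F1 hybrid draws one allele from each
parental pool (one Bernoulli(p_A) plus one Bernoulli(p_B) copy), so at
a fixed difference between the parents every F1 is heterozygous.  Loci
are treated as independent (linkage equilibrium), reasonable for a
reduced panel whose markers are spread across many chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, GenotypeError, SampleInfo, SNPMeta, concatenate_samples
from .popgen_stats import AlleleFrequencyTable
from .quality_control import drop_incomplete_samples

#: Truth label given to every simulated F1 individual.
HYBRID_LABEL = "HY"


@dataclass(frozen=True)
class CrossingPlan:
    """The simulated-cohort design.

    Defaults follow the study: every pair among the 5 populations is
    crossed (10 crossings), with 20 F1s per crossing in the hybrid
    training cohort and 10 in the hybrid validation cohort; 40
    simulated purebreds per breed form the purebred validation cohort.
    """

    crossings: tuple[tuple[str, str], ...]
    purebred_pops: tuple[str, ...]
    n_per_cross_training: int = 20
    n_per_cross_validation: int = 10
    n_per_purebred: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b in self.crossings:
            if a == b:
                raise ValueError(f"crossing {a} x {b}: parents must differ")
        for n in (
            self.n_per_cross_training,
            self.n_per_cross_validation,
            self.n_per_purebred,
        ):
            if n < 0:
                raise ValueError("cohort counts must be >= 0")


def paper_crossing_plan(
    pops: Sequence[str] = ("NS", "LW", "LR", "DU", "WB"), seed: int = 0
) -> CrossingPlan:
    """All-pairs crossing plan over the study's five populations."""
    pops = tuple(pops)
    crossings = tuple(
        (pops[i], pops[j])
        for i in range(len(pops))
        for j in range(i + 1, len(pops))
    )
    return CrossingPlan(crossings=crossings, purebred_pops=pops, seed=seed)


@dataclass
class SimulatedCohort:
    """A simulated genotype dataset plus per-sample provenance."""

    dataset: GenotypeDataset
    provenance: pd.DataFrame  # sample_id, type, parent_a, parent_b, seed

    @property
    def n_samples(self) -> int:
        return self.dataset.n_samples


def _frequencies_for(aft: AlleleFrequencyTable, pop: str) -> np.ndarray:
    freqs = aft.population_frequencies(pop).to_numpy(dtype=float)
    if np.isnan(freqs).any():
        bad = [s for s, f in zip(aft.snp_ids, freqs) if np.isnan(f)]
        raise GenotypeError(
            f"population {pop!r} has undefined frequency at SNPs {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )
    return freqs


def _snp_meta(aft: AlleleFrequencyTable) -> list[SNPMeta]:
    if aft.snps is not None:
        return list(aft.snps)
    # frequency-only tables: synthesize placeholder biallelic metadata
    return [
        SNPMeta(snp_id=s, counted_allele="A", other_allele="C")
        for s in aft.snp_ids
    ]


def simulate_purebred(
    aft: AlleleFrequencyTable,
    pop: str,
    n: int,
    seed: int,
    id_prefix: str | None = None,
) -> SimulatedCohort:
    """Draw ``n`` purebred individuals of ``pop`` (HWE, independent loci)."""
    freqs = _frequencies_for(aft, pop)
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8)
    prefix = id_prefix or f"SIM_{pop}"
    samples = [SampleInfo(f"{prefix}_{i:04d}", pop) for i in range(n)]
    prov = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "type": "purebred",
            "parent_a": pop,
            "parent_b": pop,
            "seed": seed,
        }
    )
    return SimulatedCohort(GenotypeDataset(samples, _snp_meta(aft), dosage), prov)


def simulate_f1(
    aft: AlleleFrequencyTable,
    pop_a: str,
    pop_b: str,
    n: int,
    seed: int,
    id_prefix: str | None = None,
    label: str = HYBRID_LABEL,
) -> SimulatedCohort:
    """Draw ``n`` F1 hybrids of ``pop_a`` x ``pop_b``.

    Each individual receives one Bernoulli(p_A) allele and one
    Bernoulli(p_B) allele per locus; the truth label is ``HY``.
    """
    if pop_a == pop_b:
        raise ValueError(
            f"F1 parents must differ (got {pop_a!r} twice); "
            "use simulate_purebred instead"
        )
    fa = _frequencies_for(aft, pop_a)
    fb = _frequencies_for(aft, pop_b)
    rng = np.random.default_rng(seed)
    m = len(fa)
    allele_a = rng.random((n, m)) < fa
    allele_b = rng.random((n, m)) < fb
    dosage = (allele_a.astype(np.int8) + allele_b.astype(np.int8))
    prefix = id_prefix or f"SIM_{pop_a}x{pop_b}"
    samples = [SampleInfo(f"{prefix}_{i:04d}", label) for i in range(n)]
    prov = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "type": "F1",
            "parent_a": pop_a,
            "parent_b": pop_b,
            "seed": seed,
        }
    )
    return SimulatedCohort(GenotypeDataset(samples, _snp_meta(aft), dosage), prov)


@dataclass
class StudyPopulations:
    """The four assignment cohorts.

    PTP: real purebreds with complete panel genotypes (training).
    HTP: PTP plus simulated F1 hybrids (training).
    PVP: simulated purebreds (validation).
    HVP: PVP plus simulated F1 hybrids (validation).
    """

    ptp: GenotypeDataset
    htp: GenotypeDataset
    pvp: GenotypeDataset
    hvp: GenotypeDataset
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("ptp", "htp", "pvp", "hvp"):
            ds: GenotypeDataset = getattr(self, name)
            hy = sum(p == HYBRID_LABEL for p in ds.populations)
            rows.append(
                {
                    "cohort": name.upper(),
                    "n_samples": ds.n_samples,
                    "n_purebred": ds.n_samples - hy,
                    "n_hybrid": hy,
                }
            )
        return pd.DataFrame(rows)


def build_study_populations(
    real: GenotypeDataset,
    aft: AlleleFrequencyTable,
    plan: CrossingPlan,
    panel,
) -> StudyPopulations:
    """Assemble PTP/HTP/PVP/HVP restricted to the panel markers.

    ``real`` provides the purebred training individuals (those with a
    complete panel genotype); ``aft`` provides the frequencies the
    simulated purebreds and hybrids are drawn from.  All randomness
    derives from ``plan.seed`` through a splittable seed sequence.
    """
    snp_ids = list(getattr(panel, "snp_ids", panel))
    real_panel = real.subset(snp_ids=snp_ids)
    ptp = drop_incomplete_samples(real_panel, snp_ids)
    if ptp.n_samples == 0:
        raise GenotypeError(
            "no real individual has a complete panel genotype; PTP is empty"
        )
    aft_panel = aft.restrict(snp_ids)

    n_streams = 2 * len(plan.crossings) + len(plan.purebred_pops)
    children = np.random.SeedSequence(plan.seed).spawn(max(n_streams, 1))
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    it = iter(seeds)

    prov_frames = []
    train_hybrids = []
    for a, b in plan.crossings:
        c = simulate_f1(
            aft_panel, a, b, plan.n_per_cross_training, next(it),
            id_prefix=f"HT_{a}x{b}",
        )
        train_hybrids.append(c.dataset)
        prov_frames.append(c.provenance.assign(cohort="HTP"))
    val_hybrids = []
    for a, b in plan.crossings:
        c = simulate_f1(
            aft_panel, a, b, plan.n_per_cross_validation, next(it),
            id_prefix=f"HV_{a}x{b}",
        )
        val_hybrids.append(c.dataset)
        prov_frames.append(c.provenance.assign(cohort="HVP"))
    val_purebreds = []
    for pop in plan.purebred_pops:
        c = simulate_purebred(
            aft_panel, pop, plan.n_per_purebred, next(it), id_prefix=f"PV_{pop}"
        )
        val_purebreds.append(c.dataset)
        prov_frames.append(c.provenance.assign(cohort="PVP"))

    htp = concatenate_samples(ptp, *train_hybrids)
    pvp = (
        concatenate_samples(*val_purebreds)
        if val_purebreds
        else ptp.subset(sample_ids=[])
    )
    hvp = concatenate_samples(pvp, *val_hybrids)
    prov = (
        pd.concat(prov_frames, ignore_index=True)
        if prov_frames
        else pd.DataFrame()
    )
    return StudyPopulations(ptp=ptp, htp=htp, pvp=pvp, hvp=hvp, provenance=prov)
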