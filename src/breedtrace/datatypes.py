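"""Core containers for diploid biallelic SNP genotype data.

Genotypes are stored as *dosages*: for each SNP a designated
``counted_allele`` is chosen and every genotype is the number of copies
(0, 1 or 2) of that allele carried by the individual.  Missing calls are
the reserved sentinel :data:`MISSING` (never 0, so a missing call can
never be confused with a homozygote for the other allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Reserved dosage sentinel for a missing genotype call.
MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT0")


class GenotypeError(ValueError):
    """Base class for genotype-data contract violations."""


class PlinkFormatError(GenotypeError):
    """A PLINK-format file is malformed."""


class DuplicateMarkerError(GenotypeError):
    """The same marker name occurs more than once in one dataset."""


class EmptyIntersectionError(GenotypeError):
    """Two datasets being merged share no markers."""


@dataclass(frozen=True)
class SNPMeta:
    """Metadata for one biallelic marker.

    Parameters
    ----------
    snp_id
        Chip marker name; unique within a dataset.
    chromosome
        Chromosome label as a string ("0" for unplaced markers).
    position
        1-based base-pair position; 0 for unplaced markers.
    counted_allele
        The allele whose copy number the dosage records.
    other_allele
        The second allele; the placeholder "0" when the marker is
        monomorphic and the second allele has never been observed.
    rs_id
        Optional dbSNP accession.
    """

    snp_id: str
    chromosome: str = "0"
    position: int = 0
    counted_allele: str = "0"
    other_allele: str = "0"
    rs_id: str | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise GenotypeError("snp_id must be non-empty")
        if self.position < 0:
            raise GenotypeError(f"{self.snp_id}: position must be >= 0")
        for allele in (self.counted_allele, self.other_allele):
            if allele not in _VALID_ALLELES:
                raise GenotypeError(
                    f"{self.snp_id}: allele {allele!r} not in A/C/G/T "
                    "or the missing placeholder '0'"
                )
        if self.counted_allele != "0" and self.counted_allele == self.other_allele:
            raise GenotypeError(
                f"{self.snp_id}: counted and other allele are both "
                f"{self.counted_allele!r}"
            )

    @property
    def allele_pair(self) -> frozenset[str]:
        return frozenset((self.counted_allele, self.other_allele))

    @property
    def strand_ambiguous(self) -> bool:
        """A/T and C/G pairs read identically on both strands."""
        return self.allele_pair in (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class SampleInfo:
    """One genotyped individual and its population label."""

    sample_id: str
    population: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise GenotypeError("sample_id must be non-empty")
        if not self.population:
            raise GenotypeError(f"{self.sample_id}: population must be non-empty")


class GenotypeDataset:
    """An ordered samples x SNPs dosage matrix with metadata.

    ``dosage[i, j]`` is the number of copies of SNP ``j``'s counted
    allele carried by sample ``i`` (0, 1, 2) or :data:`MISSING`.
    Empty datasets (zero samples and/or zero SNPs) are representable.
    """

    def __init__(
        self,
        samples: Sequence[SampleInfo],
        snps: Sequence[SNPMeta],
        dosage: np.ndarray,
    ) -> None:
        self.samples: list[SampleInfo] = list(samples)
        self.snps: list[SNPMeta] = list(snps)
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.size == 0:
            dosage = dosage.reshape(len(self.samples), len(self.snps))
        if dosage.shape != (len(self.samples), len(self.snps)):
            raise GenotypeError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid dosage {dosage[i, j]} at sample {i}, snp {j}"
            )
        seen: set[str] = set()
        for snp in self.snps:
            if snp.snp_id in seen:
                raise DuplicateMarkerError(f"duplicate marker {snp.snp_id!r}")
            seen.add(snp.snp_id)
        seen_s: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen_s:
                raise GenotypeError(f"duplicate sample_id {s.sample_id!r}")
            seen_s.add(s.sample_id)
        self.dosage = dosage

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def populations(self) -> list[str]:
        """Per-sample population labels, in sample order."""
        return [s.population for s in self.samples]

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosage as float64 with missing calls mapped to NaN."""
        out = self.dosage.astype(np.float64)
        out[self.dosage == MISSING] = np.nan
        return out

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([lookup[s] for s in wanted], dtype=np.intp)

    def snp_index(self, snp_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        wanted = list(snp_ids)
        missing = [s for s in wanted if s not in lookup]
        if missing:
            raise KeyError(f"unknown snp ids: {missing}")
        return np.array([lookup[s] for s in wanted], dtype=np.intp)

    # -- manipulation --------------------------------------------------------

    def subset(
        self,
        snp_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "GenotypeDataset":
        """Extract a sub-dataset, preserving the requested orderings."""
        rows = (
            np.arange(self.n_samples)
            if sample_ids is None
            else self.sample_index(sample_ids)
        )
        cols = (
            np.arange(self.n_snps)
            if snp_ids is None
            else self.snp_index(snp_ids)
        )
        return GenotypeDataset(
            [self.samples[i] for i in rows],
            [self.snps[j] for j in cols],
            self.dosage[np.ix_(rows, cols)],
        )

    def relabel_populations(self, mapping: dict[str, str]) -> "GenotypeDataset":
        """Return a copy with sample->population labels overridden."""
        samples = [
            replace(s, population=mapping.get(s.sample_id, s.population))
            for s in self.samples
        ]
        return GenotypeDataset(samples, self.snps, self.dosage.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.dosage, other.dosage)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeDataset({self.n_samples} samples x {self.n_snps} SNPs, "
            f"{len(self.population_labels)} populations)"
        )


def concatenate_samples(*datasets: GenotypeDataset) -> GenotypeDataset:
    """Stack datasets that share an identical SNP list, sample-wise."""
    if not datasets:
        raise GenotypeError("need at least one dataset")
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.snp_ids != first.snp_ids:
            raise GenotypeError("datasets do not share an identical SNP list")
    samples = [s for ds in datasets for s in ds.samples]
    dosage = np.vstack([ds.dosage for ds in datasets])
    return GenotypeDataset(samples, first.snps, dosage)
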