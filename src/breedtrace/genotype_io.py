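"""PLINK text (PED/MAP) and binary (BED/BIM/FAM) genotype I/O, plus
allele-aware dataset merging.

Conventions follow PLINK 1.9: "0" is the missing-allele placeholder in
text files; binary files are SNP-major with the 2-bit genotype codes
00 = two copies of allele 1, 10 = heterozygote, 11 = zero copies,
01 = missing.  Allele 1 of the BIM file is the counted allele.

Merging keeps only markers present in both datasets, recodes dosages
where the two datasets swapped which allele is counted, and drops
strand-ambiguous (A/T, C/G) markers whose allele pairs disagree —
for those, a swap cannot be told apart from a strand flip.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    DuplicateMarkerError,
    EmptyIntersectionError,
    GenotypeDataset,
    GenotypeError,
    PlinkFormatError,
    SampleInfo,
    SNPMeta,
)

_BED_MAGIC = bytes((0x6C, 0x1B))
_SNP_MAJOR = 0x01
# 2-bit code -> dosage of allele 1 (counted allele)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> list[SNPMeta]:
    """Read a PLINK MAP file (3- or 4-column variant)."""
    snps: list[SNPMeta] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) == 4:
            chrom, snp_id, _cm, pos = fields
        elif len(fields) == 3:
            chrom, snp_id, pos = fields
        else:
            raise PlinkFormatError(
                f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
            )
        if snp_id in seen:
            raise DuplicateMarkerError(
                f"{map_path}:{lineno}: duplicate marker {snp_id!r}"
            )
        seen.add(snp_id)
        snps.append(SNPMeta(snp_id=snp_id, chromosome=chrom, position=int(pos)))
    return snps


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    population_map: dict[str, str] | None = None,
) -> GenotypeDataset:
    """Read PED/MAP files into a :class:`GenotypeDataset`.

    The PED family-ID column becomes the population label unless
    ``population_map`` (sample_id -> population) overrides it.  The
    counted allele of each SNP is the first non-missing allele
    encountered in file order; "0 0" genotypes become :data:`MISSING`.
    """
    snps = read_map(map_path)
    n_snps = len(snps)
    samples: list[SampleInfo] = []
    raw_alleles: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * n_snps:
            raise PlinkFormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                f"for {n_snps} markers, got {len(fields)}"
            )
        fid, iid = fields[0], fields[1]
        pop = (population_map or {}).get(iid, fid)
        samples.append(SampleInfo(sample_id=iid, population=pop))
        raw_alleles.append(
            [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_snps)]
        )

    dosage = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    out_snps: list[SNPMeta] = []
    for j, snp in enumerate(snps):
        counted, other = "0", "0"
        for i in range(len(samples)):
            for allele in raw_alleles[i][j]:
                if allele == "0":
                    continue
                if counted == "0":
                    counted = allele
                elif allele != counted and other == "0":
                    other = allele
                elif allele not in (counted, other):
                    raise PlinkFormatError(
                        f"{ped_path}: marker {snp.snp_id!r} has more than "
                        f"two alleles ({counted}, {other}, {allele})"
                    )
        for i in range(len(samples)):
            a1, a2 = raw_alleles[i][j]
            if a1 == "0" or a2 == "0":
                continue  # half-calls treated as missing, PLINK-style
            dosage[i, j] = (a1 == counted) + (a2 == counted)
        out_snps.append(
            SNPMeta(
                snp_id=snp.snp_id,
                chromosome=snp.chromosome,
                position=snp.position,
                counted_allele=counted,
                other_allele=other,
                rs_id=snp.rs_id,
            )
        )
    return GenotypeDataset(samples, out_snps, dosage)


def write_plink_text(
    ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset as PED/MAP (family ID = population label)."""
    with open(map_path, "w") as fh:
        for snp in ds.snps:
            fh.write(f"{snp.chromosome}\t{snp.snp_id}\t0\t{snp.position}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(ds.samples):
            fields = [sample.population, sample.sample_id, "0", "0", "0", "-9"]
            for j, snp in enumerate(ds.snps):
                g = int(ds.dosage[i, j])
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [snp.counted_allele] * 2
                elif g == 0:
                    fields += [snp.other_allele] * 2
                else:
                    fields += [snp.counted_allele, snp.other_allele]
                if g in (0, 1) and snp.other_allele == "0":
                    raise GenotypeError(
                        f"{snp.snp_id}: dosage {g} but the other allele "
                        "is unknown; cannot write alleles"
                    )
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# binary format
# ---------------------------------------------------------------------------

def read_plink_binary(
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
    population_map: dict[str, str] | None = None,
) -> GenotypeDataset:
    """Read PLINK 1.9 BED/BIM/FAM (SNP-major) into a dataset."""
    snps: list[SNPMeta] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(bim_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6:
            raise PlinkFormatError(
                f"{bim_path}:{lineno}: expected 6 columns, got {len(fields)}"
            )
        chrom, snp_id, _cm, pos, a1, a2 = fields
        if snp_id in seen:
            raise DuplicateMarkerError(
                f"{bim_path}:{lineno}: duplicate marker {snp_id!r}"
            )
        seen.add(snp_id)
        snps.append(
            SNPMeta(
                snp_id=snp_id,
                chromosome=chrom,
                position=int(pos),
                counted_allele=a1,
                other_allele=a2,
            )
        )

    samples: list[SampleInfo] = []
    for lineno, line in enumerate(Path(fam_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 2:
            raise PlinkFormatError(
                f"{fam_path}:{lineno}: expected >= 2 columns"
            )
        fid, iid = fields[0], fields[1]
        pop = (population_map or {}).get(iid, fid)
        samples.append(SampleInfo(sample_id=iid, population=pop))

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:2]!r}, expected 6c 1b"
        )
    if len(raw) < 3 or raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: not in SNP-major mode")
    n_samples, n_snps = len(samples), len(snps)
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + bytes_per_snp * n_snps
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: truncated or padded; expected {expected} bytes, "
            f"found {len(raw)}"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(
        n_snps, bytes_per_snp
    )
    # expand each byte into its four 2-bit codes (low bits = first sample)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        codes[:, k::4] = (body >> shift) & 0b11
    dosage = _BED_DECODE[codes[:, :n_samples]].T
    return GenotypeDataset(samples, snps, dosage)


def write_plink_binary(
    ds: GenotypeDataset,
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
) -> None:
    """Write a dataset as PLINK 1.9 SNP-major BED/BIM/FAM."""
    with open(bim_path, "w") as fh:
        for snp in ds.snps:
            fh.write(
                f"{snp.chromosome}\t{snp.snp_id}\t0\t{snp.position}\t"
                f"{snp.counted_allele}\t{snp.other_allele}\n"
            )
    with open(fam_path, "w") as fh:
        for s in ds.samples:
            fh.write(f"{s.population} {s.sample_id} 0 0 0 -9\n")

    n_samples = ds.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    code = np.zeros((ds.n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for g, c in _BED_ENCODE.items():
        code[:, :n_samples][ds.dosage.T == g] = c
    packed = np.zeros((ds.n_snps, bytes_per_snp), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        packed |= code[:, k::4] << shift
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes((_SNP_MAJOR,)))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

class MergeResult(NamedTuple):
    dataset: GenotypeDataset
    report: pd.DataFrame  # columns: snp_id, action, reason


def merge_datasets(a: GenotypeDataset, b: GenotypeDataset) -> MergeResult:
    """Merge two datasets on their common markers.

    Markers only in one dataset are discarded.  Where ``b`` counts the
    opposite allele, its dosages are recoded as ``2 - g``.  A/T and C/G
    markers whose allele pairs are not written identically in both
    datasets are dropped (swap vs. strand flip is undecidable), as are
    markers with irreconcilable allele pairs.  Sample order is ``a``
    then ``b``; sample IDs must be disjoint.
    """
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise GenotypeError(f"sample ids present in both datasets: {sorted(overlap)}")
    common = [sid for sid in a.snp_ids if sid in set(b.snp_ids)]
    if not common:
        raise EmptyIntersectionError("the two datasets share no markers")

    b_idx = {s.snp_id: j for j, s in enumerate(b.snps)}
    records: list[tuple[str, str, str]] = []
    kept_snps: list[SNPMeta] = []
    kept_cols_a: list[int] = []
    b_columns: list[np.ndarray] = []
    a_idx = {s.snp_id: j for j, s in enumerate(a.snps)}

    for sid in common:
        sa = a.snps[a_idx[sid]]
        sb = b.snps[b_idx[sid]]
        col_b = b.dosage[:, b_idx[sid]].copy()
        same = (sa.counted_allele, sa.other_allele) == (
            sb.counted_allele,
            sb.other_allele,
        )
        if not same and (sa.strand_ambiguous or sb.strand_ambiguous):
            records.append((sid, "dropped", "strand_ambiguous"))
            continue
        if same:
            records.append((sid, "kept", ""))
        elif (
            sb.counted_allele == sa.other_allele
            and sb.other_allele == sa.counted_allele
        ):
            nonmiss = col_b != MISSING
            col_b[nonmiss] = 2 - col_b[nonmiss]
            records.append((sid, "flipped", "counted_allele_swapped"))
        elif sb.counted_allele == sa.counted_allele and (
            sb.other_allele == "0" or sa.other_allele == "0"
        ):
            # one side never saw the second allele; codings agree
            records.append((sid, "kept", "monomorphic_placeholder"))
        elif sb.counted_allele == sa.other_allele and sb.other_allele == "0":
            nonmiss = col_b != MISSING
            col_b[nonmiss] = 2 - col_b[nonmiss]
            records.append((sid, "flipped", "monomorphic_placeholder"))
        else:
            records.append((sid, "dropped", "irreconcilable_alleles"))
            continue
        kept_snps.append(sa)
        kept_cols_a.append(a_idx[sid])
        b_columns.append(col_b)

    only_a = [s for s in a.snp_ids if s not in b_idx]
    only_b = [s.snp_id for s in b.snps if s.snp_id not in a_idx]
    records += [(s, "dropped", "absent_in_other") for s in only_a + only_b]

    report = pd.DataFrame(records, columns=["snp_id", "action", "reason"])
    if not kept_snps:
        raise EmptyIntersectionError(
            "no markers survived allele reconciliation"
        )
    dosage = np.vstack(
        [
            a.dosage[:, kept_cols_a],
            np.column_stack(b_columns),
        ]
    )
    merged = GenotypeDataset(a.samples + b.samples, kept_snps, dosage)
    return MergeResult(merged, report)


def write_merge_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def harmonize_counted_alleles(
    ds: GenotypeDataset, reference: list[SNPMeta]
) -> GenotypeDataset:
    """Recode a dataset onto a reference allele coding.

    The PED format carries no allele metadata, so a re-read dataset may
    count the opposite allele at some markers (the reader fixes the
    counted allele as the first non-missing allele in file order).
    This flips those markers' dosages (g -> 2 - g) so the counted
    allele matches ``reference``; allele pairs must be reconcilable.
    """
    ref = {s.snp_id: s for s in reference}
    dosage = ds.dosage.copy()
    snps: list[SNPMeta] = []
    for j, snp in enumerate(ds.snps):
        r = ref.get(snp.snp_id)
        if r is None:
            raise KeyError(f"marker {snp.snp_id!r} absent from reference")
        observed = {snp.counted_allele, snp.other_allele} - {"0"}
        if not observed <= ({r.counted_allele, r.other_allele} - {"0"}) and observed:
            raise GenotypeError(
                f"{snp.snp_id}: alleles {observed} irreconcilable with "
                f"reference {r.counted_allele}/{r.other_allele}"
            )
        if snp.counted_allele not in ("0", r.counted_allele):
            nonmiss = dosage[:, j] != MISSING
            dosage[nonmiss, j] = 2 - dosage[nonmiss, j]
        snps.append(r)
    return GenotypeDataset(ds.samples, snps, dosage)


def subset(
    ds: GenotypeDataset,
    snp_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> GenotypeDataset:
    """Functional alias of :meth:`GenotypeDataset.subset`."""
    return ds.subset(snp_ids=snp_ids, sample_ids=sample_ids)
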