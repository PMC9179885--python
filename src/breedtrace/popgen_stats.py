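"""Population-genetic summaries: per-population allele frequencies,
the delta marker-informativeness statistic, identity-by-state (IBS)
similarity, and classical multidimensional scaling.

Delta for a marker and a pair of populations i, j is the absolute
difference of the counted-allele frequencies, ``|p_i - p_j|``: it is
0 when the populations are indistinguishable at the marker and 1 at a
fixed difference, and it is invariant to which allele is counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset, GenotypeError, SNPMeta


@dataclass
class AlleleFrequencyTable:
    """Counted-allele frequency per (population, SNP).

    ``freq`` and ``n_obs`` are populations x SNPs DataFrames; an entry
    with ``n_obs == 0`` has frequency NaN (undefined, never silently 0).
    """

    freq: pd.DataFrame
    n_obs: pd.DataFrame
    snps: list[SNPMeta] | None = None

    def __post_init__(self) -> None:
        if self.freq.shape != self.n_obs.shape:
            raise ValueError("freq and n_obs shapes differ")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bad = (self.freq.to_numpy() < 0) | (self.freq.to_numpy() > 1)
        if np.nan_to_num(bad).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def populations(self) -> list[str]:
        return list(self.freq.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.freq.columns)

    def population_frequencies(self, pop: str) -> pd.Series:
        if pop not in self.freq.index:
            raise KeyError(f"unknown population {pop!r}")
        return self.freq.loc[pop]

    def restrict(self, snp_ids: list[str]) -> "AlleleFrequencyTable":
        missing = [s for s in snp_ids if s not in self.freq.columns]
        if missing:
            raise KeyError(f"unknown snp ids: {missing}")
        meta = None
        if self.snps is not None:
            by_id = {s.snp_id: s for s in self.snps}
            meta = [by_id[s] for s in snp_ids]
        return AlleleFrequencyTable(
            self.freq[snp_ids].copy(), self.n_obs[snp_ids].copy(), meta
        )

    def to_tsv(self, path: str | Path) -> None:
        long = (
            self.freq.stack(future_stack=True)
            .rename("freq")
            .to_frame()
            .join(self.n_obs.stack(future_stack=True).rename("n_obs"))
            .reset_index()
        )
        long.columns = ["population", "snp_id", "freq", "n_obs"]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleFrequencyTable":
        long = pd.read_csv(path, sep="\t", dtype={"population": str, "snp_id": str})
        freq = long.pivot(index="population", columns="snp_id", values="freq")
        n_obs = (
            long.pivot(index="population", columns="snp_id", values="n_obs")
            .fillna(0)
            .astype(int)
        )
        return cls(freq, n_obs)


def allele_frequencies(
    ds: GenotypeDataset, by: list[str] | None = None
) -> AlleleFrequencyTable:
    """Counted-allele frequency per population, missing calls excluded.

    ``freq = (sum of dosages over non-missing samples) / (2 * n_obs)``.
    """
    pops = by if by is not None else ds.population_labels
    unknown = set(ds.populations) - set(pops)
    if by is not None and unknown:
        raise KeyError(f"samples with labels outside `by`: {sorted(unknown)}")
    labels = np.array(ds.populations)
    observed = ds.dosage != MISSING
    dose = np.where(observed, ds.dosage, 0).astype(np.int64)
    freq_rows, n_rows = [], []
    for pop in pops:
        rows = labels == pop
        n_obs = observed[rows].sum(axis=0)
        allele_count = dose[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_obs > 0, allele_count / (2.0 * n_obs), np.nan)
        freq_rows.append(freq)
        n_rows.append(n_obs)
    return AlleleFrequencyTable(
        pd.DataFrame(freq_rows, index=pops, columns=ds.snp_ids),
        pd.DataFrame(n_rows, index=pops, columns=ds.snp_ids),
        snps=list(ds.snps),
    )


def delta_table(
    aft: AlleleFrequencyTable, pop_i: str, pop_j: str
) -> pd.DataFrame:
    """Markers ranked by delta = |p_i - p_j|, descending.

    Markers with an undefined frequency in either population are
    excluded.  Ties are broken by ascending ``snp_id`` so rankings are
    reproducible across platforms.
    """
    if pop_i == pop_j:
        raise ValueError(f"need two distinct populations, got {pop_i!r} twice")
    fi = aft.population_frequencies(pop_i)
    fj = aft.population_frequencies(pop_j)
    delta = (fi - fj).abs().dropna()
    out = (
        delta.rename("delta")
        .rename_axis("snp_id")
        .reset_index()
        .sort_values(["delta", "snp_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def write_delta_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


@dataclass
class IBSMatrix:
    """Mean pairwise identity-by-state similarity in [0, 1].

    ``values[a, b]`` averages ``(2 - |g_a - g_b|) / 2`` over the SNPs
    non-missing in both samples; ``n_shared`` counts those SNPs.  Pairs
    sharing no genotyped SNP are NaN.
    """

    values: np.ndarray
    n_shared: np.ndarray
    sample_ids: list[str]
    populations: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def ibs_matrix(ds: GenotypeDataset) -> IBSMatrix:
    """Average IBS similarity between every pair of samples."""
    n = ds.n_samples
    if n < 2:
        raise GenotypeError("IBS needs at least 2 samples")
    observed = ds.dosage != MISSING
    dose = np.where(observed, ds.dosage, 0).astype(np.float64)
    values = np.empty((n, n))
    counts = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        both = observed & observed[i]
        diff = np.abs(dose - dose[i])
        diff[~both] = 0.0
        shared = both.sum(axis=1)
        counts[i] = shared
        with np.errstate(invalid="ignore"):
            values[i] = np.where(
                shared > 0, 1.0 - diff.sum(axis=1) / (2.0 * shared), np.nan
            )
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return IBSMatrix(values, counts, ds.sample_ids, ds.populations)


@dataclass
class MDSResult:
    """Classical-MDS embedding: n x k coordinates plus eigenvalues."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: list[str]
    populations: list[str]

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, columns=[f"dim{d + 1}" for d in range(k)]
        )
        df.insert(0, "population", self.populations)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classical_mds(ibs: IBSMatrix, k: int = 2) -> MDSResult:
    """Classical (Torgerson) MDS of the distance matrix D = 1 - IBS.

    The Gram matrix ``B = -1/2 * J D^2 J`` (J the centering matrix) is
    eigendecomposed; coordinates are ``eigvec * sqrt(eigval)`` for the
    top-k positive eigenvalues.  If fewer than k eigenvalues are
    positive, fewer columns are returned with a warning.
    """
    n = len(ibs.sample_ids)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    if np.isnan(ibs.values).any():
        raise ValueError("IBS matrix has undefined pairs; cannot embed")
    d = 1.0 - ibs.values
    np.fill_diagonal(d, 0.0)
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    avail = int(positive[:k].sum())
    if avail < k:
        warnings.warn(
            f"only {avail} positive eigenvalues available; "
            f"returning {avail} dimensions instead of {k}",
            stacklevel=2,
        )
    kk = max(avail, 0)
    coords = eigvec[:, :kk] * np.sqrt(eigval[:kk])
    return MDSResult(coords, eigval[:kk], ibs.sample_ids, ibs.populations)
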