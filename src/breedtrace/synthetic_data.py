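"""Synthetic multi-population SNP studies under the Balding-Nichols
model.

Each marker has an ancestral frequency p drawn uniformly from a
configurable range; each population's frequency is then drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
F p (1-p) — F is the differentiation (Fst) parameter.  Genotypes are
Binomial(2, p_pop) per locus (Hardy-Weinberg and linkage equilibrium
within populations), with missing calls injected completely at
random.  The default design mirrors a five-population pig study:
population sizes {NS: 93, LW: 44, LR: 37, DU: 44, WB: 88}, a few
thousand markers, and a ~98.5% mean call rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset, SampleInfo, SNPMeta

_DEFAULT_SIZES = {"NS": 93, "LW": 44, "LR": 37, "DU": 44, "WB": 88}
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]  # unambiguous
_N_CHROMOSOMES = 18


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Design of one synthetic study.

    ``fst`` may be a single value or a per-population mapping (e.g. a
    larger value for a wild population to mimic a wild-vs-domestic
    primary axis of differentiation).
    """

    population_sizes: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_SIZES)
    )
    n_snps: int = 5000
    fst: float | dict[str, float] = 0.2
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.population_sizes:
            raise ValueError("need at least one population")
        for pop, n in self.population_sizes.items():
            if n < 2:
                raise ValueError(f"population {pop!r} needs >= 2 samples, got {n}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must lie strictly inside (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for pop, f in self.fst_by_population().items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"fst for {pop!r} must be in [0, 1), got {f}")

    def fst_by_population(self) -> dict[str, float]:
        if isinstance(self.fst, dict):
            missing = set(self.population_sizes) - set(self.fst)
            if missing:
                raise ValueError(f"fst missing for populations {sorted(missing)}")
            return {p: float(self.fst[p]) for p in self.population_sizes}
        return {p: float(self.fst) for p in self.population_sizes}


@dataclass
class TruthRecord:
    """Ground-truth frequencies behind a synthetic study."""

    ancestral: pd.Series           # per SNP
    population_freq: pd.DataFrame  # populations x SNPs

    def to_tsv(self, path) -> None:
        out = self.population_freq.T.copy()
        out.insert(0, "ancestral_freq", self.ancestral)
        out.rename_axis("snp_id").to_csv(path, sep="\t")


def draw_population_frequencies(
    config: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> TruthRecord:
    """Sample ancestral and per-population frequencies (Balding-Nichols)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=config.n_snps)
    snp_ids = [f"snp{j + 1:06d}" for j in range(config.n_snps)]
    rows = {}
    for pop, f in config.fst_by_population().items():
        if f == 0.0:  # degenerate limit: no drift
            rows[pop] = ancestral.copy()
            continue
        a = ancestral * (1.0 - f) / f
        b = (1.0 - ancestral) * (1.0 - f) / f
        rows[pop] = rng.beta(a, b)
    return TruthRecord(
        ancestral=pd.Series(ancestral, index=snp_ids, name="ancestral"),
        population_freq=pd.DataFrame(rows, index=snp_ids).T[snp_ids],
    )


def generate_study(
    config: SyntheticStudyConfig,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Generate one full synthetic study (genotypes + truth record).

    Fully deterministic under ``config.seed``: frequencies, genotypes,
    missing-call positions, marker metadata and identifiers all derive
    from one generator.
    """
    rng = np.random.default_rng(config.seed)
    truth = draw_population_frequencies(config, rng)
    snp_ids = list(truth.ancestral.index)

    snps = []
    per_chrom = -(-config.n_snps // _N_CHROMOSOMES)
    for j, sid in enumerate(snp_ids):
        counted, other = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        chrom = j // per_chrom + 1
        pos = (j % per_chrom + 1) * 10_000
        snps.append(
            SNPMeta(
                snp_id=sid,
                chromosome=str(chrom),
                position=pos,
                counted_allele=counted,
                other_allele=other,
            )
        )

    samples: list[SampleInfo] = []
    blocks: list[np.ndarray] = []
    for pop, n in config.population_sizes.items():
        freqs = truth.population_freq.loc[pop].to_numpy()
        blocks.append(rng.binomial(2, freqs, size=(n, config.n_snps)))
        samples += [SampleInfo(f"{pop}_{i + 1:03d}", pop) for i in range(n)]
    dosage = np.vstack(blocks).astype(np.int8)
    if config.missing_rate > 0.0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING
    return GenotypeDataset(samples, snps, dosage), truth
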