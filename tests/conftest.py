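import numpy as np
import pytest

from breedtrace import (
    GenotypeDataset,
    SampleInfo,
    SNPMeta,
    SyntheticStudyConfig,
    allele_frequencies,
    generate_study,
)
from breedtrace.datatypes import MISSING


def make_dataset(dosage, populations=None, alleles=None, sample_prefix="s"):
    """Build a small GenotypeDataset from a dosage matrix."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    populations = populations or ["P1"] * n
    alleles = alleles or [("A", "G")] * m
    samples = [
        SampleInfo(f"{sample_prefix}{i + 1}", populations[i]) for i in range(n)
    ]
    snps = [
        SNPMeta(
            snp_id=f"snp{j + 1}",
            chromosome="1",
            position=(j + 1) * 1000,
            counted_allele=alleles[j][0],
            other_allele=alleles[j][1],
        )
        for j in range(m)
    ]
    return GenotypeDataset(samples, snps, dosage)


@pytest.fixture
def tiny_two_pop():
    """4 samples, 2 populations, 3 SNPs with one missing call."""
    return make_dataset(
        [[2, 1, 0], [2, 2, 1], [0, 1, MISSING], [1, 0, 2]],
        populations=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but realistic 5-population synthetic study."""
    cfg = SyntheticStudyConfig(n_snps=400, fst=0.2, seed=11)
    ds, truth = generate_study(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def small_study_frequencies(small_study):
    ds, _ = small_study
    return allele_frequencies(ds)
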