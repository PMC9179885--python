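import numpy as np
import pytest

from breedtrace import (
    GenotypeDataset,
    SampleInfo,
    SNPMeta,
    harmonize_counted_alleles,
    merge_datasets,
    read_plink_binary,
    read_plink_text,
    write_plink_binary,
    write_plink_text,
)
from breedtrace.datatypes import (
    MISSING,
    DuplicateMarkerError,
    EmptyIntersectionError,
    GenotypeError,
    PlinkFormatError,
)
from breedtrace.popgen_stats import allele_frequencies

from conftest import make_dataset


def write_files(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "x.ped"
    map_ = tmp_path / "x.map"
    ped.write_text("\n".join(ped_lines) + ("\n" if ped_lines else ""))
    map_.write_text("\n".join(map_lines) + "\n")
    return ped, map_


class TestTextFormat:
    def test_dosage_encoding_and_missing(self, tmp_path):
        ped, map_ = write_files(
            tmp_path,
            ["F1 s1 0 0 0 -9 A A G G", "F1 s2 0 0 0 -9 A C 0 0"],
            ["1 snp1 0 100", "1 snp2 0 200"],
        )
        ds = read_plink_text(ped, map_)
        assert np.array_equal(ds.dosage, [[2, 2], [1, MISSING]])
        assert [s.counted_allele for s in ds.snps] == ["A", "G"]
        assert ds.populations == ["F1", "F1"]

    def test_empty_ped_gives_zero_samples(self, tmp_path):
        ped, map_ = write_files(tmp_path, [], ["1 snp1 0 100", "1 snp2 0 200"])
        ds = read_plink_text(ped, map_)
        assert ds.shape == (0, 2)

    def test_malformed_line_names_the_line(self, tmp_path):
        ped, map_ = write_files(
            tmp_path, ["F1 s1 0 0 0 -9 A A"], ["1 snp1 0 100", "1 snp2 0 200"]
        )
        with pytest.raises(PlinkFormatError, match=":1"):
            read_plink_text(ped, map_)

    def test_duplicate_marker_rejected(self, tmp_path):
        ped, map_ = write_files(
            tmp_path, ["F1 s1 0 0 0 -9 A A G G"], ["1 snp1 0 100", "1 snp1 0 200"]
        )
        with pytest.raises(DuplicateMarkerError):
            read_plink_text(ped, map_)

    def test_population_override(self, tmp_path):
        ped, map_ = write_files(
            tmp_path, ["F1 s1 0 0 0 -9 A A"], ["1 snp1 0 100"]
        )
        ds = read_plink_text(ped, map_, population_map={"s1": "NS"})
        assert ds.populations == ["NS"]

    def test_round_trip_identity(self, tmp_path, tiny_two_pop):
        # PED carries no allele metadata, so the reader may count the
        # opposite allele at markers whose first genotype in file order
        # is an other-allele homozygote; harmonizing onto the original
        # coding must restore the dataset exactly
        write_plink_text(tiny_two_pop, tmp_path / "o.ped", tmp_path / "o.map")
        back = read_plink_text(tmp_path / "o.ped", tmp_path / "o.map")
        assert harmonize_counted_alleles(back, tiny_two_pop.snps) == tiny_two_pop


class TestBinaryFormat:
    def test_decodes_per_spec_codes(self, tmp_path):
        # 4 samples, 1 SNP: codes 00 00 00 00 -> one zero byte
        (tmp_path / "x.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b00000000]))
        (tmp_path / "x.bim").write_text("1 snp1 0 100 A G\n")
        (tmp_path / "x.fam").write_text(
            "".join(f"F1 s{i} 0 0 0 -9\n" for i in range(4))
        )
        ds = read_plink_binary(
            tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam"
        )
        assert np.array_equal(ds.dosage[:, 0], [2, 2, 2, 2])

    def test_het_and_missing_codes(self, tmp_path):
        # 2 samples: sample1 het (10), sample2 missing (01) -> byte 0b0110
        (tmp_path / "x.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b00000110]))
        (tmp_path / "x.bim").write_text("1 snp1 0 100 A G\n")
        (tmp_path / "x.fam").write_text("F1 s1 0 0 0 -9\nF1 s2 0 0 0 -9\n")
        ds = read_plink_binary(
            tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam"
        )
        assert ds.dosage[0, 0] == 1
        assert ds.dosage[1, 0] == MISSING

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(bytes([0x00, 0x1B, 0x01, 0]))
        (tmp_path / "x.bim").write_text("1 snp1 0 100 A G\n")
        (tmp_path / "x.fam").write_text("F1 s1 0 0 0 -9\n")
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink_binary(
                tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam"
            )

    def test_truncated_block_reports_byte_counts(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]))
        (tmp_path / "x.bim").write_text("1 snp1 0 100 A G\n")
        (tmp_path / "x.fam").write_text("F1 s1 0 0 0 -9\n")
        with pytest.raises(PlinkFormatError, match="expected 4 bytes, found 3"):
            read_plink_binary(
                tmp_path / "x.bed", tmp_path / "x.bim", tmp_path / "x.fam"
            )

    def test_text_and_binary_exports_read_back_identically(
        self, tmp_path, small_study
    ):
        ds, _ = small_study
        ds = ds.subset(snp_ids=ds.snp_ids[:50])
        write_plink_text(ds, tmp_path / "t.ped", tmp_path / "t.map")
        write_plink_binary(
            ds, tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam"
        )
        from_text = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        from_bin = read_plink_binary(
            tmp_path / "b.bed", tmp_path / "b.bim", tmp_path / "b.fam"
        )
        assert from_text.samples == from_bin.samples
        # text re-reading may re-pick the counted allele at SNPs whose
        # first non-missing genotype is an other-allele homozygote, so
        # compare frequencies allele-explicitly instead of raw dosage
        for snp_t, snp_b, col_t, col_b in zip(
            from_text.snps, from_bin.snps, from_text.dosage.T, from_bin.dosage.T
        ):
            if snp_t.counted_allele == snp_b.counted_allele:
                assert np.array_equal(col_t, col_b)
            else:
                assert snp_t.counted_allele == snp_b.other_allele
                flipped = np.where(col_b == MISSING, MISSING, 2 - col_b)
                assert np.array_equal(col_t, flipped)

    def test_binary_round_trip(self, tmp_path, tiny_two_pop):
        write_plink_binary(
            tiny_two_pop,
            tmp_path / "r.bed",
            tmp_path / "r.bim",
            tmp_path / "r.fam",
        )
        back = read_plink_binary(
            tmp_path / "r.bed", tmp_path / "r.bim", tmp_path / "r.fam"
        )
        assert back == tiny_two_pop


class TestMerge:
    def a(self):
        return make_dataset(
            [[2, 1, 0], [1, 0, 2]],
            populations=["A", "A"],
            alleles=[("A", "G"), ("C", "T"), ("A", "C")],
        )

    def test_keeps_only_common_snps(self):
        a = self.a()
        b = make_dataset(
            [[0, 1, 2], [2, 2, 0]],
            populations=["B", "B"],
            alleles=[("C", "T"), ("A", "C"), ("A", "G")],
            sample_prefix="t",
        )
        # rename b's snps so it has snp2, snp3, snp4
        b.snps = [
            SNPMeta("snp2", "1", 2000, "C", "T"),
            SNPMeta("snp3", "1", 3000, "A", "C"),
            SNPMeta("snp4", "1", 4000, "A", "G"),
        ]
        merged, report = merge_datasets(a, b)
        assert merged.snp_ids == ["snp2", "snp3"]
        assert merged.sample_ids == ["s1", "s2", "t1", "t2"]
        dropped = set(report.loc[report.action == "dropped", "snp_id"])
        assert dropped == {"snp1", "snp4"}

    def test_allele_swap_recodes_dosage(self):
        a = make_dataset([[2], [1]], alleles=[("A", "G")])
        b = make_dataset(
            [[0], [MISSING]], alleles=[("G", "A")], sample_prefix="t"
        )
        merged, report = merge_datasets(a, b)
        assert list(merged.dosage[:, 0]) == [2, 1, 2, MISSING]
        assert report.loc[report.snp_id == "snp1", "action"].item() == "flipped"

    def test_strand_ambiguous_mismatch_dropped(self):
        a = make_dataset([[2], [1]], alleles=[("A", "T")])
        b = make_dataset([[0], [1]], alleles=[("T", "A")], sample_prefix="t")
        with pytest.raises(EmptyIntersectionError):
            merge_datasets(a, b)

    def test_irreconcilable_alleles_dropped_and_reported(self):
        a = make_dataset([[2, 1], [1, 0]], alleles=[("A", "C"), ("A", "G")])
        b = make_dataset(
            [[0, 1], [1, 2]], alleles=[("A", "G"), ("A", "G")], sample_prefix="t"
        )
        merged, report = merge_datasets(a, b)
        assert merged.snp_ids == ["snp2"]
        row = report.loc[report.snp_id == "snp1"]
        assert row.action.item() == "dropped"
        assert row.reason.item() == "irreconcilable_alleles"

    def test_self_merge_conserves_frequencies(self, small_study):
        ds, _ = small_study
        ds = ds.subset(snp_ids=ds.snp_ids[:30])
        renamed = GenotypeDataset(
            [
                SampleInfo(s.sample_id + "_copy", s.population)
                for s in ds.samples
            ],
            ds.snps,
            ds.dosage.copy(),
        )
        merged, _ = merge_datasets(ds, renamed)
        assert merged.n_samples == 2 * ds.n_samples
        f_orig = allele_frequencies(ds).freq
        f_merged = allele_frequencies(merged).freq
        assert np.allclose(f_orig, f_merged, equal_nan=True)

    def test_snp_set_symmetric_in_argument_order(self):
        a = make_dataset([[2, 1], [1, 0]], alleles=[("A", "T"), ("A", "G")])
        b = make_dataset(
            [[0, 1], [1, 2]], alleles=[("T", "A"), ("G", "A")], sample_prefix="t"
        )
        ab, _ = merge_datasets(a, b)
        ba, _ = merge_datasets(b, a)
        assert set(ab.snp_ids) == set(ba.snp_ids)

    def test_overlapping_sample_ids_rejected(self):
        a = make_dataset([[2], [1]])
        with pytest.raises(GenotypeError, match="both datasets"):
            merge_datasets(a, a)


class TestSubset:
    def test_full_subset_is_identity(self, tiny_two_pop):
        ds = tiny_two_pop
        assert ds.subset(snp_ids=ds.snp_ids, sample_ids=ds.sample_ids) == ds

    def test_single_snp_column(self, tiny_two_pop):
        sub = tiny_two_pop.subset(snp_ids=["snp2"])
        assert sub.shape == (4, 1)
        assert np.array_equal(sub.dosage[:, 0], tiny_two_pop.dosage[:, 1])

    def test_composition(self, tiny_two_pop):
        via = tiny_two_pop.subset(snp_ids=["snp1", "snp3"]).subset(snp_ids=["snp3"])
        direct = tiny_two_pop.subset(snp_ids=["snp3"])
        assert via == direct

    def test_unknown_id_listed(self, tiny_two_pop):
        with pytest.raises(KeyError, match="nope"):
            tiny_two_pop.subset(snp_ids=["snp1", "nope"])
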