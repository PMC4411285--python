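"""Core types, bitsets, the global-position transform, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pananchor import bitset, io
from pananchor.datamodel import (
    Anchor,
    AnchorSet,
    GenomePosition,
    TaxaList,
    genetic_distance,
    global_position,
)
from pananchor.simpop import SimConfig, simulate_population


class TestGlobalPosition:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [(2, 345, 2_000_000_345), (1, 1, 1_000_000_001), (10, 999_999_999, 10_999_999_999)],
    )
    def test_formula(self, chrom, pos, expected):
        assert global_position(GenomePosition(chrom, pos)) == expected

    def test_coordinate_overflow_rejected(self):
        with pytest.raises(ValueError):
            GenomePosition(1, 1_000_000_000)
        with pytest.raises(ValueError):
            GenomePosition(0, 5)

    @given(
        st.integers(1, 20), st.integers(1, 999_999_999),
        st.integers(1, 20), st.integers(1, 999_999_999),
    )
    @settings(max_examples=200, deadline=None)
    def test_injective_and_order_preserving(self, c1, p1, c2, p2):
        g1 = global_position(GenomePosition(c1, p1))
        g2 = global_position(GenomePosition(c2, p2))
        assert (g1 == g2) == ((c1, p1) == (c2, p2))
        assert (g1 < g2) == ((c1, p1) < (c2, p2))


class TestGeneticDistance:
    def test_identity_and_subtraction(self):
        a = global_position(GenomePosition(1, 5_000_000))
        b = global_position(GenomePosition(1, 5_010_000))
        assert genetic_distance(a, a) == 0
        assert genetic_distance(a, b) == 10_000

    def test_cross_chromosome_edge_artifact(self):
        # positions near a chromosome boundary look close on the linear
        # scale; chromosome agreement must never be inferred from distance
        a = global_position(GenomePosition(1, 999_000_000))
        b = global_position(GenomePosition(2, 1_000))
        assert genetic_distance(a, b) == 1_001_000


class TestBitset:
    def test_intersect_matches_naive_loop(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = rng.integers(0, 2, 1000).astype(bool)
            b = rng.integers(0, 2, 1000).astype(bool)
            assert bitset.intersect_count(bitset.pack(a), bitset.pack(b)) == int(
                np.sum(a & b)
            )

    def test_all_ones_and_disjoint(self):
        n = 14129
        ones = bitset.pack(np.ones(n, dtype=bool))
        assert bitset.intersect_count(ones, ones) == n
        a = np.zeros(64, dtype=bool); a[:32] = True
        b = ~a
        assert bitset.intersect_count(bitset.pack(a), bitset.pack(b)) == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bitset.intersect_count(np.zeros(2, np.uint8), np.zeros(3, np.uint8))

    def test_matrix_rowwise_equals_scalar(self):
        rng = np.random.default_rng(1)
        mat = rng.integers(0, 2, (20, 130)).astype(bool)
        vec = rng.integers(0, 2, 130).astype(bool)
        packed = np.packbits(mat, axis=1)
        got = bitset.intersect_count_many(packed, bitset.pack(vec))
        want = [int(np.sum(row & vec)) for row in mat]
        assert got.tolist() == want


def _matrices_equal(a, b):
    return (
        a.taxa.names == b.taxa.names
        and a.snp_ids == b.snp_ids
        and np.array_equal(a.chromosomes, b.chromosomes)
        and np.array_equal(a.positions, b.positions)
        and np.allclose(a.mafs, b.mafs)
        and np.array_equal(a.minor_packed, b.minor_packed)
        and np.array_equal(a.call_packed, b.call_packed)
    )


class TestSnpIO:
    def test_toy_vcf_maf_and_callmask(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
            "1\t100\tsnp1\tA\tC\t.\t.\t.\tGT\t0/0\t1/1\t./.\n"
        )
        m = io.read_snp_matrix(vcf, format="vcf")
        assert len(m) == 1
        rec = m.record(0)
        assert rec.maf == pytest.approx(0.5)
        assert bitset.popcount(rec.call_mask) == 2

    def test_monomorphic_site_dropped(self, tmp_path):
        path = tmp_path / "g.hapmap.tsv"
        path.write_text(
            "rs\talleles\tchrom\tpos\ta\tb\tc\n"
            "s1\tA/C\t1\t100\tA\tA\tA\n"
            "s2\tA/C\t1\t200\tA\tC\tC\n"
        )
        m = io.read_snp_matrix(path)
        assert m.snp_ids == ["s2"]

    def test_hapmap_round_trip(self, tmp_path):
        bundle = simulate_population(
            SimConfig(seed=7, n_taxa=30, n_snps=80, n_tags=20,
                      chromosome_length_bp=2_000_000)
        )
        path = tmp_path / "rt.hapmap.tsv"
        io.write_snp_matrix(bundle.snps, path)
        again = io.read_snp_matrix(path)
        assert _matrices_equal(bundle.snps, again)

    def test_het_policy(self, tmp_path):
        path = tmp_path / "het.tsv"
        path.write_text(
            "rs\talleles\tchrom\tpos\ta\tb\tc\td\n"
            "s1\tA/C\t1\t100\tA\tC\tM\tA\n"  # M = A/C het
        )
        minor_policy = io.read_snp_matrix(path, het_policy="minor").record(0)
        missing_policy = io.read_snp_matrix(path, het_policy="missing").record(0)
        assert bitset.popcount(minor_policy.minor_presence) == 2  # b and het c
        assert bitset.popcount(missing_policy.minor_presence) == 1
        assert bitset.popcount(missing_policy.call_mask) == 3

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("rs\talleles\tchrom\tpos\ta\nX\tA/C\tone\t100\tA\n")
        with pytest.raises(io.ParseError, match=":2"):
            io.read_snp_matrix(path)


class TestTagIO:
    def test_duplicates_merged_and_empty_dropped(self, tmp_path):
        path = tmp_path / "tags.tsv"
        seq1, seq2 = "A" * 64, "C" * 64
        path.write_text(
            "tag_sequence\tx\ty\tz\n"
            f"{seq1}\t1\t0\t0\n"
            f"{seq1}\t0\t1\t0\n"
            f"{seq2}\t0\t0\t0\n"
        )
        tags = io.read_tag_matrix(path)
        assert tags.sequences == [seq1]
        assert tags.counts.tolist() == [2]

    def test_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "tags.tsv"
        io.write_tag_matrix(small_panel.tags, path)
        again = io.read_tag_matrix(path, taxa=small_panel.tags.taxa)
        assert again.sequences == small_panel.tags.sequences
        assert np.array_equal(again.presence_packed, small_panel.tags.presence_packed)

    def test_taxa_reordered_by_name(self, tmp_path):
        path = tmp_path / "tags.tsv"
        path.write_text("tag_sequence\ty\tx\n" + "A" * 64 + "\t1\t0\n")
        taxa = TaxaList(["x", "y"])
        tags = io.read_tag_matrix(path, taxa=taxa)
        bits = np.unpackbits(tags.presence_packed[0], count=2)
        assert bits.tolist() == [0, 1]

    def test_unresolvable_taxa_error(self, tmp_path):
        path = tmp_path / "tags.tsv"
        path.write_text("tag_sequence\tq\n" + "A" * 64 + "\t1\n")
        with pytest.raises(io.ParseError):
            io.read_tag_matrix(path, taxa=TaxaList(["x"]))

    def test_fasta_presence_lists(self, tmp_path):
        taxa = TaxaList(["a", "b", "c"])
        fasta = tmp_path / "tags.fa"
        fasta.write_text(">t1\n" + "ACGT" * 16 + "\n")
        pres = tmp_path / "pres.tsv"
        pres.write_text("t1\ta,c\n")
        tags = io.read_tag_matrix(fasta, format="fasta", presence_path=pres, taxa=taxa)
        assert np.unpackbits(tags.presence_packed[0], count=3).tolist() == [1, 0, 1]


class TestAnchorIO:
    def test_round_trip_and_empty_physical(self, tmp_path):
        anchors = AnchorSet(
            [
                Anchor("A" * 64, "G", GenomePosition(1, 500), 1e-9, 1234.0,
                       pav_flag=True, physical_pos=None),
                Anchor("C" * 64, "GJ", GenomePosition(2, 900), 1e-12, 10.0,
                       pav_flag=False, physical_pos=GenomePosition(2, 880)),
            ]
        )
        path = tmp_path / "anchors.tsv"
        io.write_anchors(anchors, path)
        lines = path.read_text().splitlines()
        pav_row = [l for l in lines if l.startswith("A" * 64)][0].split("\t")
        assert pav_row[-2] == "" and pav_row[-1] == "" and pav_row[6] == "1"
        assert io.read_anchors(path) == anchors

    def test_empty_set_is_error(self, tmp_path):
        with pytest.raises(ValueError):
            io.write_anchors(AnchorSet([]), tmp_path / "x.tsv")

    def test_rows_sorted_by_sequence(self, tmp_path):
        anchors = AnchorSet(
            [
                Anchor("T" * 64, "G", GenomePosition(1, 1), 0.5, 1.0),
                Anchor("A" * 64, "G", GenomePosition(1, 2), 0.5, 1.0),
            ]
        )
        path = tmp_path / "a.tsv"
        io.write_anchors(anchors, path)
        rows = [l.split("\t")[0] for l in path.read_text().splitlines()[1:]]
        assert rows == sorted(rows)
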