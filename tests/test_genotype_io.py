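"""Genotype containers, encodings, file dialects and marker-set algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsimpute.genotype_io import (
    GenotypeMatrix,
    MarkerRecord,
    PositionSet,
    concat_markers,
    decode_onehot,
    encode_onehot,
    marker_set_op,
    read_csv_genotypes,
    read_positions,
    read_vcf,
    segment_chromosome,
    subset_panel,
    write_integer_genotypes,
)
from conftest import make_gm, random_gm


class TestMarkerRecord:
    def test_rejects_equal_alleles(self):
        with pytest.raises(ValueError):
            MarkerRecord("1", 5, ref="A", alt="A")

    def test_rejects_nonpositive_position(self):
        with pytest.raises(ValueError):
            MarkerRecord("1", 0)


class TestGenotypeMatrix:
    def test_rejects_invalid_codes(self):
        with pytest.raises(ValueError):
            make_gm([[0, 1], [4, 2]])

    def test_rejects_unsorted_positions(self):
        markers = [MarkerRecord("1", 10), MarkerRecord("1", 5)]
        with pytest.raises(ValueError):
            GenotypeMatrix(["a"], markers, np.array([[1, 2]]))

    def test_missing_rate(self):
        g = make_gm([[0, 1, 2, 3]])
        assert g.missing_rate() == 0.25


class TestOneHot:
    @pytest.mark.parametrize(
        "code,vec", [(0, [0, 0, 0]), (1, [1, 0, 0]), (2, [0, 1, 0]), (3, [0, 0, 1])]
    )
    def test_encoding_rules(self, code, vec):
        assert encode_onehot(np.array([[code]]))[0, 0].tolist() == vec

    def test_round_trip_all_codes(self):
        codes = np.array([[0, 1, 2, 3], [3, 2, 1, 0]], dtype=np.int8)
        assert np.array_equal(decode_onehot(encode_onehot(codes)), codes)

    def test_channel_sum_zero_only_at_missing(self):
        codes = np.array([[0, 2], [1, 3]])
        s = encode_onehot(codes).sum(axis=-1)
        assert np.array_equal(s == 0, codes == 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            encode_onehot(np.array([[5]]))


class TestVCF:
    def test_gt_code_mapping(self, tmp_path, vcf_writer):
        g = make_gm([[1, 2, 3, 0], [2, 2, 1, 3]])
        path = vcf_writer(tmp_path / "t.vcf", g)
        back = read_vcf(path)
        assert np.array_equal(back.codes, g.codes)
        assert back.sample_ids == g.sample_ids
        assert [m.key for m in back.markers] == [m.key for m in g.markers]

    def test_phase_discarded(self, tmp_path, vcf_writer):
        g = make_gm([[2, 2], [2, 1]])
        path = vcf_writer(tmp_path / "p.vcf", g, phased=True)
        assert np.array_equal(read_vcf(path).codes, g.codes)

    def test_one_zero_is_het(self, tmp_path):
        # unordered allele pair: 1/0 and 0/1 both code 2
        from conftest import VCF_HEADER

        path = tmp_path / "h.vcf"
        path.write_text(
            VCF_HEADER.format(chrom="1", samples="a\tb")
            + "1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t1/0\t0/1\n"
        )
        assert read_vcf(str(path)).codes.tolist() == [[2], [2]]

    def test_skips_multiallelic(self, tmp_path):
        from conftest import VCF_HEADER

        path = tmp_path / "m.vcf"
        path.write_text(
            VCF_HEADER.format(chrom="1", samples="a")
            + "1\t5\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
            + "1\t9\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\n"
        )
        with pytest.warns(UserWarning, match="non-biallelic"):
            g = read_vcf(str(path))
        assert g.n_markers == 1 and g.markers[0].pos == 9

    def test_chrom_filter(self, tmp_path):
        from conftest import VCF_HEADER

        path = tmp_path / "c.vcf"
        path.write_text(
            VCF_HEADER.format(chrom="1", samples="a")
            + "1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\n"
            + "2\t3\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\n"
        )
        g = read_vcf(str(path), chrom_filter="2")
        assert g.keys() == [("2", 3)]


class TestCSVDialect:
    def test_parse_and_round_trip(self, tmp_path):
        g = make_gm([[1, 3], [2, 1], [3, 2]])
        path = tmp_path / "g.csv"
        write_integer_genotypes(g, str(path))
        back = read_csv_genotypes(str(path))
        assert back == g

    def test_direct_row_parse(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("chrom,pos,ref,alt,sA,sB,sC\nchr1,1234,A,G,1,3,2\n")
        g = read_csv_genotypes(str(path))
        assert g.keys() == [("chr1", 1234)]
        assert g.codes[:, 0].tolist() == [1, 3, 2]

    def test_qccode_sentinel(self, tmp_path):
        path = tmp_path / "q.csv"
        path.write_text("chrom,pos,QCcode,S1,S2\n1,10,ok,1,2\n1,20,ok,3,3\n")
        g = read_csv_genotypes(str(path))
        assert g.n_samples == 2 and g.sample_ids == ["S1", "S2"]

    def test_tab_delimiter_detected(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text("chrom\tpos\tref\talt\ta\n1\t10\tA\tG\t2\n")
        assert read_csv_genotypes(str(path)).codes.tolist() == [[2]]

    def test_missing_sentinel_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("chrom,pos,a,b\n1,10,1,2\n")
        with pytest.raises(ValueError, match="sentinel"):
            read_csv_genotypes(str(path))

    def test_empty_sample_block_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("chrom,pos,ref,alt\n1,10,A,G\n")
        with pytest.raises(ValueError, match="sample"):
            read_csv_genotypes(str(path))

    def test_bad_cell_value_rejected(self, tmp_path):
        path = tmp_path / "cell.csv"
        path.write_text("chrom,pos,ref,alt,a\n1,10,A,G,7\n")
        with pytest.raises(ValueError):
            read_csv_genotypes(str(path))

    def test_write_refuses_missing(self, tmp_path):
        g = make_gm([[0, 1]])
        with pytest.raises(ValueError, match="missing"):
            write_integer_genotypes(g, str(tmp_path / "x.csv"))

    def test_single_entry_matrix(self, tmp_path):
        g = make_gm([[2]])
        path = tmp_path / "one.csv"
        write_integer_genotypes(g, str(path))
        assert len(path.read_text().strip().splitlines()) == 2  # header + 1 row


class TestPositions:
    def test_two_column_file(self, tmp_path):
        path = tmp_path / "pos.txt"
        path.write_text("chrom\tpos\n1\t5\n1\t9\n2\t3\n")
        ps = read_positions(str(path))
        assert len(ps) == 3 and ("2", 3) in ps

    def test_genotype_file_as_positions(self, tmp_path):
        g = make_gm([[1, 2]])
        path = tmp_path / "g.csv"
        write_integer_genotypes(g, str(path))
        assert read_positions(str(path)) == g.position_set()


class TestSetAlgebra:
    def test_enumerated_union(self):
        a = PositionSet([("1", 5), ("1", 9)])
        b = PositionSet([("1", 9), ("2", 3)])
        assert len(marker_set_op(a, b, "union")) == 3
        assert marker_set_op(a, b, "intersection") == PositionSet([("1", 9)])

    def test_idempotence_and_empty(self):
        a = PositionSet([("1", 1), ("1", 2)])
        assert marker_set_op(a, a, "intersection") == a
        assert len(marker_set_op(a, PositionSet(), "intersection")) == 0

    @settings(deadline=None, max_examples=50)
    @given(
        st.sets(st.tuples(st.sampled_from("12"), st.integers(1, 50)), max_size=30),
        st.sets(st.tuples(st.sampled_from("12"), st.integers(1, 50)), max_size=30),
    )
    def test_inclusion_exclusion(self, ka, kb):
        a, b = PositionSet(ka), PositionSet(kb)
        assert len(a | b) + len(a & b) == len(a) + len(b)


class TestSubsetPanel:
    def test_identity_subset(self):
        panel = make_gm([[1, 2, 3], [3, 2, 1]])
        sub = subset_panel(panel, panel.position_set())
        assert sub == panel

    def test_intersection_semantics(self):
        rng = np.random.default_rng(0)
        panel = random_gm(rng, 4, 10)
        targets = PositionSet([m.key for m in panel.markers[::2]] + [("9", 999)])
        sub = subset_panel(panel, targets)
        assert sub.position_set() == panel.position_set() & targets

    def test_allele_mismatch_dropped(self):
        panel = make_gm([[1, 2]], ref="A", alt="G")
        # target marker at pos 1 has swapped alleles -> dropped, not flipped
        t_markers = [MarkerRecord("1", 1, ref="G", alt="A"), MarkerRecord("1", 2, ref="A", alt="G")]
        with pytest.warns(UserWarning, match="mismatched"):
            sub = subset_panel(panel, PositionSet([("1", 1), ("1", 2)]), t_markers)
        assert sub.keys() == [("1", 2)]

    def test_missing_in_panel_rejected(self):
        panel = make_gm([[0, 1]])
        with pytest.raises(ValueError, match="not permitted"):
            subset_panel(panel, panel.position_set())

    def test_empty_intersection_rejected(self):
        panel = make_gm([[1, 2]])
        with pytest.raises(ValueError):
            subset_panel(panel, PositionSet([("7", 1)]))


class TestSegmentChromosome:
    def test_slice_arithmetic(self):
        rng = np.random.default_rng(1)
        g = random_gm(rng, 2, 2500)
        parts = segment_chromosome(g, 1000)
        assert [p.n_markers for p in parts] == [1000, 1000, 500]

    def test_small_input_single_slice(self):
        g = make_gm([[1, 2, 3]])
        parts = segment_chromosome(g, 10)
        assert len(parts) == 1 and parts[0] == g

    @pytest.mark.parametrize("p,mx", [(10, 3), (7, 7), (13, 5)])
    def test_concat_reproduces_input(self, p, mx):
        rng = np.random.default_rng(p)
        g = random_gm(rng, 3, p)
        assert concat_markers(segment_chromosome(g, mx)) == g
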