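import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromofold import (ContactMatrix, LocusSpec, map_to_bead, parse_locus,
                        parse_variant_id, read_contact_matrix,
                        read_ensemble_xyz, read_eqtl_table, read_tss_bed,
                        write_contact_matrix, write_ensemble_xyz)
from chromofold.genome_io import format_locus
from chromofold.null_ensemble import Conformation, ConformationEnsemble


class TestParseLocus:
    @pytest.mark.parametrize("text,res,n_beads", [
        ("chr2:230805000-231690000", 5000, 177),
        ("chr16:85845000-86580000", 5000, 147),
        ("chr18:10530000-11160000", 5000, 126),
    ])
    def test_printed_loci(self, text, res, n_beads):
        locus = parse_locus(text, res)
        assert locus.n_beads == n_beads

    def test_non_divisible_span_reports_remainder(self):
        with pytest.raises(ValueError, match="remainder 50"):
            parse_locus("chr2:100-250", 100)

    @pytest.mark.parametrize("bad", ["chr2", "chr2:10", "chr2:a-b", ""])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_locus(bad, 5000)

    @given(start=st.integers(0, 10**8), n=st.integers(2, 500))
    @settings(max_examples=50, deadline=None)
    def test_format_parse_roundtrip(self, start, n):
        locus = LocusSpec("chr7", start, start + n * 5000, 5000)
        assert parse_locus(format_locus(locus), 5000) == locus


class TestVariantId:
    def test_gtex_dialect(self):
        assert parse_variant_id("chr16_86531581_A_T_b38") == \
            ("chr16", 86531581, "A", "T", "b38")

    def test_minimal(self):
        assert parse_variant_id("chr1_1_G_C_b38") == ("chr1", 1, "G", "C", "b38")

    @pytest.mark.parametrize("bad", ["chr1_xx_G_C_b38", "chr1_1_G_C",
                                     "chr1_1_G_C_b38_extra", "chr1_0_G_C_b38"])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            parse_variant_id(bad)


class TestMapToBead:
    def test_locus_ii_variant_bead(self):
        # floor((86531581 - 1 - 85845000) / 5000) checked by direct arithmetic
        locus = parse_locus("chr16:85845000-86580000", 5000)
        assert map_to_bead(86531581, locus) == 137
        assert (86531581 - 1 - 85845000) // 5000 == 137

    def test_window_edges(self, locus20):
        assert map_to_bead(locus20.start + 1, locus20) == 0
        assert map_to_bead(locus20.end, locus20) == locus20.n_beads - 1
        with pytest.raises(ValueError):
            map_to_bead(locus20.end + 1, locus20)
        with pytest.raises(ValueError):
            map_to_bead(locus20.start, locus20)

    def test_nondecreasing_and_surjective(self, locus20):
        beads = [map_to_bead(p, locus20)
                 for p in range(locus20.start + 1, locus20.end + 1, 997)]
        assert beads == sorted(beads)
        all_beads = {map_to_bead(p, locus20)
                     for p in range(locus20.start + 1, locus20.end + 1, 1000)}
        assert all_beads == set(range(locus20.n_beads))


class TestContactMatrixIO:
    def test_single_triplet_mirrored(self, tmp_path):
        locus = parse_locus("chr2:230805000-231690000", 5000)
        p = tmp_path / "one.tsv"
        p.write_text("230805000\t230810000\t7\n")
        m = read_contact_matrix(p, locus)
        assert m.values[0, 1] == 7 and m.values[1, 0] == 7
        assert m.values.sum() == 14

    def test_empty_file_is_zero_matrix(self, tmp_path, locus20):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        m = read_contact_matrix(p, locus20)
        assert m.values.sum() == 0 and m.kind == "counts"

    def test_roundtrip_random_symmetric(self, tmp_path):
        locus = LocusSpec("chr1", 0, 50000, 5000)
        rng = np.random.default_rng(0)
        c = rng.integers(0, 50, size=(10, 10))
        values = np.triu(c) + np.triu(c, 1).T
        m = ContactMatrix(locus, values.astype(float), "counts")
        path = tmp_path / "m.tsv"
        write_contact_matrix(m, path)
        m2 = read_contact_matrix(path, locus)
        np.testing.assert_array_equal(m.values, m2.values)

    def test_dense_autodetect(self, tmp_path):
        locus = LocusSpec("chr1", 0, 20000, 5000)
        vals = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6],
                         [3, 5, 6, 0]], dtype=float)
        p = tmp_path / "dense.txt"
        p.write_text("\n".join(" ".join(str(int(x)) for x in row)
                               for row in vals))
        m = read_contact_matrix(p, locus)
        np.testing.assert_array_equal(m.values, vals)

    @pytest.mark.parametrize("line", ["230800000\t230810000\t7",  # off locus
                                      "230805001\t230810000\t7",  # off grid
                                      "230805000\t230810000\t-1"])  # negative
    def test_bad_triplets(self, tmp_path, line):
        locus = parse_locus("chr2:230805000-231690000", 5000)
        p = tmp_path / "bad.tsv"
        p.write_text(line + "\n")
        with pytest.raises(ValueError):
            read_contact_matrix(p, locus)

    def test_symmetry_enforced(self, locus20):
        vals = np.zeros((20, 20))
        vals[0, 1] = 3  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            ContactMatrix(locus20, vals, "counts")


class TestEqtlAndBed:
    def test_eqtl_row(self, tmp_path):
        p = tmp_path / "eqtl.tsv"
        p.write_text("variant_id\tgene_id\tslope\ttissue\n"
                     "chr16_86531581_A_T_b38\tMTHFSD\t-1.9\tlymphocytes\n")
        recs = read_eqtl_table(p)
        assert len(recs) == 1
        r = recs[0]
        assert r.nes == -1.9 and abs(r.nes) == 1.9
        assert r.pos == 86531581 and r.gene_id == "MTHFSD"

    def test_empty_table(self, tmp_path):
        p = tmp_path / "eqtl.tsv"
        p.write_text("variant_id\tgene_id\tslope\n")
        assert read_eqtl_table(p) == []

    def test_missing_column(self, tmp_path):
        p = tmp_path / "eqtl.tsv"
        p.write_text("variant_id\tgene_id\n")
        with pytest.raises(ValueError, match="slope"):
            read_eqtl_table(p)

    def test_tss_strand_convention(self, tmp_path):
        p = tmp_path / "tss.bed"
        p.write_text("chr16\t86510000\t86515000\tMTHFSD\t0\t+\n"
                     "chr16\t86510000\t86515000\tOTHER\t0\t-\n")
        anns = read_tss_bed(p)
        assert anns[0].tss == 86510001   # + strand: start + 1
        assert anns[1].tss == 86515000   # - strand: end


class TestEnsembleXyz:
    def test_two_bead_roundtrip(self, tmp_path):
        ens = ConformationEnsemble(
            [Conformation(np.array([[0., 0., 0.], [30., 0., 0.]]), -1.5)])
        p = tmp_path / "e.xyz"
        write_ensemble_xyz(ens, p)
        assert len(p.read_text().splitlines()) == 3
        back = read_ensemble_xyz(p)
        np.testing.assert_allclose(back.conformations[0].coords,
                                   ens.conformations[0].coords)
        assert back.conformations[0].log_weight == -1.5

    def test_random_roundtrip_precision(self, tmp_path):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-300, 300, size=(100, 15, 3))
        ens = ConformationEnsemble.from_arrays(
            coords, rng.normal(size=100), run_ids=np.arange(100) % 7)
        p = tmp_path / "e.xyz"
        write_ensemble_xyz(ens, p)
        back = read_ensemble_xyz(p)
        err = np.abs(back.coords_array() - coords).max()
        assert err <= 1e-3
        np.testing.assert_array_equal(back.run_ids, ens.run_ids)

    def test_empty_ensemble_refused(self, tmp_path):
        with pytest.raises(ValueError):
            ConformationEnsemble([])

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "e.xyz"
        p.write_text("#model 0 wt 0\n0 0 0\n")
        with pytest.raises(ValueError, match="header"):
            read_ensemble_xyz(p)
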