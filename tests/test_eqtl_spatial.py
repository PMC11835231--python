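import numpy as np
import pytest

from chromofold import (EqtlRecord, GeneAnnotation, LocusSpec, classify_pairs,
                        compare_nes_distributions, detect_many_body)
from chromofold.eqtl_spatial import PairContactResult

from conftest import ensemble_from_coords


def _record(pos, gene, nes, locus):
    vid = f"{locus.chrom}_{pos}_A_T_b38"
    return EqtlRecord(vid, locus.chrom, pos, "A", "T", gene, nes)


def _fixed_distance_ensemble(n_beads, pair_distances, n_conf=4):
    """All conformations identical: bead b at x = b * spacing except that
    listed pairs (i, j) sit exactly at the requested distance."""
    coords = np.zeros((n_conf, n_beads, 3))
    coords[:, :, 0] = np.arange(n_beads) * 1000.0
    for (i, j), d in pair_distances.items():
        coords[:, j, 0] = coords[:, i, 0]
        coords[:, j, 1] = d
    return ensemble_from_coords(coords)


class TestClassifyPairs:
    def _locus(self, n=30):
        return LocusSpec("chr9", 0, n * 5000, 5000)

    def _setup(self, locus, gene_bead, eqtl_bead, nes=1.0):
        gene = f"G{gene_bead}"
        tss = locus.start + gene_bead * 5000 + 2501
        pos = locus.start + eqtl_bead * 5000 + 2501
        return ([_record(pos, gene, nes, locus)],
                [GeneAnnotation(gene, locus.chrom, tss)])

    def test_below_threshold_is_contact(self):
        locus = self._locus()
        ens = _fixed_distance_ensemble(30, {(2, 10): 50.0})
        recs, anns = self._setup(locus, 2, 10)
        results, _ = classify_pairs(ens, recs, anns, locus)
        assert results[0].physical_contact is True
        assert results[0].median_distance == pytest.approx(50.0)

    def test_exactly_at_threshold_is_not_contact(self):
        # the rule is strictly below 80 nm
        locus = self._locus()
        ens = _fixed_distance_ensemble(30, {(2, 10): 80.0})
        recs, anns = self._setup(locus, 2, 10)
        results, _ = classify_pairs(ens, recs, anns, locus)
        assert results[0].physical_contact is False

    def test_unmappable_records_skipped(self):
        locus = self._locus()
        ens = _fixed_distance_ensemble(30, {(2, 10): 50.0})
        recs, anns = self._setup(locus, 2, 10)
        recs.append(_record(10**9, "G2", 0.5, locus))  # outside the window
        results, skipped = classify_pairs(ens, recs, anns, locus)
        assert len(results) == 1 and len(skipped) == 1

    def test_rigid_motion_invariance(self):
        locus = self._locus()
        ens = _fixed_distance_ensemble(30, {(2, 10): 50.0, (4, 20): 200.0})
        recs = [_record(locus.start + 10 * 5000 + 1, "A", 1.0, locus),
                _record(locus.start + 20 * 5000 + 1, "B", -0.5, locus)]
        anns = [GeneAnnotation("A", locus.chrom, locus.start + 2 * 5000 + 1),
                GeneAnnotation("B", locus.chrom, locus.start + 4 * 5000 + 1)]
        before, _ = classify_pairs(ens, recs, anns, locus)
        # rotate + translate every conformation
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = ensemble_from_coords(ens.coords_array() @ R.T + [5.0, -3.0, 11.0])
        after, _ = classify_pairs(moved, recs, anns, locus)
        assert [r.physical_contact for r in before] == \
            [r.physical_contact for r in after]
        for x, y in zip(before, after):
            assert x.median_distance == pytest.approx(y.median_distance)


class TestManyBody:
    def _triad_ensemble(self, d01, d02, d12):
        # place three beads of interest at pairwise distances (d01, d02, d12)
        # via triangle coordinates; remaining beads far away
        x2 = (d01 ** 2 + d02 ** 2 - d12 ** 2) / (2 * d01)
        y2 = np.sqrt(max(d02 ** 2 - x2 ** 2, 0.0))
        coords = np.zeros((2, 10, 3))
        coords[:, :, 0] = np.arange(10) * 1000.0
        coords[:, 0] = [0, 0, 0]
        coords[:, 1] = [d01, 0, 0]
        coords[:, 2] = [x2, y2, 0]
        return ensemble_from_coords(coords)

    def test_boundary_medians_classified(self):
        ens = self._triad_ensemble(80.0, 84.0, 85.0)
        unit = detect_many_body(ens, [0, 1, 2])
        off = unit.median_matrix[np.triu_indices(3, 1)]
        np.testing.assert_allclose(sorted(off), [80.0, 84.0, 85.0])
        assert unit.classified is True

    def test_all_coincident_classified(self):
        ens = ensemble_from_coords(np.zeros((3, 5, 3)))
        assert detect_many_body(ens, [0, 2, 4]).classified is True

    def test_one_far_median_fails(self):
        ens = self._triad_ensemble(80.0, 84.0, 120.0)
        assert detect_many_body(ens, [0, 1, 2]).classified is False

    def test_just_over_tolerance_fails(self):
        ens = self._triad_ensemble(80.0, 84.0, 85.5)
        assert detect_many_body(ens, [0, 1, 2]).classified is False

    def test_duplicates_rejected(self, null_small):
        with pytest.raises(ValueError):
            detect_many_body(null_small, [1, 1, 2])
        with pytest.raises(ValueError):
            detect_many_body(null_small, [1, 2])


def _results(contact_nes, free_nes):
    locus = LocusSpec("chr1", 0, 100000, 5000)
    out = []
    for k, nes in enumerate(contact_nes):
        out.append(PairContactResult(_record(1 + k, f"C{k}", nes, locus),
                                     0, 1, 50.0, True))
    for k, nes in enumerate(free_nes):
        out.append(PairContactResult(_record(100 + k, f"F{k}", nes, locus),
                                     0, 1, 150.0, False))
    return out


class TestCompareNes:
    def test_exact_small_sample_p(self):
        res = compare_nes_distributions(_results([3, 4, 5], [0, 1, 2]))
        assert res["p_value"] == pytest.approx(0.1)
        assert res["n_contact"] == 3 and res["n_free"] == 3

    def test_absolute_values_used(self):
        res = compare_nes_distributions(_results([-1.9], [0.5]))
        assert res["median_contact"] == pytest.approx(1.9)

    def test_identical_groups_null_centered(self):
        vals = [0.5, 1.0, 1.5, 2.0]
        res = compare_nes_distributions(_results(vals, vals))
        assert res["median_contact"] == res["median_free"]
        # U at its null center n1*n2/2
        assert res["statistic"] == pytest.approx(len(vals) ** 2 / 2)

    def test_empty_group_informative_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_nes_distributions(_results([1.0], []))

    def test_power_at_planted_shift(self):
        rng = np.random.default_rng(0)
        contact = np.abs(rng.normal(1.2, 0.3, 100))
        free = np.abs(rng.normal(0.6, 0.3, 100))
        res = compare_nes_distributions(_results(contact, free))
        assert res["p_value"] < 0.01

    def test_welch_alternative(self):
        res = compare_nes_distributions(_results([3, 4, 5], [0, 1, 2]),
                                        method="welch")
        assert res["statistic_name"] == "t" and res["p_value"] < 0.05
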