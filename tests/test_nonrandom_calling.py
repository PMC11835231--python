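import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromofold import (ContactMatrix, LocusSpec, bh_adjust, bootstrap_pvalues,
                        call_nonrandom, contact_frequency_matrix,
                        observed_probability)
from chromofold.nonrandom_calling import significant_fraction
from chromofold.nonrandom_calling import tested_pairs as all_tested_pairs

from conftest import ensemble_from_coords


def _locus(n):
    return LocusSpec("chr1", 0, n * 5000, 5000)


class TestObservedProbability:
    def test_scale_cancellation(self, null_small):
        null_p = contact_frequency_matrix(null_small)
        k = 40.0
        counts_vals = np.round(k * null_p.values)
        np.fill_diagonal(counts_vals, 0)
        counts = ContactMatrix(null_p.locus, counts_vals, "counts")
        # rebuild a null whose probabilities equal counts/k exactly
        exact = ContactMatrix(null_p.locus, counts_vals / k, "probability")
        q = observed_probability(counts, exact)
        off = ~np.eye(30, dtype=bool)
        np.testing.assert_allclose(q.values[off], exact.values[off],
                                   atol=1e-9)

    def test_adjacent_only_counts(self, null_small):
        null_p = contact_frequency_matrix(null_small)
        vals = np.zeros((30, 30))
        for i in range(29):
            vals[i, i + 1] = vals[i + 1, i] = 5
        q = observed_probability(ContactMatrix(null_p.locus, vals, "counts"),
                                 null_p)
        assert (q.values[np.triu_indices(30, k=2)] == 0).all()

    def test_toy_scale(self):
        locus = _locus(4)
        counts = np.zeros((4, 4))
        for i in range(3):
            counts[i, i + 1] = counts[i + 1, i] = 10
        counts[0, 2] = counts[2, 0] = 4
        null_vals = np.full((4, 4), 0.5)
        for i in range(3):
            null_vals[i, i + 1] = null_vals[i + 1, i] = 1.0
        np.fill_diagonal(null_vals, 1.0)
        q = observed_probability(
            ContactMatrix(locus, counts, "counts"),
            ContactMatrix(locus, null_vals, "probability"))
        # scale = 1.0 / 10 -> count 4 maps to 0.4
        assert q.values[0, 2] == pytest.approx(0.4)

    def test_zero_adjacent_cannot_calibrate(self, null_small):
        null_p = contact_frequency_matrix(null_small)
        zero = ContactMatrix(null_p.locus, np.zeros((30, 30)), "counts")
        with pytest.raises(ValueError, match="calibrate"):
            observed_probability(zero, null_p)


class TestBootstrapPvalues:
    def test_zero_observation_p_one(self, null_small):
        q = contact_frequency_matrix(null_small)
        q.values[np.triu_indices(30, k=2)] = 0.0
        q.values[np.tril_indices(30, k=-2)] = 0.0
        p = bootstrap_pvalues(q, null_small, B=100, seed=0)
        assert (p == 1.0).all()

    def test_saturated_observation_floor(self, null_small):
        q = contact_frequency_matrix(null_small)
        q.values[:, :] = 1.0
        B = 100
        p = bootstrap_pvalues(q, null_small, B=B, seed=0)
        pairs = all_tested_pairs(30)
        long_range = pairs[:, 1] - pairs[:, 0] > 10
        np.testing.assert_allclose(p[long_range], 1 / (B + 1))

    def test_step_function_in_observed_value(self, null_small):
        # p_raw depends on the observed value only through its position
        # among the replicate order statistics
        q = contact_frequency_matrix(null_small)
        pairs = np.array([[0, 15]])
        p1 = bootstrap_pvalues(q, null_small, B=50, seed=3, pairs=pairs)
        q.values[0, 15] += 1e-12  # still between the same order statistics
        p2 = bootstrap_pvalues(q, null_small, B=50, seed=3, pairs=pairs)
        assert p1[0] == p2[0]

    def test_self_calibration_uniform(self, null_medium):
        """Observations drawn from the null's own replicate distribution
        get uniform raw p-values."""
        q = contact_frequency_matrix(null_medium)
        pairs = all_tested_pairs(50)
        # one replicate drawn with an independent seed plays the observation
        from chromofold.nonrandom_calling import (_contact_indicators,
                                                  _replicate_frequencies)
        rng = np.random.default_rng(99)
        ind = _contact_indicators(null_medium, pairs, 80.0).astype(float)
        obs_freq = _replicate_frequencies(null_medium, ind, 1, rng)[0]
        q.values[pairs[:, 0], pairs[:, 1]] = obs_freq
        q.values[pairs[:, 1], pairs[:, 0]] = obs_freq
        p = bootstrap_pvalues(q, null_medium, B=400, seed=5, pairs=pairs)
        frac = (p < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_bad_args(self, null_small):
        q = contact_frequency_matrix(null_small)
        with pytest.raises(ValueError):
            bootstrap_pvalues(q, null_small, B=0)


class TestBHAdjust:
    def test_hand_case(self):
        adj = bh_adjust([0.005, 0.02, 0.03, 0.05])
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.05])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.3] * 7), [0.3] * 7)

    def test_single(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(1e-9, 1.0, size=m)
            ours = bh_adjust(p)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        # monotone: a smaller p never gets a larger adjusted value
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallNonrandom:
    def test_alpha_zero_no_calls(self, null_small):
        from chromofold.synthetic_fixtures import synth_hic_from_ensemble

        counts = synth_hic_from_ensemble(null_small, depth=2e4, seed=1)
        calls = call_nonrandom(counts, null_small, alpha=0.0, B=100, seed=2)
        assert significant_fraction(calls) == 0.0

    def test_planted_saturated_pairs_all_flagged(self, null_medium):
        from chromofold.synthetic_fixtures import synth_hic_from_ensemble

        counts = synth_hic_from_ensemble(null_medium, depth=2e5, seed=3)
        rng = np.random.default_rng(4)
        planted = set()
        while len(planted) < 20:
            i = int(rng.integers(0, 30))
            j = i + int(rng.integers(10, 20))
            planted.add((i, j))
        adj_mean = np.diag(counts.values, 1).mean()
        for i, j in planted:
            counts.values[i, j] = counts.values[j, i] = adj_mean
        # B large enough that the add-one floor clears the BH threshold
        calls = call_nonrandom(counts, null_medium, alpha=0.05, B=2000, seed=5)
        flagged = {(c.i, c.j) for c in calls if c.significant}
        assert planted <= flagged

    def test_neighbor_pairs_excluded(self, null_small):
        from chromofold.synthetic_fixtures import synth_hic_from_ensemble

        counts = synth_hic_from_ensemble(null_small, depth=2e4, seed=6)
        calls = call_nonrandom(counts, null_small, B=100, seed=7)
        assert all(c.j - c.i >= 2 for c in calls)
        assert len(calls) == len(all_tested_pairs(30))
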