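"""Normalization, filtering, dispersion estimation and the NB exact test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binomtest, nbinom

import evcargo as ev
from conftest import make_matrix, two_group_matrix


class TestCpm:
    def test_single_sample_arithmetic(self):
        m = make_matrix(np.array([[3], [1]]))
        assert np.allclose(ev.cpm(m)[:, 0], [750_000, 250_000])

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 50, size=(30, 4)))
        assert np.allclose(ev.cpm(m).sum(axis=0), 1e6)

    def test_depth_invariance(self):
        counts = np.array([[5, 5], [15, 15]])
        doubled = counts.copy()
        doubled[:, 1] *= 2
        c1 = ev.cpm(make_matrix(counts))
        c2 = ev.cpm(make_matrix(doubled))
        assert np.allclose(c1[:, 1], c2[:, 1])

    def test_zero_library_errors(self):
        m = make_matrix(np.array([[0, 1], [0, 2]]))
        with pytest.raises(ev.ValidationError, match="library size"):
            ev.cpm(m)


class TestFilterByCpm:
    def test_all_zero_feature_dropped_and_cutoff_zero_keeps_all(self):
        counts = np.vstack([np.zeros(4, dtype=int), np.full(4, 10)])
        m = make_matrix(counts)
        kept, dropped = ev.filter_by_cpm(m, cutoff=2.0, min_samples=2)
        assert dropped == ["F001"]
        kept, dropped = ev.filter_by_cpm(m, cutoff=0.0, min_samples=2)
        assert dropped == [] and len(kept) == 2

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(10, 6))
        counts[0] += 100  # keep all libraries positive
        m = make_matrix(counts)
        kept, dropped = ev.filter_by_cpm(m, cutoff=2.0, min_samples=3)
        lib = counts.sum(axis=0)
        manual_kept = []
        for i, fid in enumerate(m.feature_ids):
            n_pass = sum(counts[i, j] / lib[j] * 1e6 >= 2.0 for j in range(6))
            if n_pass >= 3:
                manual_kept.append(fid)
        assert kept == manual_kept
        assert set(kept) | set(dropped) == set(m.feature_ids)
        assert not set(kept) & set(dropped)

    def test_min_samples_beyond_design_errors(self):
        m = make_matrix(np.array([[1, 2]]))
        with pytest.raises(ev.ValidationError):
            ev.filter_by_cpm(m, min_samples=5)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 80, 13, 200, 44])
        m = make_matrix(np.column_stack([col] * 3))
        f = ev.tmm_factors(m)
        assert np.allclose(f.factors, 1.0)

    def test_pure_depth_change_returns_unit_factor(self):
        rng = np.random.default_rng(2)
        col = rng.integers(10, 500, size=200)
        m = make_matrix(np.column_stack([col, col * 2]))
        f = ev.tmm_factors(m)
        assert np.allclose(f.factors, 1.0, atol=1e-8)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.integers(1, 400, size=(150, 5)))
        f = ev.tmm_factors(m)
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_small_instance_matches_hand_computation(self):
        # 4 features x 2 samples; reproduce the doubly-trimmed weighted mean
        counts = np.array([[10, 40], [20, 20], [30, 90], [40, 10]])
        m = make_matrix(counts)
        f = ev.tmm_factors(m, trim_m=0.3, trim_a=0.05)
        lib = counts.sum(axis=0).astype(float)
        q75 = [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(2)]
        ref = int(np.argmin(np.abs(np.array(q75) - np.mean(q75))))
        other = 1 - ref
        p, p_ref = counts[:, other] / lib[other], counts[:, ref] / lib[ref]
        mvals = np.log2(p / p_ref)
        w = ((lib[other] - counts[:, other]) / (lib[other] * counts[:, other])
             + (lib[ref] - counts[:, ref]) / (lib[ref] * counts[:, ref]))
        k = 4
        lo_m, hi_m = np.floor(k * 0.3) + 1, k + 1 - (np.floor(k * 0.3) + 1)
        lo_a = np.floor(k * 0.05) + 1
        rank_m = np.argsort(np.argsort(mvals)) + 1
        mask = (rank_m >= lo_m) & (rank_m <= hi_m)  # A-trim keeps everything here
        expected = 2.0 ** (np.sum(mvals[mask] / w[mask]) / np.sum(1.0 / w[mask]))
        expected_pair = np.array([1.0, expected]) if ref == 0 else np.array([expected, 1.0])
        expected_pair /= np.exp(np.mean(np.log(expected_pair)))
        assert np.allclose(f.factors, expected_pair, atol=1e-10)


class TestCommonDispersion:
    def _simulate(self, phi, n_features=3000, mean=200, seed=0):
        rng = np.random.default_rng(seed)
        mu = np.full((n_features, 6), float(mean))
        if phi == 0:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / phi
            counts = rng.negative_binomial(r, r / (r + mu))
        return two_group_matrix(counts[:, :3], counts[:, 3:])

    def test_poisson_data_gives_near_zero(self):
        m = self._simulate(0.0, seed=4)
        groups = [s.phenotype for s in m.samples]
        assert ev.estimate_common_dispersion(m, groups) <= 0.02

    def test_recovers_planted_dispersion(self):
        m = self._simulate(0.1, seed=5)
        groups = [s.phenotype for s in m.samples]
        assert 0.07 <= ev.estimate_common_dispersion(m, groups) <= 0.13

    def test_constant_counts_give_zero(self):
        m = two_group_matrix(np.full((20, 3), 50), np.full((20, 3), 50))
        groups = [s.phenotype for s in m.samples]
        assert ev.estimate_common_dispersion(m, groups) == 0.0

    def test_no_replication_errors(self):
        m = make_matrix(np.array([[5, 9], [1, 2]]))
        with pytest.raises(ev.ValidationError, match="replicate"):
            ev.estimate_common_dispersion(m, ["a", "b"])


class TestExactTest:
    def test_identical_groups_are_null(self):
        m = two_group_matrix(np.full((3, 3), 5), np.full((3, 3), 5))
        res = ev.nb_exact_test(m, m.labels[:3], m.labels[3:], dispersion=0.1)
        assert np.allclose(res["logFC"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_swapping_groups_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(6)
        m = two_group_matrix(rng.integers(5, 200, (40, 3)),
                             rng.integers(5, 200, (40, 3)))
        fwd = ev.nb_exact_test(m, m.labels[:3], m.labels[3:], dispersion=0.1)
        rev = ev.nb_exact_test(m, m.labels[3:], m.labels[:3], dispersion=0.1)
        assert np.allclose(fwd["logFC"], -rev["logFC"], atol=1e-9)
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_zero_total_convention(self):
        assert ev.exact_nb_pvalue(0, 0, 3, 3, 0.1) == 1.0

    @pytest.mark.parametrize("t", [1, 7, 24, 50])
    def test_poisson_limit_equals_exact_binomial(self, t):
        for y_a in range(t + 1):
            ours = ev.exact_nb_pvalue(y_a, t - y_a, 3, 3, phi=0.0)
            ref = binomtest(y_a, t, 0.5).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("phi", [0.1, 1.0])
    @pytest.mark.parametrize("t", [3, 12, 35])
    def test_matches_direct_nb_enumeration(self, phi, t):
        n_a, n_b, mu = 3, 3, 4.2   # conditional law must not depend on mu
        r_a, r_b = n_a / phi, n_b / phi
        a = np.arange(t + 1)
        probs = (nbinom.pmf(a, r_a, r_a / (r_a + n_a * mu))
                 * nbinom.pmf(t - a, r_b, r_b / (r_b + n_b * mu)))
        probs /= probs.sum()
        for y_a in range(t + 1):
            expected = probs[probs <= probs[y_a] * (1 + 1e-7)].sum()
            assert ev.exact_nb_pvalue(y_a, t - y_a, n_a, n_b, phi) == pytest.approx(
                min(1.0, expected), abs=1e-10)

    def test_unequal_group_sizes_against_enumeration(self):
        phi, n_a, n_b, t = 0.2, 2, 3, 20
        r_a, r_b = n_a / phi, n_b / phi
        a = np.arange(t + 1)
        probs = (nbinom.pmf(a, r_a, r_a / (r_a + n_a * 3.0))
                 * nbinom.pmf(t - a, r_b, r_b / (r_b + n_b * 3.0)))
        probs /= probs.sum()
        for y_a in range(t + 1):
            expected = probs[probs <= probs[y_a] * (1 + 1e-7)].sum()
            assert ev.exact_nb_pvalue(y_a, t - y_a, n_a, n_b, phi) == pytest.approx(
                min(1.0, expected), abs=1e-10)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(ev.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values(self):
        assert ev.bh_adjust([0.03])[0] == pytest.approx(0.03)
        assert np.allclose(ev.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ev.ValidationError):
            ev.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, pvals):
        adj = ev.bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)


class TestDeContrast:
    def test_untested_features_carry_no_pvalue(self, default_dataset):
        matrix, _, _ = default_dataset
        res = ev.de_contrast(matrix, "NSCLC", "cell")
        untested = res[~res["tested"]]
        assert untested["p_value"].isna().all()
        tested = res[res["tested"]]
        assert ((tested["p_value"] >= 0) & (tested["p_value"] <= 1)).all()
        assert (tested["adjusted_p"] >= tested["p_value"] - 1e-12).all()

    def test_power_monotone_in_effect_size(self):
        """Rejection rate does not decrease as the planted |logFC| grows."""
        rng = np.random.default_rng(8)
        n, n_de, mean, phi = 400, 40, 150, 0.1
        r = 1.0 / phi
        power = []
        for lfc in [0.5, 1.0, 2.0]:
            mu_a = np.full((n, 3), float(mean))
            mu_b = mu_a.copy()
            mu_b[:n_de] *= 2.0 ** lfc
            counts_a = rng.negative_binomial(r, r / (r + mu_a))
            counts_b = rng.negative_binomial(r, r / (r + mu_b))
            m = two_group_matrix(counts_a, counts_b)
            res = ev.nb_exact_test(m, m.labels[:3], m.labels[3:], dispersion=phi)
            power.append((res["p_value"].to_numpy()[:n_de] < 0.05).mean())
        assert power[0] <= power[1] <= power[2]
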