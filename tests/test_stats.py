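import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from scalerp import stats
from scalerp.stats import (
    NeighborGraph,
    cluster_permutation_test,
    default_neighbors,
    one_sample_tmap,
    paired_t_cohens_d,
    pca_latency,
    rm_anova,
)

ELECTRODES = ["Fz", "FCz", "Cz", "CPz", "Pz", "C3", "C4", "Oz"]


class TestTMap:
    def test_identical_nonzero_constant_infinite_t(self):
        data = np.full((5, 2, 10), 3.0)
        tm = one_sample_tmap(data)
        assert np.isinf(tm.t).all()
        assert tm.zero_variance.all()

    def test_sign_flip_negates_t(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(12, 3, 20))
        t1 = one_sample_tmap(data).t
        t2 = one_sample_tmap(-data).t
        np.testing.assert_allclose(t2, -t1, atol=1e-12)

    def test_monte_carlo_calibration(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 10, 400))
        tm = one_sample_tmap(data, alpha=0.05)
        frac = np.mean(np.abs(tm.t) > tm.critical_t)
        n_cells = 10 * 400
        lo, hi = scipy.stats.binom.interval(0.99, n_cells, 0.05)
        assert lo / n_cells <= frac <= hi / n_cells

    def test_degrees_of_freedom_and_critical_value(self):
        data = np.random.default_rng(2).normal(size=(20, 2, 5))
        tm = one_sample_tmap(data, alpha=0.05)
        assert tm.df == 19
        np.testing.assert_allclose(
            tm.critical_t, scipy.stats.t.ppf(0.975, 19), atol=1e-12
        )

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            one_sample_tmap(np.zeros((2, 2, 5)))


class TestNeighborGraph:
    def test_bundled_template_is_symmetric(self):
        g = default_neighbors()
        for e, nbrs in g.adjacency.items():
            for n in nbrs:
                assert e in g.adjacency[n]

    def test_covers_analysis_set(self):
        g = default_neighbors()
        assert g.covers(ELECTRODES)
        assert not g.covers(["NOT_AN_ELECTRODE"])

    def test_load_symmetrizes(self, tmp_path):
        p = tmp_path / "nbr.txt"
        p.write_text("A: B\nC:\n# comment\n")
        g = stats.load_neighbors(p)
        assert g.neighbors("B") == {"A"}
        assert g.neighbors("C") == set()


class TestClusterPermutation:
    def test_all_zero_data_no_clusters(self):
        data = np.zeros((10, len(ELECTRODES), 50))
        res = cluster_permutation_test(
            data, default_neighbors(), ELECTRODES, n_perm=100, seed=0
        )
        assert res.clusters == []
        assert not res.any_significant

    def test_defaults_match_convention(self):
        import inspect

        sig = inspect.signature(cluster_permutation_test)
        assert sig.parameters["n_perm"].default == 1000
        assert sig.parameters["alpha_cluster"].default == 0.05

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((20, len(ELECTRODES), 60))
        data[:, :, 20:40] += 2.0  # common effect on all electrodes
        res = cluster_permutation_test(
            data, default_neighbors(), ELECTRODES, n_perm=200, seed=1
        )
        assert res.any_significant
        sig = [c for c in res.clusters if c.significant]
        assert any(c.start_fraction <= 20 / 60 + 0.1 and c.end_fraction >= 40 / 60 - 0.1
                   for c in sig)

    def test_cluster_extents_are_fractions(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((15, len(ELECTRODES), 40)) + 1.5
        res = cluster_permutation_test(
            data, default_neighbors(), ELECTRODES, n_perm=100, seed=2
        )
        for c in res.clusters:
            assert 0.0 <= c.start_fraction < c.end_fraction <= 1.0
            assert 0.0 < c.p_value <= 1.0

    def test_raising_threshold_never_enlarges_clusters(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((15, len(ELECTRODES), 80))
        data[:, :, 30:50] += 1.0
        res_loose = cluster_permutation_test(
            data, default_neighbors(), ELECTRODES, alpha_cell=0.05,
            n_perm=100, seed=3,
        )
        res_tight = cluster_permutation_test(
            data, default_neighbors(), ELECTRODES, alpha_cell=0.001,
            n_perm=100, seed=3,
        )
        loose = {(c.seed_electrode): (c.start_fraction, c.end_fraction)
                 for c in res_loose.clusters}
        for c in res_tight.clusters:
            if c.seed_electrode in loose:
                s, e = loose[c.seed_electrode]
                # tight run must sit inside some loose run of the same seed
                runs = [(x.start_fraction, x.end_fraction)
                        for x in res_loose.clusters
                        if x.seed_electrode == c.seed_electrode]
                assert any(s0 <= c.start_fraction and c.end_fraction <= e0
                           for s0, e0 in runs)

    def test_per_cluster_scope_available(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((12, len(ELECTRODES), 30)) + 0.8
        res = cluster_permutation_test(
            data, default_neighbors(), ELECTRODES, n_perm=100, seed=4,
            null_scope="per_cluster",
        )
        assert res.null_max_mass.shape == (len(ELECTRODES), 100)

    def test_permutation_p_validity_small_null_sim(self):
        # loose nested check: under the sign-flip null the rejection rate at
        # alpha=0.1 stays below alpha plus Monte-Carlo slack
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 40
        for _ in range(reps):
            data = rng.standard_normal((12, 4, 30))
            res = cluster_permutation_test(
                data, default_neighbors(), ["Fz", "Cz", "Pz", "Oz"],
                n_perm=100, alpha_cluster=0.1, seed=int(rng.integers(1 << 31)),
            )
            rejections += res.any_significant
        assert rejections / reps <= 0.1 + 0.12

    def test_argument_validation(self):
        data = np.zeros((5, 2, 10))
        with pytest.raises(ValueError):
            cluster_permutation_test(data, default_neighbors(), ["Fz", "Cz"],
                                     n_perm=10)
        with pytest.raises(ValueError):
            cluster_permutation_test(data, default_neighbors(), ["Fz"],
                                     n_perm=100)
        with pytest.raises(ValueError, match="missing"):
            cluster_permutation_test(data, NeighborGraph({}), ["Fz", "Cz"],
                                     n_perm=100)


class TestPairedT:
    def test_equal_inputs_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        res = paired_t_cohens_d(a, a)
        assert res.mean_diff == 0.0
        assert np.isnan(res.t_statistic)  # sd_diff = 0 -> undefined, flagged

    def test_four_value_hand_oracle(self):
        b = np.zeros(4)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t_cohens_d(a, b)
        sd = np.std([1, 2, 3, 4], ddof=1)
        np.testing.assert_allclose(res.mean_diff, 2.5)
        np.testing.assert_allclose(res.sd_diff, sd)
        np.testing.assert_allclose(res.cohens_d, 2.5 / sd)
        np.testing.assert_allclose(res.t_statistic, 2.5 / (sd / 2.0))
        ref = scipy.stats.ttest_rel(a, b)
        np.testing.assert_allclose(res.t_statistic, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(res.p, ref.pvalue, atol=1e-12)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(size=10)
        r1 = paired_t_cohens_d(a, b)
        r2 = paired_t_cohens_d(b, a)
        np.testing.assert_allclose(r1.t_statistic, -r2.t_statistic, atol=1e-12)
        np.testing.assert_allclose(r1.cohens_d, -r2.cohens_d, atol=1e-12)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            paired_t_cohens_d([1.0], [2.0])


def gaussian_bump(n_time, center, width=8.0):
    t = np.arange(n_time, dtype=float)
    return np.exp(-0.5 * ((t - center) / width) ** 2)


class TestPcaLatency:
    def test_identical_bins_equal_scores(self):
        wave = gaussian_bump(100, 50)
        data = np.tile(wave, (3, 4, 1))
        data += 0.01 * np.random.default_rng(9).normal(size=data.shape)
        res = pca_latency(data)
        assert np.ptp(res.pc2_scores) < 0.2 * np.abs(res.scores[:, 0]).mean()

    def test_shifted_bumps_pc1_shape_pc2_derivative_monotone_scores(self):
        shifts = [-5.0, 0.0, 5.0]
        data = np.stack(
            [np.stack([gaussian_bump(120, 60 + s) for _ in range(4)])
             for s in shifts]
        )
        res = pca_latency(data)
        mean_wave = data.mean(axis=(0, 1))
        mean_c = mean_wave - mean_wave.mean()
        r1 = np.corrcoef(res.pc1, mean_c)[0, 1]
        assert r1 >= 0.95
        d1 = np.diff(res.pc1)
        r2 = np.corrcoef(res.pc2[:-1], d1)[0, 1]
        assert r2 >= 0.9
        diffs = np.diff(res.pc2_scores)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_reconstruction_and_variance_identity(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(3, 5, 40))
        res = pca_latency(data)
        M = data.reshape(15, 40)
        M = M - M.mean(axis=1, keepdims=True)
        recon = res.scores @ res.components
        np.testing.assert_allclose(recon, M, atol=1e-10)
        np.testing.assert_allclose(res.variance_explained.sum(),
                                   np.sum(M**2), rtol=1e-10)
        assert (np.diff(res.variance_explained) <= 1e-9).all()

    def test_rank_deficient_flagged(self):
        data = np.tile(gaussian_bump(50, 25), (3, 1, 1))  # rank 1 exactly
        with pytest.raises(ValueError, match="rank"):
            pca_latency(data)

    def test_three_bins_default_shape(self):
        data = np.random.default_rng(11).normal(size=(3, 7, 60))
        res = pca_latency(data)
        assert res.pc2_scores.shape == (3,)


def brute_force_rm_anova(Y):
    """Direct sum-of-squares oracle by explicit loops."""
    n, b = Y.shape
    grand = Y.mean()
    ss_q = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(b))
    ss_s = sum(b * (Y[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((Y[i, j] - grand) ** 2 for i in range(n) for j in range(b))
    ss_sq = ss_tot - ss_q - ss_s
    F = (ss_q / (b - 1)) / (ss_sq / ((b - 1) * (n - 1)))
    return ss_q, ss_s, ss_sq, F


class TestRmAnova:
    def test_identical_columns_zero_effect(self):
        Y = np.tile(np.array([[1.0], [2.0], [5.0], [3.0]]), (1, 3))
        res = rm_anova(Y)
        assert res.ss_effect == 0.0
        assert res.F == 0.0
        assert res.eta_p_sq == 0.0 and res.eta_g_sq == 0.0

    def test_toy_table_matches_brute_force(self):
        Y = np.array(
            [[3.0, 5.0, 4.0], [2.0, 4.0, 6.0], [5.0, 7.0, 6.0], [4.0, 8.0, 9.0]]
        )
        res = rm_anova(Y)
        ss_q, ss_s, ss_sq, F = brute_force_rm_anova(Y)
        np.testing.assert_allclose(res.ss_effect, ss_q, atol=1e-10)
        np.testing.assert_allclose(res.ss_subjects, ss_s, atol=1e-10)
        np.testing.assert_allclose(res.ss_error, ss_sq, atol=1e-10)
        np.testing.assert_allclose(res.F, F, atol=1e-10)
        np.testing.assert_allclose(res.eta_p_sq, ss_q / (ss_q + ss_sq), atol=1e-10)
        np.testing.assert_allclose(
            res.eta_g_sq, ss_q / (ss_q + ss_s + ss_sq), atol=1e-10
        )
        assert res.df_effect == 2 and res.df_error == 6

    def test_per_participant_constant_shifts_only_ss_subjects(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(6, 3))
        shift = rng.normal(size=(6, 1)) * 10
        r0 = rm_anova(Y)
        r1 = rm_anova(Y + shift)
        np.testing.assert_allclose(r1.ss_effect, r0.ss_effect, atol=1e-9)
        np.testing.assert_allclose(r1.ss_error, r0.ss_error, atol=1e-9)
        np.testing.assert_allclose(r1.F, r0.F, atol=1e-9)
        np.testing.assert_allclose(r1.eta_p_sq, r0.eta_p_sq, atol=1e-9)
        assert r1.ss_subjects > r0.ss_subjects
        assert r1.eta_g_sq < r0.eta_g_sq

    @given(
        n=st.integers(min_value=3, max_value=8),
        b=st.integers(min_value=2, max_value=5),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_ss_identity_on_random_tables(self, n, b, seed):
        Y = np.random.default_rng(seed).normal(size=(n, b))
        res = rm_anova(Y)
        ss_total = np.sum((Y - Y.mean()) ** 2)
        np.testing.assert_allclose(
            res.ss_effect + res.ss_subjects + res.ss_error, ss_total, atol=1e-9
        )

    def test_missing_cells_rejected(self):
        Y = np.ones((4, 3))
        Y[1, 2] = np.nan
        with pytest.raises(ValueError):
            rm_anova(Y)

    def test_matches_scipy_f_oneway_logic_p(self):
        Y = np.random.default_rng(13).normal(size=(8, 3)) + [0.0, 0.5, 1.0]
        res = rm_anova(Y)
        p_ref = scipy.stats.f.sf(res.F, res.df_effect, res.df_error)
        np.testing.assert_allclose(res.p, p_ref, atol=1e-15)
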