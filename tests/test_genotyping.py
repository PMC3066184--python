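import numpy as np
import pytest
from scipy import stats

from conftest import make_model
from igc2n.core_io import CandidateLocus, IgC2NError, IntensityMatrix
from igc2n.genotyping import (
    CNClassDetector,
    fit_mixture,
    fit_mixture_candidates,
    grubbs_critical_value,
    grubbs_rescue,
    merge_close_classes,
    one_cn_differences,
    select_model,
    summarize_locus,
)


class TestSummarizeLocus:
    def test_median_over_markers(self):
        m = IntensityMatrix(["a"], np.array([[0.1, 0.3, 0.5]]))
        locus = CandidateLocus("1", 1, 3, np.array([0, 1, 2]))
        assert summarize_locus(m, locus).values[0] == pytest.approx(0.3)

    def test_single_marker_identity(self):
        m = IntensityMatrix(["a", "b"], np.array([[0.7, 0.0], [0.2, 0.0]]))
        locus = CandidateLocus("1", 1, 1, np.array([0]))
        assert summarize_locus(m, locus).values.tolist() == [0.7, 0.2]

    def test_even_count_averages_middle_two(self):
        m = IntensityMatrix(["a"], np.array([[0.0, 1.0]]))
        locus = CandidateLocus("1", 1, 2, np.array([0, 1]))
        assert summarize_locus(m, locus).values[0] == pytest.approx(0.5)


class TestFitMixture:
    def test_two_component_parameter_recovery(self):
        rng = np.random.default_rng(42)
        x = np.concatenate(
            [rng.normal(-1.0, 0.05, 20), rng.normal(0.0, 0.05, 80)]
        )
        model = fit_mixture(x, 2, variance_mode="free")
        assert np.allclose(model.centers, [-1.0, 0.0], atol=0.05)
        assert np.allclose(model.weights, [0.2, 0.8], atol=0.05)
        assert model.converged

    def test_identical_values_single_component(self):
        model = fit_mixture(np.full(10, 0.3), 1)
        assert model.centers[0] == pytest.approx(0.3)
        assert model.variances[0] >= 1e-6  # variance floor engaged

    def test_location_equivariance(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-1, 0.1, 30), rng.normal(0, 0.1, 70)])
        a = fit_mixture(x, 2, variance_mode="free")
        b = fit_mixture(x + 0.37, 2, variance_mode="free")
        assert np.allclose(b.centers, a.centers + 0.37, atol=1e-9)
        assert np.array_equal(a.labels, b.labels)

    def test_too_few_distinct_values(self):
        with pytest.raises(IgC2NError, match="distinct"):
            fit_mixture(np.array([1.0, 1.0, 2.0]), 3)

    def test_agrees_with_sklearn_on_separated_data(self):
        # independent EM implementation as cross-check, not as the engine
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-1, 0.08, 60), rng.normal(0.2, 0.08, 140)])
        ours = fit_mixture(x, 2, variance_mode="free")
        ref = GaussianMixture(2, covariance_type="full", n_init=5, random_state=0)
        ref.fit(x[:, None])
        ref_means = np.sort(ref.means_.ravel())
        assert np.allclose(ours.centers, ref_means, atol=0.02)


class TestSelectModel:
    def test_three_separated_clusters(self):
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [
                rng.normal(-1.0, 0.05, 50),
                rng.normal(0.0, 0.05, 50),
                rng.normal(0.585, 0.05, 50),
            ]
        )
        model = select_model(x)
        assert model.n_comp == 3
        assert np.allclose(model.centers, [-1.0, 0.0, 0.585], atol=0.05)

    def test_single_center_selects_one(self):
        rng = np.random.default_rng(2)
        model = select_model(rng.normal(0.0, 0.1, 200))
        assert model.n_comp == 1

    def test_selection_is_argmin_of_candidate_bics(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-1, 0.05, 60), rng.normal(0, 0.05, 140)])
        fits = fit_mixture_candidates(x)
        best_k = min(fits, key=lambda f: f.bic).n_comp
        assert select_model(x).n_comp == best_k

    def test_shift_equivariance_full_selection(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-1, 0.08, 40), rng.normal(0, 0.08, 160)])
        a = select_model(x)
        b = select_model(x + 0.9)
        assert a.n_comp == b.n_comp
        assert np.allclose(b.centers, a.centers + 0.9, atol=1e-8)
        assert np.array_equal(a.labels, b.labels)
        da, db = one_cn_differences(a).diffs, one_cn_differences(b).diffs
        assert np.allclose(da, db, atol=1e-8)

    def test_posterior_rows_partition_samples(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-1, 0.1, 50), rng.normal(0, 0.1, 150)])
        model = select_model(x)
        counts = model.class_counts()
        assert counts.sum() == 200
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-8)

    def test_ncomp_recovery_rate_on_simulated_loci(self):
        # CN1/CN2, CN2/CN3 and CN1/CN2/CN3 genotype models at log2 spacing,
        # spread 0.1: the selected component count matches truth >= 90%.
        grids = {
            2: [(-1.0, 0.3), (0.0, 0.7)],
            3: [(-1.0, 0.15), (0.0, 0.6), (0.585, 0.25)],
        }
        gain2 = [(0.0, 0.7), (0.585, 0.3)]
        cases = [(2, grids[2]), (2, gain2), (3, grids[3])]
        rng = np.random.default_rng(6)
        hits = total = 0
        for true_k, blocks in cases:
            for _ in range(50):
                x = np.concatenate(
                    [rng.normal(c, 0.1, int(200 * w)) for c, w in blocks]
                )
                m = select_model(x)
                hits += m.n_comp == true_k
                total += 1
        assert hits / total >= 0.90


class TestGrubbsRescue:
    def test_critical_value_formula(self):
        # n=3, alpha=0.05: ((n-1)/sqrt(n)) * sqrt(t^2/(n-2+t^2)),
        # t = t_{1-alpha/(2n), n-2} -- hand-frozen from the t quantile
        assert grubbs_critical_value(3, 0.05) == pytest.approx(1.1543, abs=1e-4)

    def test_symmetric_three_points_not_outlying(self):
        x = np.array([1.0, 2.0, 3.0])
        model = make_model([2.0], [1.0], [0, 0, 0], variances=[1.0])
        out = grubbs_rescue(x, model, alpha=0.05)
        # G = 1/1 = 1 < 1.1543: unchanged
        assert out.n_comp == 1

    def test_single_outlier_promoted_to_singleton(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0.0, 0.05, 50), [1.0]])
        model = make_model([0.0], [1.0], np.zeros(51, dtype=int), variances=[0.0025])
        out = grubbs_rescue(x, model, alpha=0.05)
        assert out.n_comp == 2
        assert out.centers[-1] == pytest.approx(1.0)
        assert out.class_counts()[-1] == 1

    def test_noop_below_three_samples(self):
        x = np.array([0.0, 5.0])
        model = make_model([2.5], [1.0], [0, 0], variances=[1.0])
        assert grubbs_rescue(x, model).n_comp == 1

    def test_values_conserved(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 0.05, 40), [-1.0, 1.2]])
        model = make_model([0.0], [1.0], np.zeros(42, dtype=int), variances=[0.0025])
        out = grubbs_rescue(x, model, alpha=0.05)
        assert out.labels.size == x.size
        assert out.class_counts().sum() == x.size

    def test_decision_matches_brute_force_oracle(self):
        # oracle: direct two-sided Grubbs decision computed from scratch
        rng = np.random.default_rng(10)
        for _ in range(20):
            x = rng.normal(0, 1, 25)
            if rng.random() < 0.5:
                x[0] += rng.choice([-6, 6])
            model = make_model([np.median(x)], [1.0], np.zeros(25, dtype=int))
            out = grubbs_rescue(x, model, alpha=0.05)
            g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
            tq = stats.t.ppf(1 - 0.05 / (2 * 25), 23)
            crit = (24 / np.sqrt(25)) * np.sqrt(tq**2 / (23 + tq**2))
            first_rejects = g > crit
            assert (out.n_comp > 1) == first_rejects


class TestMergeCloseClasses:
    def test_sub_transition_gap_merged(self):
        x = np.concatenate([np.full(5, 0.00), np.full(5, 0.10), np.full(5, 1.0)])
        labels = np.repeat([0, 1, 2], 5)
        model = make_model([0.0, 0.10, 1.0], [1, 1, 1], labels)
        out = merge_close_classes(x, model, min_gap=0.25)
        assert out.n_comp == 2
        assert out.class_counts().tolist() == [10, 5]

    def test_real_transition_gap_preserved(self):
        x = np.concatenate([np.full(10, 0.0), np.full(10, 0.585)])
        labels = np.repeat([0, 1], 10)
        model = make_model([0.0, 0.585], [1, 1], labels)
        assert merge_close_classes(x, model, min_gap=0.25).n_comp == 2


class TestOneCNDifferences:
    def test_diffs_from_class_medians(self):
        labels = np.repeat([0, 1, 2], 10)
        model = make_model([-1.0, 0.0, 0.585], [1, 1, 1], labels)
        d = one_cn_differences(model, "L1")
        assert np.allclose(d.diffs, [1.0, 0.585])

    def test_single_class_yields_empty(self):
        model = make_model([0.0], [1.0], np.zeros(5, dtype=int))
        assert one_cn_differences(model).diffs.size == 0

    def test_shift_invariance(self):
        labels = np.repeat([0, 1], 10)
        a = make_model([-1.0, 0.0], [1, 1], labels)
        b = make_model([-0.5, 0.5], [1, 1], labels)
        assert np.allclose(
            one_cn_differences(a).diffs, [1.0]
        ) and np.allclose(one_cn_differences(b).diffs, [1.0])


class TestCNClassDetector:
    def test_estimator_interface(self):
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(-1, 0.05, 30), rng.normal(0, 0.05, 170)])
        det = CNClassDetector().fit(x)
        assert det.model_.n_comp == 2
        assert det.labels_.size == 200
        assert det.diffs_.diffs.size == 1
        params = det.get_params()
        assert params["grubbs_alpha"] == 0.05

    def test_rare_class_rescued_end_to_end(self):
        # 3 carriers in 200: EM alone keeps one class, Grubbs + merge recover
        # a single rare deletion class
        rng = np.random.default_rng(13)
        x = rng.normal(0.0, 0.05, 200)
        x[:3] = rng.normal(-1.0, 0.05, 3)
        det = CNClassDetector().fit(x)
        assert det.model_.n_comp == 2
        assert det.model_.class_counts()[0] == 3
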