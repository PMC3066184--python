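import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import labels_for_counts, make_model
from igc2n.bias_correction import (
    THEORETICAL_DIFF_CENTERS,
    DiffMixture,
    ReferenceBiasGenotyper,
    UnresolvedLocus,
    assign_genotypes,
    expected_bias_direction,
    fit_diff_mixture,
    zero_presence_test,
)
from igc2n.bias_correction import _greedy_assign
from igc2n.core_io import GenotypedLocus, IgC2NError, OneCNDifference
from igc2n.genotyping import CNClassDetector, one_cn_differences


def theoretical_mixture():
    return DiffMixture(
        THEORETICAL_DIFF_CENTERS.copy(), np.full(4, 0.01), np.full(4, 0.25)
    )


class TestFitDiffMixture:
    def test_parameter_recovery_around_theoretical_centers(self):
        rng = np.random.default_rng(0)
        diffs = np.concatenate(
            [rng.normal(c, 0.05, 30) for c in THEORETICAL_DIFF_CENTERS]
        )
        mix = fit_diff_mixture(diffs, seed=0)
        assert not mix.fallback
        assert np.allclose(mix.centers, THEORETICAL_DIFF_CENTERS, atol=0.05)

    def test_fallback_below_minimum_pool(self):
        mix = fit_diff_mixture(np.array([1.0, 0.6, 2.0]), min_pooled=20)
        assert mix.fallback
        assert np.allclose(mix.centers, THEORETICAL_DIFF_CENTERS)

    def test_label_order_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        diffs = np.concatenate(
            [rng.normal(c, 0.05, 15) for c in THEORETICAL_DIFF_CENTERS]
        )
        a = fit_diff_mixture(diffs, seed=0)
        b = fit_diff_mixture(diffs[::-1].copy(), seed=0)
        assert (np.diff(a.centers) < 0).all()
        assert np.allclose(a.centers, b.centers, atol=1e-6)

    def test_membership_rows_sum_to_one(self):
        mix = theoretical_mixture()
        probs = mix.membership(np.array([1.0, 0.6, 2.1]))
        assert np.allclose(probs.sum(axis=1), 1.0)


class TestExpectedBiasDirection:
    def test_major_extreme_near_zero_is_anchor(self):
        m = make_model([-1.0, -0.04], [0.1, 0.9], labels_for_counts([10, 90]))
        assert expected_bias_direction(m) == 1

    def test_major_extreme_but_far_from_zero(self):
        m = make_model([0.30, 1.30], [0.9, 0.1], labels_for_counts([90, 10]))
        assert expected_bias_direction(m) is None

    def test_major_middle_class_is_not_anchor(self):
        m = make_model(
            [-1.0, 0.0, 0.6], [0.2, 0.6, 0.2], labels_for_counts([20, 60, 20])
        )
        assert expected_bias_direction(m) is None


def _brute_force_binom_two_sided(k, n, p):
    """Exact two-sided binomial p-value: sum of outcome masses <= mass(k)."""
    pk = stats.binom.pmf(k, n, p)
    masses = stats.binom.pmf(np.arange(n + 1), n, p)
    return masses[masses <= pk * (1 + 1e-12)].sum()


class TestZeroPresenceTest:
    def test_hw_consistent_counts_supported(self):
        pval, ok = zero_presence_test(np.array([1, 18, 81]))
        # p = (2+18)/200 = 0.10, expected p^2 = 0.01, observed 1/100
        oracle = _brute_force_binom_two_sided(1, 100, 0.01)
        assert pval == pytest.approx(oracle, rel=1e-9)
        assert pval == pytest.approx(1.0, abs=1e-6) and ok

    def test_zero_count_with_zero_allele_frequency(self):
        pval, ok = zero_presence_test(np.array([0, 0, 50]))
        assert pval == 1.0 and ok

    def test_excess_homozygous_deletions_rejected(self):
        pval, ok = zero_presence_test(np.array([50, 0, 50]))
        oracle = _brute_force_binom_two_sided(50, 100, 0.25)
        assert pval == pytest.approx(oracle, rel=1e-9)
        assert pval < 1e-6 and not ok

    def test_empty_input_rejected(self):
        with pytest.raises(IgC2NError):
            zero_presence_test(np.array([0, 0, 0]))


class TestAssignGenotypes:
    def test_two_class_deletion_with_anchor(self):
        # oracle: the diff 0.99 has its highest membership density in the
        # 1-2 component (direct density comparison), anchor fixes class 2
        m = make_model([-1.02, -0.03], [0.2, 0.8], labels_for_counts([40, 160]))
        d = OneCNDifference("L", np.array([0.99]))
        mix = theoretical_mixture()
        dens = stats.norm.pdf(0.99, mix.centers, np.sqrt(mix.variances))
        assert np.argmax(dens) == 1  # 1-2 transition
        out = assign_genotypes(m, d, mix, anchor=expected_bias_direction(m))
        assert isinstance(out, GenotypedLocus)
        assert sorted(set(out.cn_calls)) == [1, 2]
        assert out.bias_estimate == pytest.approx(-0.03, abs=1e-9)
        assert out.polymorphism_type == "del"
        assert out.maf == pytest.approx(0.2)

    def test_three_class_del_gain(self):
        m = make_model(
            [-1.0, 0.0, 0.585], [0.2, 0.6, 0.2], labels_for_counts([40, 120, 40])
        )
        d = OneCNDifference("L", np.array([1.0, 0.585]))
        out = assign_genotypes(m, d, theoretical_mixture(), anchor=None)
        assert sorted(set(out.cn_calls)) == [1, 2, 3]
        assert out.bias_estimate == pytest.approx(0.0, abs=1e-9)
        assert out.polymorphism_type == "del-gain"

    def test_anchor_removes_injected_shift(self):
        for b in (-0.2, 0.0, 0.2):
            m = make_model(
                [-1.0 + b, 0.0 + b], [0.2, 0.8], labels_for_counts([40, 160])
            )
            d = OneCNDifference("L", np.array([1.0]))
            out = assign_genotypes(
                m, d, theoretical_mixture(), anchor=expected_bias_direction(m)
            )
            assert sorted(set(out.cn_calls)) == [1, 2]
            assert out.bias_estimate == pytest.approx(b, abs=1e-9)

    def test_gain_ladder_without_anchor(self):
        m = make_model([0.02, 0.59], [0.8, 0.2], labels_for_counts([160, 40]))
        d = OneCNDifference("L", np.array([0.57]))
        out = assign_genotypes(m, d, theoretical_mixture(), anchor=None)
        assert sorted(set(out.cn_calls)) == [2, 3]
        assert out.polymorphism_type == "gain"

    def test_zero_presence_veto_shifts_ladder(self):
        # a diff near 2.0 says 0-1, but 5 CN0 with no CN1 class grossly
        # violates HW (p = 0.51 predicts 26% homozygous deletions, seen 2.5%)
        m = make_model([-2.0, 0.0], [0.025, 0.975], labels_for_counts([5, 195]))
        d = OneCNDifference("L", np.array([2.0]))
        out = assign_genotypes(m, d, theoretical_mixture(), anchor=None)
        assert isinstance(out, GenotypedLocus)
        assert out.cn_calls.min() >= 1  # CN 0 vetoed

    def test_single_class_is_unresolved(self):
        m = make_model([0.0], [1.0], labels_for_counts([10]))
        out = assign_genotypes(
            m, OneCNDifference("L", np.empty(0)), theoretical_mixture()
        )
        assert isinstance(out, UnresolvedLocus)

    def test_never_negative_and_consecutive(self):
        rng = np.random.default_rng(3)
        mix = theoretical_mixture()
        for _ in range(50):
            k = rng.integers(2, 5)
            start = rng.integers(0, 5 - k + 1)
            cns = np.arange(start, start + k)
            centers = np.where(
                cns > 0, np.log2(np.maximum(cns, 1) / 2.0), np.log2(0.25 / 2)
            ) + rng.normal(0, 0.03)
            counts = rng.integers(5, 60, size=k)
            m = make_model(centers, counts, labels_for_counts(counts))
            d = one_cn_differences(m)
            out = assign_genotypes(m, d, mix, anchor=None)
            if isinstance(out, GenotypedLocus):
                vals = np.unique(out.cn_calls)
                assert vals.min() >= 0
                assert np.array_equal(vals, np.arange(vals.min(), vals.max() + 1))


class TestGreedyAssignment:
    def _exhaustive(self, probs):
        """Brute force over injective column labelings, maximize the product."""
        k = probs.shape[0]
        best, best_cols = -np.inf, None
        for cols in itertools.permutations(range(4), k):
            v = np.prod(probs[np.arange(k), list(cols)])
            if v > best:
                best, best_cols = v, np.array(cols)
        return best_cols

    def test_agrees_with_exhaustive_on_simulated_diffs(self):
        rng = np.random.default_rng(4)
        mix = theoretical_mixture()
        agree = total = 0
        for _ in range(200):
            k1 = rng.integers(1, 4)  # number of diffs
            start = rng.integers(0, 4 - k1 + 1)
            true_cols = np.arange(start, start + k1)
            diffs = mix.centers[true_cols] + rng.normal(0, 0.05, k1)
            probs = mix.membership(diffs)
            agree += np.array_equal(_greedy_assign(probs), self._exhaustive(probs))
            total += 1
        assert agree / total >= 0.95


class TestEndToEndBiasRecovery:
    def test_genotype_accuracy_and_bias_correlation(self):
        # loci with an injected reference shift b: >=95% of per-sample integer
        # genotypes correct, and the estimated bias tracks the injected one
        rng = np.random.default_rng(5)
        shifts = [-0.3, -0.15, 0.0, 0.15, 0.3]
        locus_plan = []
        for b in shifts:
            for kind in ("del12", "gain23", "del012"):
                for _ in range(3):
                    locus_plan.append((b, kind))
        models, truths, biases = [], [], []
        n = 200
        for b, kind in locus_plan:
            if kind == "del12":
                q = 0.18
                n1 = rng.binomial(n, 2 * q * (1 - q) + q * q)
                cn = np.array([1] * n1 + [2] * (n - n1))
            elif kind == "gain23":
                q = 0.18
                n3 = rng.binomial(n, 2 * q * (1 - q) + q * q)
                cn = np.array([3] * n3 + [2] * (n - n3))
            else:
                q = 0.3
                u = rng.random((n, 2))
                cn = 2 - (u < q).sum(axis=1)
            base = np.where(cn > 0, np.log2(np.maximum(cn, 1) / 2.0), np.log2(0.125))
            x = base + b + rng.normal(0, 0.05, n)
            det = CNClassDetector(random_state=0).fit(x)
            models.append((det.model_, x, cn, b))
            truths.append(cn)
            biases.append(b)

        corr = ReferenceBiasGenotyper(random_state=0).fit([m for m, *_ in models])
        acc, est_bias, true_bias = [], [], []
        i_geno = 0
        resolved = corr.genotyped_loci_
        # map back: fit() preserves order for resolved loci
        unresolved_ids = {u.locus_id for u in corr.unresolved_}
        gi = 0
        for idx, (model, x, cn, b) in enumerate(models):
            lid = f"locus{idx}"
            if lid in unresolved_ids:
                continue
            g = resolved[gi]
            gi += 1
            acc.append((g.cn_calls == cn).mean())
            est_bias.append(g.bias_estimate)
            true_bias.append(b)
        assert len(acc) >= 0.9 * len(models)  # few unresolved
        assert np.mean(acc) >= 0.95
        r = stats.pearsonr(est_bias, true_bias).statistic
        assert r >= 0.9
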