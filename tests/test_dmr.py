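"""Size factors, dispersion, the exact conditional NB test, and BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gbsmedip.core import CountMatrix, ROI
from gbsmedip.dmr import (
    ContrastSpec,
    DMRModel,
    bh_adjust,
    estimate_dispersion,
    exact_nb_pvalue,
    size_factors,
)


def oracle_conditional_p(k1, total, factors1, factors2, phi, mu=3.7):
    """Independent route: convolve per-sample count pmfs, condition on total.

    Each sample count is NB with mean mu*s and size s/phi (Poisson at
    phi=0); the group-sum pmfs are obtained by numerical convolution and the
    two-sided p sums conditional split probabilities no more likely than the
    observed one.
    """

    def group_pmf(factors):
        pmf = np.array([1.0])
        for s in factors:
            if phi == 0:
                d = stats.poisson.pmf(np.arange(total + 1), mu * s)
            else:
                r = s / phi
                p = r / (r + mu * s)
                d = stats.nbinom.pmf(np.arange(total + 1), r, p)
            pmf = np.convolve(pmf, d)[: total + 1]
        return pmf

    p1 = group_pmf(factors1)
    p2 = group_pmf(factors2)
    joint = p1 * p2[::-1]  # index k -> P(X1 = k) P(X2 = total - k)
    joint = joint / joint.sum()
    obs = joint[k1]
    return float(joint[joint <= obs * (1 + 1e-8)].sum())


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.arange(1, 21)[:, None], (1, 2))
        np.testing.assert_allclose(size_factors(counts), [1, 1])

    def test_doubled_sample_gives_sqrt2_split(self):
        a = np.arange(1, 31)
        counts = np.column_stack([a, 2 * a])
        np.testing.assert_allclose(
            size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_invariant_to_roi_order(self, rng):
        counts = rng.poisson(20, size=(50, 4)) + 1
        perm = rng.permutation(50)
        np.testing.assert_allclose(
            size_factors(counts), size_factors(counts[perm]), rtol=1e-12
        )

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            size_factors(np.zeros((5, 2)))


class TestDispersion:
    def test_poisson_counts_give_near_zero_common(self, rng):
        counts = rng.poisson(30, size=(500, 18))
        groups = np.repeat([0, 1], 9)
        disp = estimate_dispersion(counts, groups, np.ones(18))
        assert disp.common < 0.02

    def test_nb_counts_recover_known_dispersion(self, rng):
        phi = 0.2
        mu = 30.0
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(200, 18))
        groups = np.repeat([0, 1], 9)
        disp = estimate_dispersion(counts, groups, np.ones(18))
        assert 0.1 <= disp.common <= 0.3

    def test_constant_counts_zero_raw_dispersion(self):
        counts = np.full((10, 6), 17)
        disp = estimate_dispersion(counts, np.repeat([0, 1], 3), np.ones(6))
        assert (disp.raw == 0).all()

    def test_single_sample_group_rejected(self):
        counts = np.ones((5, 3))
        with pytest.raises(ValueError):
            estimate_dispersion(counts, np.array([0, 1, 1]), np.ones(3))


class TestExactTest:
    def test_constructed_0_10_case(self):
        # phi=0, one sample per group, equal factors: conditional binomial(10, 1/2)
        assert exact_nb_pvalue(0, 10, 1.0, 1.0, 0.0) == pytest.approx(2 / 1024, abs=1e-15)

    def test_equal_split_gives_p_one(self):
        assert exact_nb_pvalue(5, 10, 1.0, 1.0, 0.0) == pytest.approx(1.0)
        assert exact_nb_pvalue(8, 16, 3.0, 3.0, 0.3) == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self):
        for phi in (0.0, 0.15):
            p_a = exact_nb_pvalue(3, 20, 4.0, 5.0, phi)
            p_b = exact_nb_pvalue(17, 20, 5.0, 4.0, phi)
            assert p_a == pytest.approx(p_b, rel=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.2, 0.7])
    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (4, 4)])
    def test_matches_convolution_oracle(self, phi, n1, n2):
        for total in (1, 4, 11, 30):
            f1, f2 = [1.0] * n1, [1.0] * n2
            s1, s2 = float(n1), float(n2)
            for k1 in range(total + 1):
                expected = oracle_conditional_p(k1, total, f1, f2, phi)
                got = exact_nb_pvalue(k1, total, s1, s2, phi)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_unequal_size_factors_match_oracle(self):
        f1, f2 = [0.8, 1.3], [1.1, 0.9, 1.2]
        s1, s2 = sum(f1), sum(f2)
        for phi in (0.0, 0.25):
            for k1 in range(13):
                expected = oracle_conditional_p(k1, 12, f1, f2, phi)
                got = exact_nb_pvalue(k1, 12, s1, s2, phi)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_phi_limit_agrees_with_conditional_binomial(self):
        # phi -> 0 limit equals the exact binomial conditional distribution
        for total in range(1, 31):
            for k1 in range(total + 1):
                p_nb = exact_nb_pvalue(k1, total, 2.0, 3.0, 0.0)
                pmf = stats.binom.pmf(np.arange(total + 1), total, 2 / 5)
                obs = pmf[k1]
                p_binom = pmf[pmf <= obs * (1 + 1e-8)].sum()
                assert p_nb == pytest.approx(p_binom, abs=1e-12)

    def test_zero_total_p_one(self):
        assert exact_nb_pvalue(0, 0, 1.0, 1.0, 0.1) == 1.0


class TestBH:
    def test_step_up_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.33]), [0.33])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1, 1, 1]), [1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_invariant_to_input_order(self, pvals, rnd):
        p = np.array(pvals)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], rtol=1e-12)


def _matrix(counts, samples):
    counts = np.asarray(counts)
    rois = [
        ROI("chr1", 1000 * i, 1000 * i + 300, f"roi{i}") for i in range(len(counts))
    ]
    return CountMatrix(
        rois=rois, samples=samples, counts=counts, library_sizes=counts.sum(0)
    )


class TestDMRModel:
    def test_min_row_sum_boundary(self):
        counts = np.array([[1, 2, 3, 4], [1, 2, 3, 3]])
        cm = _matrix(counts, ["a1", "a2", "b1", "b2"])
        res = DMRModel(
            cm, ContrastSpec("t", ("a1", "a2"), ("b1", "b2"))
        ).fit(min_row_sum=10)
        assert res.n_tested == 1
        assert res.records[0].roi_name == "roi0"

    def test_group_swap_negates_log2fc_and_flips_label(self, rng):
        counts = rng.poisson(25, size=(40, 8))
        counts[:5, :4] *= 3
        samples = [f"T_E{i}" for i in range(1, 5)] + [f"T_B{i}" for i in range(1, 5)]
        cm = _matrix(counts, samples)
        c12 = ContrastSpec("f", tuple(samples[:4]), tuple(samples[4:]))
        c21 = ContrastSpec("r", tuple(samples[4:]), tuple(samples[:4]))
        r12 = DMRModel(cm, c12).fit(min_row_sum=1)
        r21 = DMRModel(cm, c21).fit(min_row_sum=1)
        for a, b in zip(r12.records, r21.records):
            assert a.p == pytest.approx(b.p, rel=1e-9)
            assert a.log2fc == pytest.approx(-b.log2fc, rel=1e-9)
            assert a.hyper_group == b.hyper_group  # label carries direction

    def test_missing_contrast_sample_rejected(self):
        cm = _matrix(np.ones((3, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            DMRModel(cm, ContrastSpec("x", ("a",), ("zzz",)))

    def test_tiers_follow_thresholds(self, rng):
        counts = rng.poisson(30, size=(100, 12))
        counts[:3, :6] *= 4
        samples = [f"T_E{i}" for i in range(6)] + [f"T_B{i}" for i in range(6)]
        cm = _matrix(counts, samples)
        res = DMRModel(
            cm, ContrastSpec("t", tuple(samples[:6]), tuple(samples[6:]))
        ).fit()
        df = res.to_frame()
        assert set(df.loc[df.p <= 0.05, "roi_name"]) == {
            r.roi_name for r in res.exploratory
        }
        assert set(df.loc[df.q <= 0.6, "roi_name"]) == {r.roi_name for r in res.top}

    def test_summary_reports_counts(self, rng):
        counts = rng.poisson(30, size=(30, 8))
        samples = [f"T_E{i}" for i in range(4)] + [f"T_B{i}" for i in range(4)]
        cm = _matrix(counts, samples)
        res = DMRModel(
            cm, ContrastSpec("T-E/B", tuple(samples[:4]), tuple(samples[4:]))
        ).fit()
        text = res.summary()
        assert "T-E/B" in text and "tested" in text
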