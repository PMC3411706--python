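"""Per-voxel log(V/Q): normalization, infinity conventions, moments,
mismatch fractions and voxelwise correlation."""

import numpy as np
import pytest

import vqmouse as vq
from vqmouse.vqstats import Category
from conftest import four_voxel_label


class TestNormalizeActivity:
    def test_uniform_counts(self):
        v, _, lab = four_voxel_label([1, 1, 1, 1], [1, 1, 1, 1])
        out = vq.normalize_activity(v, lab)
        assert np.allclose(out[lab.mask], 25.0)

    def test_mixed_counts(self):
        v, _, lab = four_voxel_label([0, 2, 3, 5], [1, 1, 1, 1])
        out = vq.normalize_activity(v, lab)
        assert np.allclose(sorted(out[lab.mask]), [0, 20, 30, 50])

    def test_scale_invariance(self):
        v, _, lab = four_voxel_label([0, 2, 3, 5], [1, 1, 1, 1])
        assert np.allclose(vq.normalize_activity(v, lab),
                           vq.normalize_activity(v * 1000.0, lab))

    def test_sums_to_100(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 10, (6, 6, 6))
        lab = vq.LungLabel(rng.random((6, 6, 6)) < 0.5, 1.0)
        out = vq.normalize_activity(data, lab)
        assert out[lab.mask].sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(out[~lab.mask] == 0)

    def test_zero_total_rejected(self):
        v, _, lab = four_voxel_label([0, 0, 0, 0], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="zero total"):
            vq.normalize_activity(v, lab)


class TestComputeLogVQ:
    def test_equal_fields_give_zero(self):
        v, q, lab = four_voxel_label([1, 2, 3, 4], [1, 2, 3, 4])
        res = vq.compute_log_vq(vq.normalize_activity(v, lab),
                                vq.normalize_activity(q, lab), lab)
        assert np.allclose(res.logvq[lab.mask], 0.0)

    def test_optimal_human_ratio(self):
        # a V/Q ratio of 0.80 corresponds to log(V/Q) = -0.097
        v, q, lab = four_voxel_label([0.8, 1.0], [1.0, 0.8])
        res = vq.compute_log_vq(v, q, lab)
        assert round(float(res.logvq[0, 0, 0]), 3) == -0.097

    def test_infinity_and_both_zero_categories(self):
        v, q, lab = four_voxel_label([0.0, 0.5, 0.0, 1.0],
                                     [0.3, 0.0, 0.0, 1.0])
        res = vq.compute_log_vq(v, q, lab)
        flat = [res.category[idx] for idx in np.argwhere(lab.mask)]
        cats = {tuple(i): res.category[tuple(i)] for i in np.argwhere(lab.mask)}
        vals = sorted(int(c) for c in cats.values())
        assert sorted([int(Category.NEG_INF), int(Category.POS_INF),
                       int(Category.BOTH_ZERO), int(Category.FINITE)]) == vals
        bz = res.category == Category.BOTH_ZERO
        assert np.all(res.logvq[bz] == 0.0)  # display convention

    def test_category_partition_is_exact(self, small_bundle):
        b = small_bundle
        res = vq.compute_log_vq(
            vq.normalize_activity(b.vent, b.label),
            vq.normalize_activity(b.perf, b.label), b.label)
        total = sum(res.category_percent(c) for c in
                    (Category.FINITE, Category.NEG_INF, Category.POS_INF,
                     Category.BOTH_ZERO))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_negative_activity_rejected(self):
        v, q, lab = four_voxel_label([-1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="negative"):
            vq.compute_log_vq(v, q, lab)


class TestSummarize:
    def test_back_transformed_mean_ratio(self):
        # mean log(V/Q) of -0.071 corresponds to a V/Q ratio of 0.85
        q = np.ones(8)
        v = q * 10.0 ** (-0.071)
        vv, qq, lab = four_voxel_label(v, q, shape=(8, 2, 2))
        res = vq.compute_log_vq(vq.normalize_activity(vv, lab),
                                vq.normalize_activity(qq, lab), lab)
        # normalization cancels the common offset; re-impose the mean field
        res.logvq[res.finite_mask] = -0.071
        summ = vq.summarize(res)
        assert round(summ.mean_vq_ratio, 2) == 0.85

    def test_degenerate_field_moments(self):
        v, q, lab = four_voxel_label([1, 1, 1, 1], [1, 1, 1, 1])
        res = vq.compute_log_vq(vq.normalize_activity(v, lab),
                                vq.normalize_activity(q, lab), lab)
        summ = vq.summarize(res)
        assert summ.sd == 0.0
        assert summ.skewness is None and summ.excess_kurtosis is None
        assert summ.warnings

    def test_moments_match_explicit_formulas(self):
        vals = np.array([-0.30, -0.12, -0.07, -0.05, 0.0, 0.03, 0.11, 0.40])
        q = np.ones(8)
        v = q * 10.0 ** vals
        vv, qq, lab = four_voxel_label(v, q, shape=(8, 2, 2))
        res = vq.compute_log_vq(vq.normalize_activity(vv, lab),
                                vq.normalize_activity(qq, lab), lab)
        summ = vq.summarize(res)
        # spreadsheet-style population moments on the normalized values
        x = res.finite_values
        m = x.mean()
        sd = np.sqrt(((x - m) ** 2).mean())
        skew = ((x - m) ** 3).mean() / sd**3
        kurt = ((x - m) ** 4).mean() / sd**4 - 3.0
        assert summ.mean == pytest.approx(m, rel=1e-12)
        assert summ.sd == pytest.approx(sd, rel=1e-12)
        assert summ.skewness == pytest.approx(skew, rel=1e-9)
        assert summ.excess_kurtosis == pytest.approx(kurt, rel=1e-9)

    def test_mismatch_thresholds_and_totals(self):
        rng = np.random.default_rng(1)
        n = 4000
        vals = rng.normal(-0.071, 0.361, n)
        q = np.ones(n + 2)
        v = np.concatenate([10.0 ** vals, [0.0, 1.0]])
        q[-1] = 0.0  # one unperfused voxel
        vv, qq, lab = four_voxel_label(v, q, shape=(n + 2, 2, 2))
        res = vq.compute_log_vq(vq.normalize_activity(vv, lab),
                                vq.normalize_activity(qq, lab), lab)
        ref = vq.ReferenceStats(ref_mean=float(res.finite_values.mean()),
                                ref_sd=float(res.finite_values.std()))
        summ = vq.summarize(res, ref)
        x = res.finite_values
        exp_low = 100.0 * (x < ref.low_threshold).sum() / lab.voxel_count
        exp_high = 100.0 * (x > ref.high_threshold).sum() / lab.voxel_count
        assert summ.pct_low == pytest.approx(exp_low)
        assert summ.pct_high == pytest.approx(exp_high)
        assert summ.pct_low_total == pytest.approx(
            summ.pct_low + summ.pct_neg_inf)
        assert summ.pct_high_total == pytest.approx(
            summ.pct_high + summ.pct_pos_inf)

    def test_too_few_finite_voxels(self):
        v, q, lab = four_voxel_label([1.0, 0.0], [1.0, 1.0])
        res = vq.compute_log_vq(v, q, lab)
        with pytest.raises(ValueError, match="finite"):
            vq.summarize(res)


class TestHistogram:
    def test_single_value_field(self):
        v, q, lab = four_voxel_label([2, 2, 2, 2], [1, 1, 1, 1])
        res = vq.compute_log_vq(vq.normalize_activity(v, lab),
                                vq.normalize_activity(q, lab), lab)
        df = vq.histogram(res)
        regular = df[df.bin_center.notna()]
        assert regular.pct_tlv.max() == pytest.approx(100.0)

    def test_total_conservation(self, small_bundle):
        b = small_bundle
        res = vq.compute_log_vq(
            vq.normalize_activity(b.vent, b.label),
            vq.normalize_activity(b.perf, b.label), b.label)
        df = vq.histogram(res, 0.05)
        assert df.pct_tlv.sum() == pytest.approx(100.0, abs=1e-9)

    def test_normal_field_matches_analytic_cdf(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        n = 50000
        mu, sd = -0.071, 0.361
        vals = rng.normal(mu, sd, n)
        q = np.ones(n)
        vv, qq, lab = four_voxel_label(q * 10.0 ** vals, q, shape=(n, 2, 2))
        res = vq.compute_log_vq(vq.normalize_activity(vv, lab),
                                vq.normalize_activity(qq, lab), lab)
        # normalization shifts the location; compare against the realized one
        mu_r = res.finite_values.mean()
        df = vq.histogram(res, 0.1)
        regular = df[df.bin_center.notna()]
        for _, row in regular[regular.pct_tlv > 1.0].iterrows():
            lo, hi = row.bin_center - 0.05, row.bin_center + 0.05
            expect = 100 * (stats.norm.cdf(hi, mu_r, sd)
                            - stats.norm.cdf(lo, mu_r, sd))
            assert row.pct_tlv == pytest.approx(expect, abs=0.5)


class TestVoxelCorrelation:
    def test_identical_fields(self):
        v, q, lab = four_voxel_label([1, 2, 3, 4], [1, 2, 3, 4])
        assert vq.voxel_correlation(v, q, lab) == pytest.approx(1.0)

    def test_independent_fields_near_zero(self):
        rng = np.random.default_rng(3)
        n = 20000
        v, q, lab = four_voxel_label(rng.random(n), rng.random(n),
                                     shape=(n, 2, 2))
        assert abs(vq.voxel_correlation(v, q, lab)) < 0.03

    def test_five_pairs_match_closed_form(self):
        vs = [1.0, 2.0, 4.0, 3.0, 5.0]
        qs = [2.0, 1.0, 4.0, 5.0, 3.0]
        v, q, lab = four_voxel_label(vs, qs, shape=(5, 2, 2))
        x, y = np.array(vs), np.array(qs)
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        assert vq.voxel_correlation(v, q, lab) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_zero_variance_rejected(self):
        v, q, lab = four_voxel_label([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="variance"):
            vq.voxel_correlation(v, q, lab)


class TestScaleInvariance:
    """The ~24:1 perfusion:ventilation activity ratio must be immaterial."""

    def test_all_result_fields_invariant(self, small_bundle):
        b = small_bundle
        def run(v_scale, q_scale):
            v = b.vent.with_data(b.vent.data * v_scale)
            q = b.perf.with_data(b.perf.data * q_scale)
            res = vq.compute_log_vq(
                vq.normalize_activity(v, b.label),
                vq.normalize_activity(q, b.label), b.label)
            return res
        base = run(1.0, 1.0)
        scaled = run(24.2, 1 / 24.2)
        assert np.allclose(base.logvq, scaled.logvq, atol=1e-9)
        assert np.array_equal(base.category, scaled.category)
        assert np.allclose(base.v_rel, scaled.v_rel, atol=1e-9)
        assert np.allclose(base.q_rel, scaled.q_rel, atol=1e-9)

    def test_normal_field_two_sigma_coverage(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(-0.071, 0.361, 100000)
        frac = np.mean(np.abs(vals + 0.071) <= 2 * 0.361)
        assert frac >= 0.95
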