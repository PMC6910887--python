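"""Mutation ratios, interval counts, the quadratic fit and the verdict.

The parabola here is an exact three-point interpolation, so most checks
have closed-form expectations; the least-squares fit on the same three
points serves as an independent oracle (it is exact for three points).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snp_ploidy import (ClassifyConfig, IntervalConfig, SNPSite, batch_z,
                        classify, count_intervals, fit_parabola, mutation_ratio,
                        ratio_statistic)
from snp_ploidy.classifier import (DegenerateFitError, IntervalCounts,
                                   UndefinedRatioError)

counts_strategy = st.tuples(st.integers(0, 5000), st.integers(0, 5000),
                            st.integers(0, 5000)).filter(lambda t: sum(t) > 0)


def make_counts(n1, n2, n3):
    return IntervalCounts(n1, n2, n3, n1 + n2 + n3)


class TestMutationRatio:
    @pytest.mark.parametrize("ref,alt,expected", [
        (5, 5, 0.5), (20, 10, 1 / 3), (4, 8, 2 / 3), (0, 7, 1.0),
    ])
    def test_alt_read_fraction(self, ref, alt, expected):
        s = SNPSite("chr1", 10, "A", "G", ref, alt)
        assert mutation_ratio(s) == pytest.approx(expected)

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError, match="zero depth"):
            mutation_ratio(SNPSite("chr1", 10, "A", "G", 0, 0))


class TestCountIntervals:
    def test_one_mr_per_interval(self):
        c = count_intervals([0.30, 0.50, 0.66, 0.90])
        assert (c.n_third, c.n_half, c.n_two_thirds, c.n_candidates) == (1, 1, 1, 4)

    def test_closed_boundaries(self):
        c = count_intervals([0.28, 0.38, 0.45, 0.55, 0.62, 0.72])
        assert (c.n_third, c.n_half, c.n_two_thirds) == (2, 2, 2)

    def test_out_of_interval_mrs_only_count_as_candidates(self):
        c = count_intervals([0.40] * 7)
        assert (c.n_third, c.n_half, c.n_two_thirds, c.n_candidates) == (0, 0, 0, 7)

    def test_mrs_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            count_intervals([0.5, 1.2])


class TestFitParabola:
    def test_symmetric_counts(self):
        fit = fit_parabola(make_counts(25, 50, 25))
        assert fit.a == pytest.approx(-9.0)
        assert fit.axis == pytest.approx(0.5)

    def test_uniform_counts_degenerate(self):
        fit = fit_parabola(make_counts(100, 100, 100))
        assert fit.a == 0.0 and fit.axis is None

    def test_all_zero_counts_raise(self):
        with pytest.raises(DegenerateFitError):
            fit_parabola(IntervalCounts(0, 0, 0, 50))

    @pytest.mark.parametrize("ratio,printed_a", [(2.16, 0.91), (1.79, -1.35)])
    def test_printed_coefficients_recovered_from_ratio(self, ratio, printed_a):
        """Side-to-centre ratios of known samples reproduce their printed a."""
        n_half = 10_000
        n_side = round(ratio * n_half)
        fit = fit_parabola(make_counts(n_side // 2, n_half, n_side - n_side // 2))
        assert round(fit.a, 2) == printed_a

    @settings(max_examples=300, deadline=None)
    @given(counts=counts_strategy)
    def test_interpolation_exact_and_normalised(self, counts):
        fit = fit_parabola(make_counts(*counts))
        for x, y in [(1 / 3, fit.y1), (1 / 2, fit.y2), (2 / 3, fit.y3)]:
            assert abs(fit(x) - y) <= 1e-12
        assert fit.y1 + fit.y2 + fit.y3 == pytest.approx(1.0, abs=1e-12)
        assert np.sign(fit.a) == np.sign(fit.y1 + fit.y3 - 2 * fit.y2)

    @settings(max_examples=200, deadline=None)
    @given(counts=counts_strategy)
    def test_least_squares_oracle_agrees(self, counts):
        """3-point least squares is exact, so it must equal the closed form."""
        fit = fit_parabola(make_counts(*counts))
        total = sum(counts)
        coeffs = np.polyfit([1 / 3, 1 / 2, 2 / 3], [c / total for c in counts], 2)
        assert np.allclose([fit.a, fit.b, fit.c], coeffs, atol=1e-8)

    @settings(max_examples=200, deadline=None)
    @given(n_side=st.integers(0, 3000), n_half=st.integers(0, 3000))
    def test_symmetric_side_counts_centre_the_axis(self, n_side, n_half):
        if n_side == 0 and n_half == 0:
            return
        fit = fit_parabola(make_counts(n_side, n_half, n_side))
        if fit.a != 0:
            assert fit.axis == 0.5  # exact, not approximate


class TestRatioStatistic:
    def test_balanced(self):
        assert ratio_statistic(make_counts(10, 20, 10)) == 1.0

    def test_sign_boundary_is_two(self):
        """ratio == 2 exactly where a == 0 (y2 == 1/3 under normalisation)."""
        counts = make_counts(10, 10, 10)
        assert ratio_statistic(counts) == 2.0
        assert fit_parabola(counts).a == 0.0

    def test_undefined_without_centre_sites(self):
        with pytest.raises(UndefinedRatioError):
            ratio_statistic(make_counts(5, 0, 5))

    @settings(max_examples=300, deadline=None)
    @given(counts=counts_strategy.filter(lambda t: t[1] > 0))
    def test_parabola_sign_equivalent_to_ratio_cutoff(self, counts):
        fit = fit_parabola(make_counts(*counts))
        r = ratio_statistic(make_counts(*counts))
        assert (fit.a > 0) == (r > 2.0)
        assert (fit.a == 0) == (r == 2.0)


class TestBatchZ:
    def test_sample_at_reference_mean_scores_zero(self):
        zs, stats = batch_z([1.68, 1.77, 1.86])
        assert stats.mean == pytest.approx(1.77)
        assert zs[1] == pytest.approx(0.0, abs=1e-9)

    def test_printed_batch_stats_give_expected_z(self):
        """(2.29 - 1.77) / 0.09 = 5.78 on the printed rounded values."""
        z = (2.29 - 1.77) / 0.09
        assert z == pytest.approx(5.7778, abs=1e-3)
        # the same arithmetic through the API, constructing a batch whose
        # reference mean/sd are exactly 1.77/0.09
        ref = [1.68, 1.77, 1.86]  # mean 1.77, sd 0.09
        zs, stats = batch_z(ref + [2.29])
        assert stats.mean == pytest.approx(1.77)
        assert stats.sd == pytest.approx(0.09)
        assert zs[-1] == pytest.approx(5.7778, abs=1e-3)

    def test_robust_reference_excludes_presumed_triploids(self):
        zs, stats = batch_z([1.7, 1.8, 1.9, 2.5], robust=True)
        assert stats.n_reference == 3
        zs2, stats2 = batch_z([1.7, 1.8, 1.9, 2.5], robust=False)
        assert stats2.n_reference == 4

    def test_degenerate_batches(self):
        zs, stats = batch_z([1.5, 1.5, 1.5])
        assert stats.sd == 0.0 and np.all(np.isnan(zs))
        with pytest.raises(ValueError, match=">= 3"):
            batch_z([1.5, 1.6])
        with pytest.raises(ValueError, match="reference"):
            batch_z([2.5, 2.6, 2.7], robust=True)


class TestClassify:
    def run(self, n1, n2, n3, n_cand=None, cfg=None, z=None):
        counts = IntervalCounts(n1, n2, n3, n_cand or (n1 + n2 + n3 + 1000))
        fit = fit_parabola(counts) if n1 + n2 + n3 else None
        try:
            r = ratio_statistic(counts)
        except UndefinedRatioError:
            r = None
        return classify(fit, r, z, counts, cfg or ClassifyConfig(min_candidate_sites=100))

    def test_triploid_profile(self):
        # counts giving ratio 2.29 and axis 0.55, as for a confirmed 68,XX
        call = self.run(1233, 1000, 1057)
        assert call.verdict == "triploid"
        assert round(call.fit.axis, 2) == 0.55
        assert call.ratio > 2

    def test_diploid_profile(self):
        call = self.run(880, 1000, 920)
        assert call.verdict == "diploid" and call.fit.a < 0

    def test_axis_slightly_out_is_triploid_with_flag(self):
        # ratio 2.16, axis ~0.56: one printed confirmed triploid looks like this
        call = self.run(1138, 1000, 1022)
        assert round(call.fit.axis, 2) == 0.56
        assert call.verdict == "triploid"
        assert "axis_out_of_range" in call.flags

    def test_strict_axis_demotes_to_low_confidence(self):
        cfg = ClassifyConfig(min_candidate_sites=100, strict_axis=True)
        call = self.run(1138, 1000, 1022, cfg=cfg)
        assert call.verdict == "triploid_low_confidence"

    def test_axis_far_out_is_low_confidence(self):
        call = self.run(2100, 1000, 200)  # a > 0 but heavily lopsided
        assert call.fit.a > 0
        assert call.verdict == "triploid_low_confidence"
        assert "axis_out_of_range" in call.flags

    def test_degenerate_fit_is_inconclusive_not_diploid(self):
        call = self.run(500, 500, 500)
        assert call.verdict == "inconclusive"
        assert "degenerate_fit" in call.flags

    def test_low_sites_blocks_verdict(self):
        cfg = ClassifyConfig(min_candidate_sites=1000)
        call = self.run(130, 100, 99, n_cand=400, cfg=cfg)
        assert call.verdict == "inconclusive" and "low_sites" in call.flags

    def test_undefined_ratio_is_inconclusive(self):
        call = self.run(300, 0, 300)
        assert call.verdict == "inconclusive" and "ratio_undefined" in call.flags

    def test_z_is_auxiliary_only(self):
        with_z = self.run(880, 1000, 920, z=9.0)
        assert with_z.verdict == "diploid"  # parabola wins
        assert "z_outlier" in with_z.flags


class TestParameterRecovery:
    def test_simulated_ploidy_recovered_at_operating_scale(self):
        """200 uncontaminated replicates (>=5000 candidate sites, mean
        depth 15) must essentially all be classified correctly."""
        from snp_ploidy import SimConfig, call_batch, evaluate_batch, simulate_batch
        genome = {"chr1": 60_000_000, "chr2": 60_000_000, "chr3": 60_000_000}
        sim = simulate_batch(100, 100, SimConfig(genome=genome, n_panel_sites=5000),
                             seed=12345)
        calls, _ = call_batch(sim.samples, sim.panel)
        cc, _ = evaluate_batch(calls, sim.truth_table)
        assert min(c.counts.n_candidates for c in calls.values()) >= 5000
        assert (cc.tp + cc.tn) / cc.total >= 0.99
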