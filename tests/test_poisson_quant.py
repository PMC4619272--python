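"""Poisson concentration estimation, chip quantification, spike-in normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from chipdpcr import (
    NoValidPartitionsError,
    SaturatedChipError,
    SimulationConfig,
    SpikeInError,
    estimate_concentration,
    quantify_chip,
    simulate_chip,
    spikein_normalize,
)

from conftest import MID_THRESHOLD, make_result

VOL = 8.09e-4


class TestEstimateConcentration:
    def test_all_negative_chip_reports_rule_of_three_bound(self):
        est = estimate_concentration(12_000, 0, partition_volume=VOL)
        assert est.copies_per_ul == 0
        assert est.ci_low == 0
        assert est.ci_high == pytest.approx((3 / 12_000) / VOL)

    def test_known_occupancy(self):
        # 10% positive: lambda = -ln(0.9), frozen from direct evaluation
        est = estimate_concentration(10_000, 1_000, partition_volume=VOL)
        assert est.lambda_hat == pytest.approx(0.10536051565782628)
        assert est.copies_per_ul == pytest.approx(130.23549525071232)
        assert est.ci_low < est.copies_per_ul < est.ci_high

    def test_saturated_chip_raises(self):
        with pytest.raises(SaturatedChipError, match="saturated"):
            estimate_concentration(100, 100)

    def test_no_valid_partitions_raises(self):
        with pytest.raises(NoValidPartitionsError):
            estimate_concentration(0, 0)

    def test_lambda_increases_with_positive_count(self):
        lams = [
            estimate_concentration(5_000, k).lambda_hat
            for k in range(0, 5_000, 250)
        ]
        assert all(a < b for a, b in zip(lams, lams[1:]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 19_999), st.floats(1e-5, 1e-2))
    def test_concentration_scales_inversely_with_partition_volume(self, k, vol):
        a = estimate_concentration(20_000, k, partition_volume=vol)
        b = estimate_concentration(20_000, k, partition_volume=vol * 10)
        assert a.copies_per_ul == pytest.approx(10 * b.copies_per_ul)
        assert a.ci_high == pytest.approx(10 * b.ci_high)

    def test_linear_limit_at_low_occupancy(self):
        # for p < 0.01, copies ~= n_positive / (n_valid * volume) within 1%
        for k in (5, 50, 190):
            est = estimate_concentration(20_000, k, partition_volume=VOL)
            linear = k / (20_000 * VOL)
            assert est.copies_per_ul == pytest.approx(linear, rel=0.01)

    def test_matches_occupancy_inversion_oracle(self):
        """lambda_hat equals numerically inverting the Poisson occupancy curve.

        Oracle route: solve P(K >= 1 | lambda) = p_hat with brentq on
        scipy's Poisson survival function, never using the closed form.
        """
        for k in (20, 1_000, 10_000, 19_000):
            est = estimate_concentration(20_000, k)
            p_hat = k / 20_000
            lam_oracle = brentq(
                lambda lam: stats.poisson.sf(0, lam) - p_hat, 1e-9, 20.0,
                xtol=1e-12,
            )
            assert est.lambda_hat == pytest.approx(lam_oracle, rel=1e-6)

    def test_binomial_ci_brackets_point_and_widens_at_low_counts(self):
        delta = estimate_concentration(18_000, 5, ci_method="delta")
        exact = estimate_concentration(18_000, 5, ci_method="binomial")
        assert exact.ci_low < exact.copies_per_ul < exact.ci_high
        # exact interval is wider than the normal approximation here
        assert exact.ci_high - exact.ci_low > delta.ci_high - delta.ci_low

    def test_confidence_level_widens_interval(self):
        lo = estimate_concentration(10_000, 500, confidence_level=0.90)
        hi = estimate_concentration(10_000, 500, confidence_level=0.99)
        assert hi.ci_high - hi.ci_low > lo.ci_high - lo.ci_low


class TestQuantifyChip:
    def test_coverage_of_both_channels(self):
        """Each channel's 95% CI covers its truth at ~nominal rate."""
        hits_t = hits_s = 0
        n_rep = 300
        for seed in range(n_rep):
            cfg = SimulationConfig(
                true_target_copies_per_ul=500,
                true_spike_copies_per_ul=250,
                seed=seed,
            )
            chip, truth = simulate_chip(cfg)
            r = quantify_chip(chip)
            hits_t += r.target.ci_low <= 500 <= r.target.ci_high
            hits_s += r.spike.ci_low <= 250 <= r.spike.ci_high
        assert 0.91 <= hits_t / n_rep <= 0.985
        assert 0.91 <= hits_s / n_rep <= 0.985

    def test_all_negative_chip_quantifies_to_zero(self):
        cfg = SimulationConfig(
            true_target_copies_per_ul=0.0, true_spike_copies_per_ul=250,
            fill_rate=0.95, seed=3,
        )
        chip, _ = simulate_chip(cfg)
        r = quantify_chip(chip, fam_threshold=MID_THRESHOLD)
        assert r.target.copies_per_ul == 0
        assert r.qc.passed  # ~19,000 valid wells

    def test_qc_failure_still_reports_estimates(self):
        cfg = SimulationConfig(fill_rate=0.4, seed=5)  # ~8,000 valid wells
        chip, _ = simulate_chip(cfg)
        r = quantify_chip(chip)
        assert not r.qc.passed
        assert r.target.copies_per_ul > 0
        assert r.spike.copies_per_ul > 0

    def test_saturated_chip_raises_through_pipeline(self):
        cfg = SimulationConfig(
            true_target_copies_per_ul=30_000,  # lambda ~ 24: every well occupied
            true_spike_copies_per_ul=250,
            seed=2,
        )
        with pytest.warns(UserWarning, match="saturation"):
            chip, _ = simulate_chip(cfg)
        with pytest.raises(SaturatedChipError):
            quantify_chip(chip, fam_threshold=MID_THRESHOLD)


class TestSpikeinNormalize:
    def test_two_chip_hand_example(self):
        results = [
            make_result(100, 1000, dilution=5, sample="A"),
            make_result(200, 400, dilution=1, sample="B"),
        ]
        out = spikein_normalize(results)
        assert [n.normalization_factor for n in out] == [1.5, 0.75]
        assert [n.normalized_copies_per_ul for n in out] == [7500, 300]

    def test_identical_spikes_leave_only_dilution_scaling(self):
        results = [make_result(150, t, dilution=d, sample=s)
                   for t, d, s in [(10, 1, "A"), (20, 5, "B"), (30, 10, "C")]]
        out = spikein_normalize(results)
        for n in out:
            assert n.normalization_factor == 1.0
            assert n.normalized_copies_per_ul == pytest.approx(
                n.raw_copies_per_ul * n.dilution_factor
            )

    def test_singleton_collection(self):
        out = spikein_normalize([make_result(123, 456, dilution=10)])
        assert out[0].normalization_factor == 1.0
        assert out[0].normalized_copies_per_ul == pytest.approx(4560)

    def test_zero_spike_names_the_chip(self):
        good = make_result(100, 10, sample="ok")
        bad = make_result(0.0, 10, sample="dead", chip_id="chip-dead")
        # a zero spike cannot even be constructed as a valid estimate ratio,
        # so build it via object construction with 0 concentration
        with pytest.raises(SpikeInError, match="chip-dead"):
            spikein_normalize([good, bad])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1000.0))
    def test_scale_equivariance_in_spike_units(self, c):
        """Rescaling all spike values leaves normalized targets unchanged."""
        base = [make_result(100, 1000, 5, "A"), make_result(250, 400, 1, "B"),
                make_result(80, 50, 10, "C")]
        scaled = [make_result(r.spike.copies_per_ul * c, r.target.copies_per_ul,
                              r.dilution_factor, r.sample_id)
                  for r in base]
        out1 = spikein_normalize(base)
        out2 = spikein_normalize(scaled)
        for a, b in zip(out1, out2):
            assert b.normalized_copies_per_ul == pytest.approx(
                a.normalized_copies_per_ul
            )

    def test_per_sample_scope_uses_sample_means(self):
        results = [
            make_result(100, 10, sample="A", chip_id="a1"),
            make_result(300, 10, sample="A", chip_id="a2"),
            make_result(50, 10, sample="B", chip_id="b1"),
        ]
        out = spikein_normalize(results, scope="per-sample")
        # sample A reference = 200; sample B singleton reference = 50
        assert out[0].normalization_factor == pytest.approx(2.0)
        assert out[1].normalization_factor == pytest.approx(200 / 300)
        assert out[2].normalization_factor == pytest.approx(1.0)
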