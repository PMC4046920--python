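"""Live gating, conservative gate calibration and frequency estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radr.flow import (GateSpec, calibrate_gate, live_gate, percent_positive,
                       recombinant_frequency)
from radr.simulate import FlowSimConfig, simulate_flow_events


def wt_table(n, seed=0):
    return simulate_flow_events(FlowSimConfig(n_events=n, seed=seed))


class TestLiveGate:
    def test_debris_excluded_live_fraction(self):
        df = simulate_flow_events(FlowSimConfig(n_events=50_000, seed=1))
        live = live_gate(df)
        assert live.is_debris.mean() < 0.005
        assert 0.75 <= len(live) / len(df) <= 0.93

    def test_full_quantile_bounds_identity(self):
        df = wt_table(5_000, seed=2)
        spec = GateSpec(live_quantiles=(0.0, 1.0))
        assert len(live_gate(df, spec)) == len(df)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            live_gate(pd.DataFrame(columns=["fsc", "ssc", "green", "orange"]))


class TestCalibrateGate:
    def test_target_fpr_one_passes_everything(self):
        df = wt_table(20_000, seed=3)
        gate = calibrate_gate(df, target_fpr=1.0)
        live = live_gate(df, gate)
        assert gate.is_positive(live).all()

    def test_gaussian_tail_matches_analytic_quantile(self):
        """The discriminant of the autofluorescent cloud is exactly Gaussian
        (a linear combination of the bivariate-normal log channels), so the
        tail-extrapolated threshold must match the closed-form normal
        quantile computed from the generator's own parameters."""
        cfg = FlowSimConfig(n_events=200_000, debris_fraction=0.0, seed=4)
        df = simulate_flow_events(cfg)
        fpr = 1e-4
        gate = calibrate_gate(df, target_fpr=fpr, tail_mode="gaussian",
                              live_quantiles=(0.0, 1.0))
        p = cfg.autofluor_params
        k, rho, sd = gate.slope_k, p["correlation"], p["sd_log"]
        mu_d = p["mean_log_green"] - k * p["mean_log_orange"]
        sd_d = sd * np.sqrt(1.0 + k**2 - 2.0 * rho * k)
        analytic = mu_d + stats.norm.ppf(1 - fpr) * sd_d
        assert gate.threshold_t == pytest.approx(analytic, abs=0.01 * abs(sd_d) + 5e-3)

    def test_small_reference_empirical_mode_errors(self):
        df = wt_table(10_000, seed=5)
        with pytest.raises(ValueError, match="tail"):
            calibrate_gate(df, target_fpr=1e-6, tail_mode="empirical")

    def test_invalid_fpr_errors(self):
        df = wt_table(1_000, seed=6)
        with pytest.raises(ValueError):
            calibrate_gate(df, target_fpr=0.0)

    def test_calibration_consistency_on_heldout_reference(self):
        """Gated WT fraction on held-out data matches target_fpr within
        binomial error, pooled across seeds."""
        fpr = 1e-3
        hits, total = 0, 0
        for seed in range(10):
            ref = wt_table(100_000, seed=100 + seed)
            heldout = wt_table(100_000, seed=200 + seed)
            gate = calibrate_gate(ref, target_fpr=fpr)
            live = live_gate(heldout, gate)
            hits += int(gate.is_positive(live).sum())
            total += len(live)
        expected = fpr * total
        assert abs(hits - expected) < 4 * np.sqrt(expected)

    def test_lower_fpr_never_gates_more(self):
        sample = simulate_flow_events(FlowSimConfig(
            n_events=200_000, positive_frequency=1e-4, seed=7))
        ref = wt_table(200_000, seed=8)
        counts = []
        for fpr in [1e-2, 1e-3, 1e-4, 1e-5]:
            gate = calibrate_gate(ref, target_fpr=fpr)
            live = live_gate(sample, gate)
            counts.append(int(gate.is_positive(live).sum()))
        assert counts == sorted(counts, reverse=True)


class TestFrequency:
    def test_zero_positives_rule_of_three_upper_bound(self):
        n = 1_000_000
        rng = np.random.default_rng(9)
        df = pd.DataFrame(dict(
            fsc=rng.normal(1000, 50, n), ssc=rng.normal(800, 50, n),
            green=np.full(n, 100.0), orange=np.full(n, 100.0),
        ))
        gate = GateSpec(live_quantiles=(0.0, 1.0), slope_k=1.0,
                        threshold_t=10.0)
        est = recombinant_frequency(df, gate)
        assert est.positives == 0
        assert est.per_million == 0.0
        expected_upper = (1 - 0.025 ** (1 / n)) * 1e6  # ~3.69/million
        assert est.ci_high_per_million == pytest.approx(expected_upper, rel=0.01)

    def test_all_events_positive(self):
        df = wt_table(10_000, seed=10)
        gate = calibrate_gate(df, target_fpr=1.0)
        est = recombinant_frequency(df, gate)
        assert est.per_million == pytest.approx(1e6)

    def test_planted_frequency_recovered_with_interval_coverage(self):
        ref = wt_table(500_000, seed=11)
        gate = calibrate_gate(ref, target_fpr=1e-6, tail_mode="gaussian")
        covered = 0
        ests = []
        for seed in range(10):
            sample = simulate_flow_events(FlowSimConfig(
                n_events=500_000, positive_frequency=2e-5, seed=300 + seed))
            est = recombinant_frequency(sample, gate)
            ests.append(est.per_million)
            if est.ci_low_per_million <= 20.0 <= est.ci_high_per_million:
                covered += 1
        assert covered >= 9
        assert np.mean(ests) == pytest.approx(20.0, rel=0.25)

    def test_estimator_unbiased_at_1e5(self):
        """Mean recovered frequency across seeds within 5% of the planted
        1e-5 at n=1e6 per sample."""
        ref = wt_table(1_000_000, seed=12)
        gate = calibrate_gate(ref, target_fpr=1e-6, tail_mode="gaussian")
        ests = []
        for seed in range(60):
            sample = simulate_flow_events(FlowSimConfig(
                n_events=1_000_000, positive_frequency=1e-5, seed=400 + seed))
            ests.append(recombinant_frequency(sample, gate).per_million)
        assert np.mean(ests) == pytest.approx(10.0, rel=0.05)


class TestPercentPositive:
    def test_high_frequency_positive_control(self):
        sample = simulate_flow_events(FlowSimConfig(
            n_events=100_000, positive_frequency=0.94, seed=13))
        ref = wt_table(100_000, seed=14)
        gate = calibrate_gate(ref, target_fpr=1e-4)
        est = percent_positive(sample, gate)
        assert est.per_million == pytest.approx(94.0, abs=1.0)  # percent scale

    def test_extremes(self):
        ref = wt_table(50_000, seed=15)
        gate = calibrate_gate(ref, target_fpr=1e-4)
        none = simulate_flow_events(FlowSimConfig(n_events=50_000, seed=16))
        assert percent_positive(none, gate).per_million == pytest.approx(0.0, abs=0.05)
        allpos = simulate_flow_events(FlowSimConfig(
            n_events=50_000, positive_frequency=1.0, seed=17))
        assert percent_positive(allpos, gate).per_million == pytest.approx(100.0, abs=0.1)
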