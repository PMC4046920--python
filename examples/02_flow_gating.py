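"""Calibrate a conservative flow gate and recover a rare planted frequency.

An autofluorescent-only (wild-type) reference calibrates the sloped
two-channel discriminant to a 1e-6 false-positive target; a sample with
EGFP-positive cells planted at 2e-5 is then gated and the frequency per
million live cells reported with its exact binomial interval.
"""

from radr.flow import calibrate_gate, recombinant_frequency
from radr.simulate import FlowSimConfig, simulate_flow_events

reference = simulate_flow_events(FlowSimConfig(n_events=1_000_000, seed=11))
gate = calibrate_gate(reference, target_fpr=1e-6, tail_mode="gaussian")
print(f"gate: d = log10(green) - {gate.slope_k:.3f} * log10(orange) "
      f">= {gate.threshold_t:.3f}  ({gate.tail_mode} calibration)")

sample = simulate_flow_events(FlowSimConfig(
    n_events=2_000_000, positive_frequency=2e-5, seed=12))
est = recombinant_frequency(sample, gate)
print(f"positives: {est.positives} / {est.total_gated} live events")
print(f"frequency: {est.per_million:.1f} per million "
      f"(95% CI {est.ci_low_per_million:.1f}-{est.ci_high_per_million:.1f})")
# The planted 20/million lies inside the exact binomial interval; the
# conservative gate costs essentially no sensitivity because EGFP shifts
# positives ~1.5 decades off the autofluorescent diagonal.
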