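"""Why count only large foci: power of a young-vs-old cohort comparison.

Two cohorts differ only in large-focus (converted crypt) density, 3x, on
top of a heavy small transit-cell focus load. Counting everything drowns
the signal in small-focus noise; counting only large foci detects it.
"""

from radr.quantify import compare_cohorts, counting_mode_power
from radr.simulate import COHORT_PRESETS, simulate_cohort_counts

samples = simulate_cohort_counts(COHORT_PRESETS["aged-colon"],
                                 n_per_group=6, seed=2)
for mode in ["total", "large_only"]:
    cmp, _ = compare_cohorts(samples, mode=mode)
    print(f"{mode:>10}: medians {cmp.median_x:.0f} vs {cmp.median_y:.0f} /cm^2, "
          f"U={cmp.u_statistic:.0f}, two-tailed p={cmp.p_value:.3f} ({cmp.mode})")

power = counting_mode_power(
    {"young": (400.0, 40.0), "old": (400.0, 120.0)},
    n_per_group=6, n_reps=200, seed=55)
print(f"power at n=6/group over 200 replicates: "
      f"large_only={power['large_only']:.2f}, total={power['total']:.2f}")
# One realized cohort gives the per-experiment picture; the replicate loop
# shows large-only counting reaching ~80% power where total counting stays
# near the type-I floor.
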