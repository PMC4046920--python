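# radr

Automated quantification of homologous-recombination (HR) events in mouse
reporter tissue, for labs using direct-repeat EGFP reporters (RaDR-GFP /
FYDR-style mice). An HR event at the reporter locus restores fluorescence,
so recombination shows up two ways: as **fluorescent foci** in intact,
compressed whole organs imaged at low magnification, and as rare
**EGFP-positive cells** in flow cytometry. This package implements both
readouts end to end, plus a synthetic-data generator that makes every stage
testable without any tissue.

## What it computes

**Foci counting.** A whole-organ frame is median-filtered, and candidate
foci are the *extended maxima* — the regional maxima of the h-maxima
transform (morphological reconstruction by dilation of `I − h` under `I`),
i.e. the intensity domes taller than `h`. Each candidate is modeled as an
isotropic 2-D Gaussian

```
I(x, y) = b + A·exp(−((x−x0)² + (y−y0)²) / 2σ²)
```

whose fit sets an adaptive per-focus threshold `b + f·A` (default `f = 0.5`,
the half maximum, with analytic contour radius `σ√(2 ln 2)`). Segmented
candidates are classified by a two-stage SVM with an RBF kernel — true focus
vs. noise, then large bright focus vs. small irregular focus — and accepted
foci are summed over the entire organ and divided by the tissue area
(foci/cm²). A conservative mode raises the stage-1 decision threshold so
false positives are essentially eliminated at the cost of false negatives.
Cohorts of per-animal frequencies are compared with the two-tailed
Mann–Whitney U test (exact by enumeration for small tie-free samples).

**Rare-event flow gating.** Autofluorescent cells form a correlated
diagonal cloud in the (log green, log orange) plane; EGFP shifts events
along the green axis. The gate is the sloped discriminant
`d = log₁₀(green) − k·log₁₀(orange)`, with `k` fit as the principal axis of
a wild-type reference and the threshold calibrated to a target
false-positive rate (default 10⁻⁶, the detection floor). Frequencies are
reported per million live-gated cells with exact binomial 95% intervals.

## Worked example

```bash
python examples/01_simulate_and_count.py
```

```
planted foci:        136
accepted foci:       131 (large: 37)
tissue area:         1.001 cm^2
recovered frequency: 130.9 foci/cm^2
```

A 1 cm² synthetic pancreas planted at the spontaneous rate (~140 foci/cm²)
is counted by the full pipeline with a simulator-trained classifier: 131 of
136 planted foci are recovered (losses are the dimmest σ≈1 px foci and
merged neighbors), and no noise dome is accepted. `examples/02_flow_gating.py`
recovers a planted 2×10⁻⁵ recombinant-cell frequency through a gate
calibrated at 10⁻⁶, and `examples/03_cohort_comparison.py` shows why
large-focus-only counting detects a 3× difference in clonal-focus density
(p = 0.004, ~80% power at n = 6/group) that total counting misses
(p = 0.49) under a heavy small-focus load.

The same stages are scriptable from a shell via the thin `radr` CLI
(`radr simulate | mask | detect | count | train | flow | compare`).

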