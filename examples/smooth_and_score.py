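"""Smooth a noisy redox curve and compute a %RSI tolerance score.

Builds one control and one stressed well for a single strain, runs the
standard kinetic preprocessing (baseline anchor -> monotone smoothing ->
replicate mean) and scores stress tolerance at the 50-h endpoint.
"""

import numpy as np

from phenoplate import (
    ConditionSpec,
    aggregate_replicates,
    baseline_transform,
    score_study,
    simulate_curve,
    smooth_monotone,
)

conditions = [
    ConditionSpec("ctrl30", "glucose control", 6, "%w/v", 30, 50, ""),
    ConditionSpec("sorb10", "sorbitol", 10, "%w/v", 30, 50, "ctrl30"),
]

curves = {}
for ci, (cond, theta) in enumerate((("ctrl30", 1.0), ("sorb10", 0.55))):
    reps = [
        simulate_curve("YPS606", cond, rep, A=60, r=0.35, t_m=12, b=3,
                       theta=theta, sigma=2.0, seed=[42, rep, ci])
        for rep in (1, 2, 3)
    ]
    smoothed = [smooth_monotone(baseline_transform(c)) for c in reps]
    print(f"{cond}: smoothing windows used: {[s.window for s in smoothed]}")
    curves[("YPS606", cond)] = aggregate_replicates(smoothed)

(score,) = score_study(curves, conditions)
print(f"RSI under stress at 50 h : {score.rsi_stress:.1f} units")
print(f"RSI under control at 50 h: {score.rsi_control:.1f} units")
print(f"%RSI                     : {score.percent_rsi:.1f} %")
print(
    "\nThe strain retains about"
    f" {score.percent_rsi:.0f}% of its unstressed metabolic output under"
    " 10% sorbitol; the planted tolerance multiplier was 0.55, so the"
    " pipeline recovers the attenuation despite 2-unit imaging noise."
)
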