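"""Quantify the delay a stress imposes on a fermentation-progress curve.

A sensitive strain's progress curve is generated with a planted 2-hour
lag plus 1%-of-amplitude noise; the grid-search estimator recovers the
delay at the sampling resolution (15 min).
"""

from phenoplate import estimate_time_shift, simulate_curve, smooth_monotone

A = 50.0
ref = simulate_curve("control", "ferm", 1, A=A, r=0.3, t_m=20, sigma=0.01 * A,
                     seed=[1, 0])
stressed = simulate_curve("inhibited", "ferm", 1, A=A, r=0.3, t_m=20, delta=2.0,
                          sigma=0.01 * A, seed=[1, 1])

shift = estimate_time_shift(
    smooth_monotone(ref).to_series(), smooth_monotone(stressed).to_series()
)
print(f"planted delay   : 2.00 h")
print(f"recovered delay : {shift:.2f} h (grid resolution 0.25 h)")
print(
    "\nThe inhibited fermentation tracks the control curve shifted by"
    f" {shift:.2f} hours - the kind of slow-down a stress-sensitive strain"
    " shows when inhibitors are present."
)
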