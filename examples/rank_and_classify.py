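"""Rank strains of a synthetic study by %RSI and label the extremes.

Runs the full scoring path on a 20-strain study and prints one stress
condition's ranking with tolerant / intermediate / sensitive labels.
"""

from phenoplate import (
    SyntheticStudySpec,
    aggregate_replicates,
    baseline_transform,
    classify_extremes,
    rank_strains,
    score_study,
    simulate_study,
    smooth_monotone,
)

spec = SyntheticStudySpec(n_strains=20, replicates=3, noise_sd=2.0, seed=5)
curves, truth = simulate_study(spec)

smoothed = [smooth_monotone(baseline_transform(c)) for c in curves]
groups = {}
for s in smoothed:
    groups.setdefault((s.strain_id, s.condition_id), []).append(s)
means = {k: aggregate_replicates(g) for k, g in sorted(groups.items())}
scores = score_study(means, spec.conditions)

cond = "etoh10"
table = rank_strains([s for s in scores if s.condition_id == cond])
labels = classify_extremes(table, k_sensitive=5, k_tolerant=10)

print(f"Ranking for {cond} (ethanol 10% v/v), most tolerant first:\n")
print(f"{'rank':>4}  {'strain':<8} {'%RSI':>7}  class         planted")
for pos, ((strain, pct), label) in enumerate(zip(table.entries, labels), start=1):
    print(
        f"{pos:>4}  {strain:<8} {pct:>7.1f}  {label:<12}  "
        f"{truth.strain_class[strain]}"
    )
print(
    "\nStrains the generator planted as tolerant (amplitude multiplier"
    " 0.8-1.0) fill the top of the table, the planted-sensitive block"
    " (0.1-0.3) the bottom; %RSI ranks recover the hidden classes."
)
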