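# phenoplate

Analysis of phenotype-microarray (PM) kinetics for high-throughput
stress-tolerance profiling of microbial strain panels — the kind of
screen used to pick robust *Saccharomyces* strains for lignocellulosic
bioethanol fermentations, where candidate yeasts face osmotic, ethanol
and temperature stress plus hydrolysate inhibitors (weak acids, furans,
phenolics).

A PM instrument photographs plates at 15-minute intervals and converts a
redox-sensitive dye into an arbitrary-unit **redox signal intensity
(RSI)** per well, a proxy for metabolic output. `phenoplate` turns those
kinetic curves into tolerance rankings and phenotypic clusterings:

1. **Kinetics** — baseline-anchor each curve, then smooth it with the
   smallest centred moving-average window (odd, ≤ 25 points) that
   removes every negative slope; average ≥ 3 replicates.
2. **Scoring** — percentage redox signal intensity of control,

   %RSI = 100 · RSI(stress, t*) / RSI(control, t*),

   at endpoint t* = 50 h (24 h for 40 °C thermal stress, applied to both
   curves). Strains are ranked per condition and the extremes labelled
   (by default 10 tolerant, 5 sensitive).
3. **Profiles** — strains × conditions log₂ ratios versus a reference
   strain (default S288C), clipped to ±3.
4. **Clustering** — centred Pearson distance d = 1 − r between strain
   profiles, agglomerated with size-weighted average linkage (UPGMA,
   Sokal–Michener), exported as Cluster 3.0 `.cdt`/`.gtr` for Java
   TreeView and as ultrametric Newick.
5. **Fermentation delay** — a grid-search estimator for the time shift
   δ minimising Σ[test(t) − ref(t−δ)]² between cumulative progress
   curves, at the 15-min sampling resolution.

Because raw OmniLog exports for such screens are rarely published, the
package ships a first-class synthetic-study generator (logistic redox
curves with planted tolerance blocks, lags and seeded noise) so every
stage is testable against known ground truth.

## Worked example

```bash
python examples/time_shift.py
```

```
planted delay   : 2.00 h
recovered delay : 2.00 h (grid resolution 0.25 h)
```

A progress curve generated with a hidden 2-hour lag and 1 %-of-amplitude
noise is smoothed and aligned against its control; the estimator returns
the delay exactly at grid resolution — the readout used to confirm that
an inhibitor-sensitive strain slows a fermentation.

```bash
python examples/smooth_and_score.py
```

```
sorb10: smoothing windows used: [25, 25, 25]
RSI under stress at 50 h : 32.8 units
RSI under control at 50 h: 61.1 units
%RSI                     : 53.7 %
```

Three noisy replicates per condition are monotone-smoothed and averaged;
the strain keeps ~54 % of its unstressed metabolic output under 10 %
sorbitol, recovering the planted tolerance multiplier of 0.55.

Other examples: `rank_and_classify.py` (per-condition ranking with
tolerant/intermediate/sensitive labels), `cluster_profiles.py`
(log-ratio matrix → UPGMA → Newick), `full_pipeline.py` (the complete
bundle, equal to `phenoplate demo`).

## Command line

```bash
phenoplate demo --outdir demo_out --seed 0          # end-to-end on synthetic data
phenoplate simulate --n-strains 90 --outdir study   # write synthetic input tables
phenoplate run --kinetics study/kinetics.tsv \
               --conditions study/conditions.tsv \
               --strains study/strains.tsv --outdir out
phenoplate score ... / phenoplate cluster ...       # individual stages
```

Inputs are tidy delimited text (strain, condition, replicate, time_h,
signal) plus a condition table linking each stress to its control and
endpoint. Outputs: tolerance-score and rank TSVs, the log-ratio matrix,
`clustered.cdt`/`.gtr`, `dendrogram.nwk` and a JSON run manifest.
Reruns with the same configuration and seed are byte-identical.

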