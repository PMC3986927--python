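# Methods

## The measurement and the statistic

A phenotype-microarray run incubates a strain panel in microwells with a
redox-sensitive tetrazolium dye and photographs the plates every 15
minutes; pixel intensity of the reduced dye gives a cumulative,
arbitrary-unit *redox signal intensity* (RSI) per well. Because dye
reduction is irreversible, the true signal is non-decreasing in time;
apparent decreases are imaging noise.

Stress tolerance is summarised by the **percentage redox signal
intensity of control**,

    %RSI = 100 · RSI_stress(t*) / RSI_control(t*),

evaluated at a fixed endpoint t\* on both curves. We use t\* = 50 h as
the standard endpoint and t\* = 24 h for assays at 40 °C (runs at that
temperature are truncated to 24 h; the matched control is read at the
same 24 h so the ratio compares like with like). Where a protocol
wavers between 48 h and 50 h readings we standardise on 50 h;
`endpoint_hours` is configurable per condition. %RSI may exceed 100 —
mild heat can stimulate output — so no ceiling is applied.

## Kinetic preprocessing

**Baseline anchor.** Each raw curve is shifted by its first sample and
floored at zero. This removes well-to-well offsets in initial dye state
while preserving the arbitrary-unit scale (healthy control endpoints
fall in the 35–75-unit range). The transform is deliberately minimal;
the smoothing step, not the transform, carries the noise handling.

**Monotone smoothing.** The smoother tries centred moving averages with
odd windows w = 1, 3, 5, … up to a cap (default 25 points ≈ 6 h) and
returns the first window whose output has no negative slope. The window
is centred and truncated at the array bounds: at index i the mean runs
over `[max(0, i−h), min(n−1, i+h)]` with h = (w−1)/2. Truncation (rather
than shrinking both sides symmetrically) keeps the effective window as
wide as possible near the edges, which is what lets small windows
monotonise curves whose only defects sit at the ends; on `[0, 2, 1, 3]`
window 3 yields `[1, 1, 2, 2]`. If even the capped window leaves
decreases — routine for white noise on a plateau — the residual
negative slopes are counted (exposed as
`SmoothedCurve.residual_negative_slopes` and totalled in the run
manifest) and a running-maximum pass enforces the invariant, so every
downstream consumer can rely on a cumulative curve. The running maximum
biases plateau values upward by roughly the noise amplitude surviving
the average; since stress and control curves receive the same
treatment, the ratio statistic is insensitive to it (parameter-recovery
results below confirm this empirically).

**Replicate handling.** Each replicate is transformed and smoothed
individually, then replicates are averaged pointwise (label `"mean"`).
Scores are computed on replicate-mean smoothed curves rather than as
means of per-replicate ratios; with ≥ 3 replicates and matched grids the
two differ only at second order, and the mean-curve route gives one
well-defined endpoint pair per strain.

**Endpoint rule.** The endpoint value is the signal at the latest
sample at or before t\*, with no interpolation — exact on the 0.25-h
grid (50 h = index 200) and deterministic on any grid.

**Time-shift estimation.** For two non-decreasing progress curves on a
common grid (e.g. fermentation weight-loss curves), the delay of the
test curve is the δ ≥ 0 minimising the mean squared difference between
test(t) and ref(t − δ) over the overlapping window, found by exhaustive
search over grid multiples. Resolution therefore equals the sampling
step (15 min), which matches the precision at which such delays are
meaningful; ties resolve to the smallest shift, and the overlap is
required to cover at least half the series so plateau-on-plateau
alignments cannot win spuriously.

## Scoring, ranking, profiles

A control signal below ε (default 1 RSI unit) marks a well that never
grew; its ratio is reported as 0 with a `low_control` flag instead of
propagating a near-infinite value, and such strains rank last,
labelled. The ε-guard is configurable — a signal under ~20 units
already indicates poor growth on this scale, and 1 unit is well below
any real signal.

Rankings sort by descending %RSI with alphabetical tie-break, making
tables deterministic. Extreme classes default to the top 10 (tolerant)
and bottom 5 (sensitive) strains per condition, mirroring common
reporting practice; both k's are parameters. A cross-condition
"all-stress" summary by unweighted mean rank is provided but labelled
non-canonical — no standard aggregation rule exists for this assay.

Phenotypic profiles are log₂(%RSI_strain / %RSI_reference) per
condition, clipped to ±3 (the conventional heat-map colour range),
reference strain S288C by default. The reference row is exactly zero;
cells involving a low-control strain or reference are missing, not
zero. Clustering operates on this log-ratio matrix — the displayed,
reference-normalised quantity — rather than raw %RSI; both are
accessible if the other is wanted.

Condition–condition comparisons use the sample Pearson correlation
across strains, pairwise-complete with ≥ 3 strains; zero variance makes
the correlation undefined and NaN is returned rather than a fabricated
value. The columns compared can hold endpoint signals (sugar-utilisation
comparisons) or %RSI (stress comparisons), whichever the question needs.

## Clustering

Distances are d = 1 − r with r the (mean-centred) Pearson correlation
between two strain profiles over their shared non-missing conditions
(minimum 2). A flat profile has undefined correlation; r is treated as
0 (distance 1 to everything) and the row flagged. d ∈ [0, 2]: 0 for
identical shapes, 2 for mirrored ones.

Agglomeration is size-weighted average linkage (UPGMA proper): merge
the pair at minimum distance — equivalently, scan the similarity matrix
for its highest value — recording the merge at that distance, with the
new cluster's distance to node k being (nᵢ·d(k,i) + nⱼ·d(k,j))/(nᵢ+nⱼ).
UPGMA guarantees non-decreasing merge heights (no inversions), which the
implementation validates on every run. Ties break by smallest node
creation index (leaves in input order, then internal nodes in merge
order), with the older node as left child: published tie rules for the
classic desktop tools are undocumented, so determinism, not
bit-compatibility with any one tool, is the contract. Tests verify
exact agreement (≤ 1e-12) with a brute-force oracle that recomputes
every inter-cluster distance from the original matrix each step, and
with an independent library implementation via cophenetic distances.

**Exports.** `.gtr` lists merges as `NODEkX child1 child2 similarity`
with similarity = 1 − height (the correlation-mode convention of the
Cluster 3.0 family); `.cdt` carries the matrix with rows in dendrogram
leaf order, 6 significant digits, missing cells blank. Newick output
halves merge heights so the tree is ultrametric: a node at height h
sits at depth h/2, every leaf is equidistant from the root, and the
path length between two leaves equals their cophenetic distance.
Column (condition) clustering is not performed; strain clustering is
the analysis target.

## Synthetic studies

The generator exists because raw kinetic exports for screens of this
design are effectively never deposited. It is an explicit stand-in with
stated structure, not a mechanistic model of dye chemistry. A well's
curve is a logistic,

    S(t) = b + θ·A / (1 + e^{−r(t − t_m − δ)}) + ε_t,  ε_t ~ N(0, σ²),

floored at 0 on the 0.25-h grid (96-h runs, 24 h at 40 °C). Defaults:

| parameter | default | why |
|---|---|---|
| A, amplitude | U(35, 75) units per strain | observed endpoint range of healthy control wells |
| r, rate | U(0.25, 0.5) h⁻¹ | sigmoid completes well before the 50-h endpoint |
| t_m, midpoint | U(8, 16) h | typical lag-to-log timing for yeast on glucose |
| b, baseline | U(1, 5) units | initial dye state offset, removed by the anchor |
| σ, noise | 2 units | ≈ 3–6 % of the endpoint range |
| replicates | 3 | the assay's minimum replication |
| panel | 1 control + 9 stresses | control glucose 30 °C; sorbitol ×2, ethanol, 35/40 °C, acetic, formic, furfural, vanillin |

A study of 90 strains plants a tolerant block (θ ~ U(0.8, 1.0)), a
sensitive block (θ ~ U(0.1, 0.3), plus a lag δ ~ U(1, 3) h) and an
intermediate remainder (θ ~ U(0.4, 0.7)); controls have θ = 1, δ = 0.
Stress is thus modelled as amplitude attenuation plus lag — the two
failure modes seen in real screens (reduced metabolic output; delayed
fermentations). Blocks are strain-level so the same strains are
tolerant across conditions, giving the log-ratio matrix a recoverable
block structure. One global seed drives everything; each curve draws
from a substream keyed by (seed, strain, condition, replicate), so
studies are reproducible to the bit and insensitive to generation
order. A separate helper generates log-ratio matrices directly with two
mirrored-profile blocks and log-scale noise (default σ = 0.3) for
cluster-recovery checks — mirrored shapes, not offset magnitudes,
because a centred-Pearson metric is blind to profile level by design.

What the generator does *not* emulate: dose–response shape across
inhibitor concentrations, evaporation artefacts beyond the 24-h
truncation, correlated (non-white) imaging noise, plate-position
effects, and condition-specific curve shapes. Passing recovery tests
therefore show the pipeline's statistics are consistent and invertible
on sigmoidal-plus-white-noise data at realistic signal-to-noise — they
do not certify behaviour on systematically biased real plates.

## Numerical conventions

- Monotonicity tolerance 1e-9 (signal units per step) both when testing
  slopes and in the `SmoothedCurve` invariant.
- Distance-matrix symmetry and UPGMA oracle agreement at 1e-12;
  distances clamped to [0, 2] against float wobble.
- Tables serialize numbers at 6 significant digits; round-trips are
  exact to that precision.
- Degenerate inputs fail loudly with the offending series/row named:
  non-uniform grids, duplicate time rows, dangling control references,
  mixed-condition rankings, a missing reference strain.
- With σ = 0 the smoother is the identity on the logistic (window 1)
  and the pipeline's %RSI equals the closed form
  100·θ·(L(t\*−δ) − L(−δ))/(L(t\*) − L(0)), L(t) = 1/(1+e^{−r(t−t_m)}),
  to 1e-9 — the analytic check used in the tests and acceptance script.

## Problem sizes used in the shipped checks

The test battery and `scripts/acceptance.py` run the full-scale study
(90 strains × 10 conditions × 3 replicates, 385-point curves), a
1,000-curve smoothing battery, 200 random UPGMA oracle matrices
(n = 3–8), and a 40-strain cluster-recovery matrix; the complete set
executes in well under a minute on a single core, so nothing is
down-scaled relative to the design being emulated.

## Known limitations

- The smoothing cap plus running maximum slightly inflates plateau
  endpoints under white noise; ratios are unaffected to first order but
  absolute endpoint values carry the bias.
- Doubling-time / growth-rate inference from optical-density curves is
  out of scope; the pipeline scores redox endpoints only.
- The time-shift estimator assumes a pure delay; shape changes between
  curves are absorbed into the MSE and can bias δ.
- `.cdt`/`.gtr` output targets the TreeView dialect (GID/UNIQID/NAME
  header, GENEiX/NODEkX naming); array-tree (`.atr`) output and column
  clustering are not produced.
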