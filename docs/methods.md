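# Methods

## Network construction

Input is a per-subject square, nonnegative, (near-)symmetric matrix of
streamline counts over a parcellation (default 90 regions). Construction:

1. **Symmetrization** — average with the transpose. Tractography is
   undirected, so real asymmetry indicates corrupted input; relative
   asymmetry beyond 1e-6 raises an error rather than being silently fixed.
2. **Diagonal removal** — self-connections are meaningless here.
3. **Noise threshold** — edges with fewer than 10 streamlines are zeroed.
   The threshold is stated in raw streamline units, so it is applied
   *before* normalization. Whether thresholding precedes or follows
   symmetrization is genuinely open in pipelines of this kind; averaging
   first is the default because the threshold then acts on the best
   estimate of each edge's count. `min_streamlines` is configurable.
4. **Total-fiber normalization** — divide by the sum of upper-triangle
   counts (each anatomical connection counted once). After this the
   upper-triangle weights sum to 1. The pre-normalization sum is retained
   (`total_fibers`), so raw counts are always recoverable.

A matrix whose every edge falls below threshold is a degenerate network and
raises an explicit error.

### Raw versus normalized strength

Total-fiber normalization fixes each subject's summed weight at exactly 1,
which *removes* any diffuse (global multiplicative) group difference from
normalized strength — the very signal a severity dose-response on strength
consists of. Published strength values in this literature are ~1e4 per
node, i.e. raw streamline units. The measure table therefore carries both
`strength` (normalized weights) and `raw_strength` (streamline units), and
all group comparisons of strength use `raw_strength`. Efficiency and
clustering are computed on normalized weights, where the diffuse scaling
cancels and only topological/threshold effects remain.

## Graph measures

Weight-to-length mapping is `l = 1/w` (the Brain Connectivity Toolbox
convention; `-log w` is available via `mapping="neglog"`). All-pairs
distances use Dijkstra (scipy's csgraph); unreachable pairs are infinite.

- **Global efficiency**: mean of `1/d_ij` over ordered pairs, unreachable
  pairs contributing 0 (infinitely long paths are excluded by
  construction). **Nodal efficiency**: the per-node row mean of `1/d_ij`.
- **Characteristic path length**: mean `d_ij` over *reachable* ordered
  pairs; undefined (error) when no pair is reachable.
- **Clustering**: the Onnela geometric-mean form on weights max-scaled to
  [0, 1], `C_i = Σ_{jh}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1))` with binary
  degree `k_i`; `C_i = 0` for `k_i < 2`. This is the weighted-undirected
  clustering of the toolbox rather than the binary fraction-of-neighbor-
  pairs definition; the two coincide on binary graphs.
- **Local efficiency**: global efficiency of the subgraph induced by each
  node's neighbors (0 with fewer than 2 neighbors). Both nodal and local
  efficiency are computed because published "efficiency" tables do not
  always distinguish them; hub-region and correlation analyses use nodal
  efficiency, the whole-brain local analysis uses local efficiency.
- **Betweenness**: Brandes' exact accumulation over the shortest-path
  predecessor DAG, endpoints excluded, each unordered pair counted once.
  Equal-length path ties share multiplicities; float length comparisons
  use relative tolerance 1e-12.

Every measure is validated against naive brute-force implementations
(Floyd–Warshall triple loop, exhaustive triple enumeration, exhaustive
shortest-path enumeration) on random graphs of ≤8 nodes, and betweenness
additionally against networkx.

**Measure normalization for reporting**: min–max scaling to [0, 1] per
(scope, measure) family across the cohort, recorded with its parameters.
The map is linear and shared across subjects, so ANOVA F statistics and
correlations are unchanged; raw values are used for the statistics tables
and the scaled table is written alongside for same-scale inspection.

## Hubs

Per group: arithmetic mean of per-subject betweenness per node, ranks 1..n
ascending (n = most central), ties broken by node index for full
determinism. Hubs are the `floor(0.10 n)` top-ranked nodes — exactly 9 for
n = 90. Whether group aggregation should average subject measures or
compute measures on a group-mean network is not settled; averaging subject
measures is the default here (it weights subjects equally and needs no
group-level network construction). The 10% cutoff is itself an operational
convention — there is no principled hub threshold — and is configurable.

## Statistics

Classical pooled-variance (equal-variance) forms throughout; Welch
variants are deliberately not implemented, matching the ANOVA/LSD
framework the reported analyses use.

- One-way ANOVA from raw data or from group (mean, SD, n) — sufficient
  statistics for the one-way model, so summary-based recomputation of
  published tables is exact up to printed rounding. Degrees of freedom
  follow the group sizes actually supplied: 22/12/10 gives (2, 41).
- LSD post-hoc: pairwise t on `MS_within` with the ANOVA's within df, no
  multiplicity adjustment (that is what "least significant difference"
  means).
- Benjamini–Hochberg step-up FDR within each analysis family: the 3 global
  measures; hub-region tests jointly (regions × 3 measures); whole-brain
  local tests per measure (90 regions each). Each family's m is recorded
  in the output tables.
- Pearson correlations between cognitive change scores (post minus pre;
  missing scores flagged, never imputed as zero) and nodal measures in the
  hub regions that differ between groups, pooled and per group; groups
  with fewer than 3 scored subjects are skipped with a warning; FDR within
  the pooled family.

## Synthetic cohort generator

The generator's defaults are the study conditions: 90 nodes; groups of
22 controls, 12 mild TBI (GCS 14–15), 10 moderate-severe TBI (GCS 3–13);
edge density 0.3; mean streamline count 500 per present edge (giving
per-node raw strengths of order 1e4, the magnitude published tables show).

- **Template** ("anatomy"): Erdős–Rényi edge presence at the configured
  density with gamma-distributed counts (shape 2) on present edges,
  resampled until connected. Real templates have geometric and modular
  structure; none of the measures require it, and topology only needs to
  support the measures, so no anatomical template is emulated.
- **Subjects**: negative-binomial counts per present edge around the
  template mean times the group attenuation (variance `μ + φμ²`,
  dispersion φ = 0.5 by default; φ = 0 degenerates to the rounded mean).
  Severity attenuation is multiplicative and diffuse: control 1.0, mTBI
  0.9, msTBI 0.75 — values chosen to reproduce the qualitative
  dose-response only, since no effect sizes for edge attenuation are
  published. Optional targeted damage multiplies edges incident to chosen
  hub nodes by `extra_hub_attenuation` (default 0.5) in selected groups
  (default msTBI only).
- **GCS** is drawn uniformly over each patient group's legal range; age
  and time-since-injury metadata are drawn from normal distributions
  matching the published group summaries.
- **Cognition**: the change score is `slope · z + intercept + noise` for
  controls, where z is the control-group z-score of the target region's
  nodal efficiency on the subject's built network, and
  `group_shift + noise` (no coupling) for TBI subjects. Using the z-score
  makes the control population correlation exactly
  `slope/√(slope² + σ²)` regardless of the generator's efficiency scale;
  the defaults slope = 1.5, σ = 1.5, shift = −3 give a control coupling of
  r ≈ 0.71 and, with the target hub's edges attenuated in TBI groups, a
  pooled correlation of r ≈ 0.5–0.6 — the coupling structure reported for
  this design. Only 8 of 22 controls carry cognition scores by default,
  mirroring the availability of pre-injury scores.

### What the generator does not emulate

Independent per-edge noise averages out over ~1,200 edges, so simulated
between-subject variability in global measures (CV ≈ 2%) is far smaller
than in real cohorts (CV ≈ 25%), and simulated group F statistics are
correspondingly much larger than published ones. There is no anatomical
topology, no lesion geometry, no spatially correlated damage, and no
subject-level random effect. Passing recovery tests therefore show that
the pipeline detects the planted effects under idealized noise — not that
real data would yield the published effect sizes, which depend on
between-subject anatomical variability the generator does not model.
Published subject-level statistics (global F values, observed hub lists,
real-data correlations) are consequently *not* reproduction targets;
only statistics recomputable from printed summary values are.

## Validation experiments and problem sizes

Replicate experiments (package's own choices of size, seeds spawned
independently per replicate):

- dose-response power: 50 cohorts; the FDR-corrected global strength ANOVA
  must reject in ≥80%.
- null calibration: 200 cohorts with all attenuations 1.0; strength ANOVA
  rejection rate at α = 0.05 must lie in [0.01, 0.10].
- hub-disruption recovery: 25 cohorts. Each replicate first generates its
  undamaged cohort to identify the top-ranked control hub, then
  regenerates with that node's edges attenuated ×0.5 in msTBI (control
  matrices are identical across the two passes because attenuation never
  zeroes an expected count, so the draw streams align). Success: the node
  leaves the msTBI hub set and remains a control hub; required in ≥80%.
- cognition-coupling recovery: 20 cohorts; pooled correlation
  significantly positive in ≥80% of replicates, TBI per-group mean r
  within ±0.2 of zero.
- oracle equivalence: 200 random weighted graphs of 3–8 nodes; every
  measure must match its brute-force oracle to 1e-10.

## Known limitations

- The degenerate case of a subject whose network loses all edges to the
  threshold aborts the pipeline with the subject identified, rather than
  dropping the subject.
- Age-adjusted (ANCOVA) group comparisons are not implemented; the model
  specifics for such an adjustment are not fully determined by published
  descriptions.
- The generator cannot express spatially structured damage beyond
  node-targeted attenuation.
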