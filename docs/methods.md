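# Methods

This note documents the models, conventions and numerical choices
behind `strucnet`, in the spirit of a model-documentation page: what is
computed, under which assumptions, and what the synthetic-data tests do
and do not establish.

## Network construction

Inputs are per-subject region-by-region matrices: streamline counts and
mean FA per region pair, on a shared parcellation (default: 34
Desikan-Killiany cortical regions per hemisphere plus 17 subcortical
structures, 85 regions). Directed streamline counts are symmetrized by
averaging the two directions. An edge exists at threshold τ iff
`counts_ij > τ` — the comparison is **strict**, so τ = 0 removes only
zero-count pairs. Surviving edges carry their FA value (or, for
sensitivity analyses, the count, count normalized by mean ROI size, or
count normalized by mean streamline length).

Edge classes partition all region pairs: any pair touching a
subcortical region is *subcortical* (this includes
subcortical-subcortical pairs, a convention this package fixes
explicitly because atlases only name the subcortical-cortical class);
cortico-cortical pairs are *left*, *right* or *interhemispheric*.
Class-mean weights average over **all** pairs of the class, absent
edges counting as zero. This is deliberate: it makes the class mean
sensitive to both edge weight and density, and it is the convention
under which sparse interhemispheric connectivity yields class means far
below the FA of any present edge.

Group-consensus thresholding retains only edges present in every
subject (jointly across both groups by default; a per-group scope is
available). It is applied per grid threshold when comparing
density-sensitive metrics, equalizing network density between groups so
clustering/efficiency differences cannot be driven by edge count alone.

## Graph metrics

All metrics treat networks as weighted and undirected, following the
Brain Connectivity Toolbox conventions:

- **Degree / strength**: count of nonzero connections; sum of incident
  weights.
- **Clustering**: Onnela geometric-mean-of-triangles form on weights
  normalized by the network maximum,
  `C_i = Σ_{jh}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1))`, zero for
  `k_i < 2`. Max-normalization makes `C_i` invariant to global weight
  rescaling — a property the tests assert, and one with a real
  consequence for group comparisons (below).
- **Paths**: edge length is the reciprocal weight `l = 1/w`
  (configurable); distances via Dijkstra; unreachable pairs are
  infinite.
- **Global efficiency**: mean inverse distance over ordered pairs,
  `1/∞ = 0`; lies in [0, 1] for weights in [0, 1].
- **Local efficiency**: published weighted variants differ; the
  convention here (isolated in one function) is the toolbox one: for
  node *u* with neighbors *V*,
  `E_loc(u) = Σ_{j≠h∈V} (w_uj w_uh)^{1/3} / d⅓_jh / (k(k−1))` where
  `d⅓` is the shortest-path distance within the subgraph induced by
  *V* using lengths `(1/w)^{1/3}`. A unit-weight clique scores exactly
  1; for binary graphs it reduces to the efficiency of the
  neighborhood subgraph.
- **Eccentricity** (largest finite distance per node) is provided as a
  secondary metric because regional tables in this literature sometimes
  label local efficiency that way; local efficiency is the primary
  regional integration measure here.

Every metric has a brute-force oracle in the test suite (triple
enumeration for clustering, Floyd-Warshall for distances, literal loop
evaluation for local efficiency) and is checked to `1e-10` on hundreds
of random graphs, plus binary-limit equivalence against networkx.

## Threshold sweep and AUC

There is no principled single streamline threshold, so metrics are
evaluated over a grid and reduced to the trapezoidal area under the
curve; per-subject AUCs are the unit of statistical comparison. The
default grid is integer thresholds 0–20, a logged configuration item —
no analysis or acceptance check depends on a particular grid. Trapezoid
integration is exact for piecewise-linear curves, which anchors the
tests. Bootstrap confidence intervals around group medians (percentile
type, default 10⁴ resamples) are provided for descriptive reporting.

## Statistical battery

The cohort design is individually age-matched pairs (±2 years), so the
primary test is the paired t-test on per-subject AUCs (two-sided
throughout; direction is read off the sign afterwards). Shapiro-Wilk
screens each group's values; comparisons failing the screen at
α = 0.05 are flagged and excluded from significance claims rather than
silently dropped. The Wilcoxon signed-rank test (exact null
distribution for n ≤ 25 without ties, normal approximation with
midranks otherwise) is available as the nonparametric fallback.

Multiplicity: Bonferroni across the 4 edge classes and across the 4
global metrics; Benjamini-Hochberg step-up FDR across regions for the
nodal tables, one family per metric (85 regions). Regions with
zero-variance paired differences are removed from the FDR family with a
logged warning. BH is implemented directly (`q_(i) = min_{j≥i} m·p_(j)/j`,
capped at 1) and cross-checked against an independent step-up and
against statsmodels.

## Expression association

Donor expression tables are z-scored within donor across regions
(sample SD), then averaged region-wise across donors. Each screen cell
fits `metric_r = β·expr_r + β₀` by OLS over the **cortical** regions
only (68 by default) — atlas expression maps are cortical, and
subcortical inclusion is an explicit flag. The regional metric entering
the regression is the group mean of per-subject regional AUCs.
Influence uses Cook's distance with the conventional 4/n cutoff; exact
leverage points (h = 1) are flagged with infinite distance; a
numerically perfect fit has all distances defined as zero. The
sensitivity refit re-estimates on the complement, shrinking the
residual df by the number of exclusions (n in → F df (1, n−2); k
excluded → (1, n−k−2)). The screen's Bonferroni family is
`m = groups × genes × metrics` (2 × 5 × 4 = 40 in the canonical
configuration of one candidate gene plus four comparison genes).

## Synthetic cohorts: what is emulated, and what is not

The generator (`netgen`) plants known effects so every stage can be
tested for calibration and recovery:

| parameter | default | meaning |
|---|---|---|
| `n_pairs` | 7 | age-matched case/control pairs |
| `density` | 0.35 | expected edge density of control networks |
| `class_mean_fa` | 0.18 / 0.33 / 0.30 / 0.06 | control mean FA of present edges per class (subcortical, left, right, interhemispheric) |
| `global_attenuation` | 0.55 | multiplicative case/control ratio on counts and FA |
| `expression_coupling` | 0.15 | slope of extra case-side nodal attenuation in expression |
| `subject_noise_sd` | 0.03 | per-edge FA noise, truncated to (0, 1) |
| `count_scale` | 12 | mean streamline count of present control edges |

Choices worth stating:

- **Topology.** One edge support per cohort: a random spanning tree
  (guaranteeing connectedness and a consensus backbone) plus
  Erdős-Rényi pairs to the target density. Sharing the support across
  subjects makes the zero-noise null cohort exactly pairwise identical
  and keeps consensus thresholding non-degenerate; support variation
  between subjects then arises only through count thresholding.
- **Attenuation acts on counts and FA alike**, so the planted deficit
  is visible in degree and strength as well as in edge weight — as in
  real pathology, where fewer reconstructable streamlines accompany
  lower FA.
- **Expression coupling** multiplies each node's incident edge weights
  by `g_i = clip(1 − coupling · expr_i, floor, 1)` (edges get
  `√(g_i g_j)`), producing a regional metric-expression association
  without dictating its magnitude.
- **Noise is independent across edges and subjects given the class
  means.** Real cohorts have strong between-subject covariance (a
  subject with globally high FA is high everywhere); group means and
  SEs constrain only the marginals, so independence is the minimal
  assumption. Consequence: per-subject class means average over
  hundreds of edges, between-subject variance is tiny, and paired t
  statistics on synthetic cohorts are an order of magnitude larger
  than real data would give. Passing power tests therefore demonstrate
  correctness of the machinery, not realistic effect sizes.
- **Clustering under pure global attenuation.** Because clustering is
  max-normalized, multiplying all case weights by a constant changes it
  only through second-order mechanisms (the unscaled noise floor makes
  case networks relatively noisier, and consensus masks shift). At 85
  regions this depresses case clustering reliably; on toy parcellations
  (~10 nodes) the effect is unstable, which is why the small-fixture
  unit test asserts only the scale-sensitive metrics while the
  study-scale acceptance test asserts all four.
- **Determinism.** The root seed expands via
  `SeedSequence(seed).spawn()` into one substream for cohort structure
  and one per subject; identical inputs give bit-identical cohorts.
  With `subject_noise_sd = 0` the generator is fully deterministic,
  counts included.
- **Ages**: controls uniform on 10–43 years, case = control ± U(−2, 2),
  clipped to 8–45.

Not simulated: diffusion signal, streamline geometry, voxels, motion or
scanner artifacts, between-subject covariance, medication or seizure
covariates.

## Calibration and power checks (problem sizes)

The acceptance suite runs, at study-scale conditions (7 pairs, 85
regions, grid 0–20 step 2):

- 500 null cohorts (attenuation 1, coupling 0): nodal FDR-significant
  fraction stays within the nominal level and global paired-t p-values
  are uniform (KS).
- 200 cohorts with attenuation 0.576 (a left-hemisphere-like
  control→case FA ratio): edge-class and global comparisons each reject
  in ≥95%, never in the case-higher direction.
- 500 regressions with a planted metric-expression slope: unbiased
  estimate, 95% CI coverage within 0.95 ± 0.03; 200 runs of the
  five-gene screen flag only the coupled gene ≥90% of the time.
- 200 random graphs vs brute-force metric oracles; exhaustive 2ⁿ
  enumeration for the signed-rank test (n ≤ 10); 1000 random p-vectors
  for BH.

These sizes were chosen to keep Monte-Carlo error well below the
asserted margins while the whole suite runs in a few minutes on one
CPU.

## Known limitations

- The local-efficiency convention is one of several in circulation;
  results are comparable only across software using the same variant.
- Voxel-level FA averaging, tractography and parcellation are upstream:
  the package trusts its input matrices.
- The expression stage assumes region-level expression tables are
  already mapped to the parcellation; probe selection and
  donor-to-template registration are out of scope.
- With 7 pairs, normality screening at n = 7 has little power; the
  flag is a guard, not a guarantee.
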