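# Methods

This note documents the models and procedures implemented in `graphms`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Graphs and thresholding

A subject's connectome is a symmetric, zero-diagonal, nonnegative
`q x q` matrix of streamline counts (`q = 84` parcels by default,
matching a standard cortical + subcortical parcellation).  The weighted
graph has one edge per strictly positive pair; its density is the
fraction of possible pairs connected.

Binarization is proportional: with threshold `tau` in [0, 1] the budget
is `T = floor((q^2 - q) tau / 2)` and the `T` largest-weight edges are
kept.  Two conventions needed fixing:

* **Rounding.** `(q^2 - q) tau / 2` is generally non-integer (at
  `q = 84`, `tau = 0.35` it is 1220.1); we take the floor, the
  conservative reading of "keep at most a fraction tau".
* **Ties at the cutoff weight** are broken by ascending `(i, j)` node
  index.  This makes the transform deterministic and, because edges are
  totally ordered by `(-weight, i, j)`, the edge set at a smaller `tau`
  is always nested inside the set at a larger `tau`.

Shortest paths are unweighted breadth-first distances; disconnected
pairs carry an explicit `+inf`, never a silent drop.  Triangle counts
use the closed-neighbor-pair definition, `t_i = diag(A^3)_i / 2`.

## The six global metrics

Density is evaluated on the weighted graph (pre-threshold support); the
other five on the binarized graph.

* **Assortativity `r`** is the Pearson correlation of degrees across
  edge endpoints, evaluated with each undirected edge contributing its
  symmetrized endpoint statistics (equivalent to counting both
  orientations).  On degree-regular graphs the variance term vanishes
  and `r` is undefined: we return NaN with a flag rather than a
  convention value.
* **Transitivity** `sum(2 t_i) / sum(k_i (k_i - 1))`, 0 when no node
  has two neighbors.
* **Global efficiency** `E_g = (1/q) sum_i sum_{j != i} d_ij^-1 / (q-1)`;
  infinite distances contribute zero, so `E_g` is always defined.  The
  inner normalization uses `q - 1`, mirroring the path-length formula.
* **Characteristic path length** averages each node's mean distance to
  the nodes it can reach; cohorts analyzed at `tau = 0.35` on dense
  connectomes are essentially always connected, and any exclusion of
  unreachable pairs is flagged.  A graph with no edges yields NaN.
* **Modularity** `Q = sum_u [e_uu - (sum_v e_uv)^2]` with `e_uu` the
  within-module edge fraction and off-diagonal entries split so rows
  sum to the fraction of edge ends per module.  The partition is found
  by exhaustive set-partition enumeration for `q <= 8` (exact, cheap at
  Bell(8) = 4140) and otherwise by seeded multi-level (Louvain)
  optimization with 10 restarts, keeping the best `Q`; the trivial
  one-module partition (`Q = 0`) is always a candidate, so the reported
  value is never negative.  Community detection is delegated to
  networkx; `Q` itself is always evaluated by this package's formula.

Undefined values propagate as NaN plus a flag on the per-subject metric
vector; imputation is deferred to the classifier (training-fold means),
so upstream tables remain faithful.

## Parameter selection

Two acquisition/processing knobs are chosen from data rather than by
convention:

* **Streamline budget `f`.** Matrices are resampled by distributing `f`
  streamlines multinomially over pairs in proportion to a base weight
  pattern; the mean weighted density rises with `f` and saturates at
  the support density once every positive pair is hit.  `f` should sit
  in the saturated regime; the preset default is 500,000.
* **Threshold `tau`.** For each `tau` on the grid 0.05, 0.10, ..., 1.00
  the across-subject CV (sample SD over |mean|, ddof = 1) of the five
  binarized-graph metrics is computed on the control cohort.  Any `tau`
  strictly above the cohort's mean weighted density is rejected — the
  edge budget then exceeds the available edges and the transform
  degenerates to the support.  Among admissible thresholds the smallest
  one whose metric-averaged CV lies within 10% (relative) of the
  admissible minimum is selected.  The 10% stability tolerance is this
  package's choice; the underlying criteria (low and stable
  inter-subject variability) admit any reasonable tolerance, and the
  selection is insensitive to it on plateau-shaped curves.

The spherical-harmonic helper returns the largest even order `h` with
`(h + 1)(h + 2)/2 < d` coefficients for `d` gradient directions
(`h = 4` at `d = 24`), useful when planning the upstream acquisition.

## Group statistics

All group pairs are compared per metric with a two-sided
Wilcoxon-Mann-Whitney test: exact enumeration when the pooled sample
has at most 12 observations and no ties, otherwise the normal
approximation with tie and continuity corrections (via scipy).  No
multiplicity correction is applied by default, matching the per-test 5%
convention of small clinical group studies; Holm adjustment is
available behind a flag.

## Classification

Features are the six metrics (or any subset).  The classifier is a
soft-margin SVM with RBF kernel; `C` and `gamma` are tuned over powers
of two with exponent step 2 spanning `[2^-5, 2^15]` and `[2^-15, 2^3]`
— the conventional coarse grid for this kernel.  Model selection uses
stratified K-fold cross-validation (K = 10, reduced with a warning when
the smallest class is smaller) scored by support-weighted F-measure;
standardization and mean imputation are fitted inside each training
fold, so no test statistics leak into the transform.  Multi-class tasks
use the one-vs-one scheme of the underlying solver with majority vote.

Reports contain per-class confusion counts, per-class P/R/F (each class
as "positive" in turn), and support-weighted aggregates; the weighted
average is what single-triple-per-task tables report, and the averaging
convention is recorded on every report.  The fitted binary model is
exposed in its dual representation (support vectors, multipliers
`alpha in [0, C]`, bias); tests verify the dual box and equality
constraints to 1e-6 on every trained model, so the solver contract, not
a particular algorithm, is normative.

## Synthetic cohorts

The generator emulates streamline-count tractography output, not
imaging: each subject has a latent intensity over node pairs and a
single multinomial draw of `f` streamlines (counts sum to `f` exactly).
The intensity composes four effects: a block structure (4 interleaved
modules; within-module pairs `weight_concentration` times stronger), a
Bernoulli support mask rescaled to the profile's target density, node
propensities entering as
`exp(heterogeneity (u_i + u_j) + hub_tilt u_i u_j)`, and an optional
ring-locality penalty.  Subject-level variability comes from log-normal
pair jitter (sigma 0.35) and a density jitter (SD 0.04).

The group presets plant the clinically observed contrast directions on
the latent structure — metrics are emergent, never set directly:

| group | support density | concentration | heterogeneity | hub tilt |
|-------|-----------------|---------------|---------------|----------|
| HC    | 0.58            | 1.50          | 0.20          | 0.00     |
| CIS   | 0.58            | 1.18          | 0.36          | 0.00     |
| RR    | 0.56            | 1.95          | 0.30          | 0.00     |
| SP    | 0.51            | 1.65          | 0.30          | 0.45     |
| PP    | 0.53            | 1.50          | 0.32          | 0.70     |

Support densities follow the observed group ordering of weighted
densities; concentration orders modularity (CIS < HC < SP < RR); degree
heterogeneity creates disassortative hubs (controls sit near r = -0.1)
and, by isolating weak nodes after thresholding, lengthens paths and
lowers efficiency in the patient groups; a positive hub tilt makes
similar-propensity nodes prefer each other, pushing assortativity
upward in the progressive groups.  Group sizes default to
HC 24 / CIS 12 / RR 24 / SP 24 / PP 17 with `q = 84` and
`f = 500,000`.

What the synthetic cohorts do **not** capture: anatomical geometry and
tract anatomy, lesion-induced local rerouting, scanner and tractography
biases, realistic between-metric correlations, and the much larger
group overlap of real cohorts.  Planted contrasts are strong enough for
sign recovery at these sample sizes, which makes classification nearly
perfect on default presets — a statement about the planted effect size,
not about attainable clinical accuracy.  Passing tests therefore
establish correctness and internal consistency of the pipeline, not
clinical performance.

## Numerical and reproducibility choices

* All randomness flows from a single master seed through named
  `SeedSequence` child streams (simulation, folds, solver); reruns are
  bit-identical, and derived seeds stay below 2^31.
* Assortativity's undefined test uses an absolute tolerance of 1e-12 on
  the variance term; with integer degrees the smallest nonzero value is
  far larger.
* CV curves exclude NaN metric values from both moments and log the
  exclusion count; a CV cell is NaN when fewer than two defined values
  remain or the mean is zero.
* Test-suite and acceptance-script problem sizes (cohorts of 12-24
  subjects per group, 20-50 simulated cohorts, Louvain restarts 3-5
  in scans) are chosen to keep runs fast while leaving the checked
  contrasts far from marginal; the library defaults are the full study
  conditions.

## Known limitations

* Louvain is a heuristic for `q > 8`: the reported `Q` is the best of
  the restarts, a lower bound on the optimum.  Exact enumeration
  guards correctness only at small `q`.
* The weighted density band (~0.5-0.6) keeps binarized graphs at
  `tau = 0.35` connected and diameter-2 to -3; path-based metrics vary
  in a narrow range there, as they do in the clinical literature.
* The grid-search F-measure reported for a task is mildly optimistic
  (model selection and evaluation share folds); null cohorts score
  about 0.55-0.65 rather than exactly 0.5 for this reason.
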