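# Methods

`rsnet` reimplements, as a tested library, a complete graph-theoretical
group analysis of resting-state functional MRI for a two-group rodent
design (unilaterally lesioned vs sham animals): BOLD time-series
cleanup, Pearson connectomes, sparsity-thresholded binary graphs,
topology metrics with random-network normalization, and three layers of
group inference. Because no animal data ship with the package, a
first-class synthetic-cohort generator provides every stage with a
planted, recoverable ground truth.

## Signal model and preprocessing

Each subject is a T x R matrix of BOLD-like samples (default T = 900
volumes at TR = 1 s, R = 150 ROIs, 75 per hemisphere). The cleanup chain
is fixed in order:

1. **Initial-volume drop** (default 50): discards pre-steady-state
   magnetization.
2. **Nuisance regression**: each ROI column is replaced by its OLS
   residual against six rigid-body motion parameters plus the mean CSF
   signal, with an intercept always appended. The residual is computed
   through a QR projection, so residuals are orthogonal to every
   regressor to machine precision (|r| < 1e-10 is asserted in tests).
   The intercept is included even though the nuisance set nominally
   lists only motion + CSF: residualizing without it leaves per-ROI mean
   offsets that distort Pearson correlations.
3. **Band-pass filtering** 0.01-0.1 Hz: a Butterworth design (order 2
   per pass, configurable) applied forward-backward (`sosfiltfilt`), so
   the effective order is 4 and phase is preserved. Columns are
   de-meaned first and the mean is not restored; DC lies outside the
   pass band by construction. The filter family/order is a design choice
   of this package — standard resting-state practice — since only the
   band is inherent to the analysis.
4. **Temporal masking** to 300 artifact-free volumes: if the leading 300
   volumes are valid they are taken as a continuous block, otherwise
   valid volumes are concatenated in temporal order. The downstream
   correlation treats the possibly non-continuous result as stationary.
   Filtering runs on the continuous series *before* masking; masking
   afterwards only selects rows (asserted as a property test). A helper
   flags volumes by frame-to-frame motion (defaults 2.5 mm / 2.5 deg)
   for data without explicit validity flags.

ROI extraction from voxel data (`extract_roi_means`, with a NIfTI
loader) is a plain within-label arithmetic mean per volume.

## Graphs

Connectivity is the sample Pearson correlation between ROI columns.
A binary undirected graph at sparsity SP keeps the
K = round(SP * R(R-1)/2) strongest off-diagonal entries (round half away
from zero; K is asserted exact in tests). Edges are ranked by **signed**
correlation by default — the strongest positive correlations win —
with an `absolute` option; nothing in the analysis depends on the choice
except which correlations compete. Ties at the K-th rank break
lexicographically by node-index pair, which makes edge sets
deterministic and nested across the default grid
SP = 0.05, 0.10, ..., 0.50.

## Topology metrics

For a graph with adjacency A (R nodes, m edges):

- degree k_i = row sum; clustering c_i = 2 t_i / (k_i (k_i - 1)) with
  t_i triangles through i and c_i = 0 for k_i < 2; the network mean C
  is the average over all R nodes.
- distances are BFS hop counts; nodal efficiency
  e_i = mean_{j != i} 1/d(i,j) with 1/inf = 0, global efficiency
  E_glob = mean_i e_i; the characteristic path length L averages finite
  distances over reachable ordered pairs only. These conventions keep
  every metric defined on the disconnected graphs that SP = 0.05
  inevitably produces; an edgeless graph is an error, not NaN.
- the neighbourhood-subgraph "local efficiency" variant exists behind
  `nodal_efficiency="local"` but the default nodal efficiency is the
  whole-network quantity above, matching the methods definition being
  replicated (its abstract-level naming is ambiguous).
- modularity uses greedy agglomerative (CNM) maximization of Newman's
  Q = sum_c (e_cc - a_c^2), via networkx; the partition at maximal Q is
  returned and Q is re-derived from that partition. Module count
  includes singleton modules from isolated nodes. On graphs of <= 8
  nodes the greedy Q is checked against exhaustive partition
  enumeration.
- the small-world index is S = (C/C_rand) / (L/L_rand) where C_rand and
  L_rand are means over n_rand (default 100) degree-preserving
  randomizations (Maslov-Sneppen double-edge swap, 10 accepted swaps
  per edge, swap-free graphs such as K3 returned unchanged). The swap
  loop is seeded and bit-reproducible; the degree multiset is preserved
  in every draw.
- threshold-independent nodal summaries integrate each nodal measure
  over the sparsity grid with the composite trapezoid rule (exact for
  the piecewise-linear curve the grid defines); units are
  measure x sparsity, so a [0,1]-bounded measure has AUC in [0, 0.45]
  on the default grid.

## Group inference

- **Global layer**: per metric, a two-factor mixed ANOVA (group between
  subjects, sparsity within; pingouin), no sphericity correction by
  default (Greenhouse-Geisser epsilon is reported by the backend). Post
  hoc, a pooled two-sample t-test at each sparsity with Bonferroni
  adjustment alpha / |grid|. With a single grid level the design
  degenerates and F = t^2 is computed directly (checked numerically).
- **Nodal layer**: two-sample t-tests (pooled variance by default,
  Welch optional) on per-node AUCs, Benjamini-Hochberg q-values across
  nodes, direction coded I/D for lesion increase/decrease relative to
  sham; both uncorrected (p < 0.05) and FDR (q < 0.05) sets are
  reported.
- **Connection layer (NBS)**: edge-wise pooled t-statistics on the raw,
  unthresholded correlations (Fisher z optional, off by default);
  edges beyond a primary threshold (default t = 3.1) in the requested
  one-sided tail form a suprathreshold graph; connected components are
  scored by extent (edge count — the quantity reported as "abnormal
  connections"); n_perm (default 10000) random relabelings of subjects
  build the null distribution of the maximal extent; component
  p = (b + 1)/(n_perm + 1) (add-one permutation estimator, so p is
  never 0). Both one-sided contrasts are run by the pipeline because a
  decrease-only report implies the increase contrast was also
  evaluated. A warning fires when the relabeling space is smaller than
  n_perm. FWER validity under the null and recovery of a planted
  component are both exercised in the acceptance suite.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not scanner physics:

- **Covariance**: a block correlation matrix with n_modules (default 6)
  bilaterally mirrored modules — mirror nodes share a module — with
  within_corr = 0.7 inside modules and between_corr = 0.25 elsewhere.
  These defaults describe band-limited, anesthetized-rodent-like data
  with graded correlations, and were chosen once so that the default
  planted effect is a strong, recoverable contrast at the replica's
  statistical thresholds (13 vs 11 subjects, primary t = 3.1).
- **Signal**: multivariate normal draws are low-pass filtered at
  0.12 Hz (BOLD fluctuations are slow); a common linear filter
  preserves the correlation structure exactly and makes the analysis
  band nearly transparent to signal. One global scalar restores
  unit-scale variance.
- **Planted effect**: the lesion group's "thalamic" increase multiplies
  the within-block off-diagonal correlations by increase_factor
  (>= 1), followed by a Cholesky check with shrinkage-toward-identity
  as a last-resort fallback. The "cortical" reduction is applied as a
  node-level coupling loss: block nodes' rows/columns are scaled by
  sqrt(reduction_factor), so within-block correlations shrink by
  exactly the requested factor, block-to-outside correlations by its
  square root, and the matrix stays positive definite by congruence
  (the variance freed returns to the diagonal as node-private noise).
  A naive within-block-only reduction is structurally non-PD whenever
  the block is a strict subset of a module, and rescuing it by
  shrinkage would silently turn the local effect into a global one;
  the node-scaling construction is also the pattern an actual loss of
  signal coupling produces. Under `null_flag` both groups share one
  generating distribution.
- **Artifacts**: slow sinusoidal drift below 0.01 Hz per ROI
  (amplitude 0.5 SD); a low-pass-noise CSF signal mixed into every ROI
  (coefficient 0.3) so nuisance regression has a measurable effect; six
  smooth random-walk motion traces; ceil(spike_fraction * T) spike
  volumes (default 2%) placed uniformly among volumes 51..T, flagged
  invalid and corrupted with 6-10 SD offsets drawn independently per
  ROI. Independent-per-ROI offsets are deliberate: a volume-wide common
  offset would smear through the band-pass (which precedes masking)
  and act as a shared signal inflating every correlation.

What the generator does **not** model: haemodynamic response shape,
spatial autocorrelation and anatomy, physiological (cardiac or
respiratory) cycles, scanner drift nonstationarity, or
hemisphere-asymmetric baseline covariance. Passing tests therefore
demonstrate correctness of the analysis pipeline and the calibration of
its inference under the stated statistical model — not robustness to
every artifact of real rsfMRI.

## Reproducibility and numerics

One master seed drives everything: stage seeds are derived by hashing
`seed:stage`, per-subject and per-sparsity streams are spawned through
`numpy` SeedSequence, and rerunning a pipeline config reproduces
byte-identical artifacts (sha256 checksums in the run manifest, asserted
in tests). Ties in thresholding and greedy merges are broken
deterministically. Degenerate inputs error early with the offending
subject or ROI named: constant columns at correlation, rank-deficient
nuisance designs, fewer valid volumes than the mask target, edgeless
graphs at L/Q, zero-triangle reference ensembles at S.

## Problem sizes used by the test and acceptance suites

The shipped suites keep the paper-replica defaults where they matter
and scale elsewhere: metric oracles run on 100 random graphs (n <= 30);
small-world discrimination uses n = 100 with 20 references; the
planted-effect recovery test runs the full 13 vs 11, 150-node,
900-volume design with 1000-2000 NBS permutations; NBS FWER validity
uses 200 null cohorts (10 vs 10, 60 nodes, 450 volumes) at 500
permutations; null calibration of the ANOVA and nodal t-tests uses 500
simulated metric tables. The full-default pipeline (`n_rand = 100`,
`n_perm = 10000`, 150 nodes) is the intended replica run and takes
correspondingly longer; all sizes are plain config parameters.

## Known limitations

- The mixed ANOVA relies on the pingouin backend's sums-of-squares
  decomposition (validated against a hand-computed balanced example);
  heavily unbalanced or missing-cell designs are rejected rather than
  approximated.
- NBS component extents use edge counts only; cluster-mass and TFCE
  variants are out of scope.
- Weighted, directed, and dynamic (sliding-window) connectivity are out
  of scope; the analysis assumes stationary networks.
- The generator's effect magnitudes are free parameters of the study
  design; conclusions about statistical power transfer to real data
  only insofar as real effect sizes resemble the planted ones.
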