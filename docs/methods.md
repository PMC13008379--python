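# Methods

This note documents the models, numerical choices, and validation designs
behind scnkit, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structural covariance model

A structural covariance network over regions *1..p* and a subject group is
the matrix of Pearson correlations of residualized regional volumes across
the group's subjects. Self-edges are undefined (stored as 0 and excluded by
the edge mask). Bipartite networks (thalamocortical, thalamosubcortical)
keep only cross-set edges, so a 50 × 68 network has exactly 3,400 unique
edges and a node's strength is the row sum of the cross block.

Assumptions: volumes are approximately multivariate normal after
residualization; subjects are exchangeable within group (the permutation
null depends on this); correlations, not covariances, carry the signal, so
region scale is irrelevant after standardization.

## Data preparation

**Outlier screening.** A subject is removed when any region volume deviates
from that region's sample mean by more than `z_threshold` sample SDs
(default 2.698, the Tukey 1.5 × IQR point of a normal distribution).
Statistics are computed once on the full pooled sample — a single pass, not
iterated — which makes the rule idempotent given the frozen statistics.
Screening is per network: each analysis's region set gets its own pass, so
a subject can fail the thalamocortical screen but survive the intrathalamic
one. Pooled (rather than per-group) means are used; with balanced groups and
modest effect sizes the difference is negligible, and pooling avoids making
the screening rule depend on the diagnosis.

**Site harmonization.** `ComBatHarmonizer` implements parametric
empirical-Bayes ComBat: region-wise location/scale batch adjustment where
per-site means shrink toward a normal prior and per-site variances toward an
inverse-gamma prior, both estimated across regions. The covariate design
preserved during harmonization is a polynomial age basis (degree 2 by
default, a deliberate simplification of spline-based ComBat variants) plus
linear sex and ICV terms. A single site is returned unchanged — there is no
batch effect to estimate, and the EB priors are undefined for one batch.
Harmonization estimates batch effects from the data it adjusts, so the
entry point is `fit_transform`; there is no out-of-sample `transform`.

**Residualization.** Per region, OLS on [intercept, age, age², sex, ICV]
over all subjects pooled; residuals are the SCN input. Pooled fitting keeps
between-group covariance differences intact (a per-group mode exists for
sensitivity analyses). The design matrix is column-scaled before a
condition-number check (default bound 1e10) so that ICV's units do not
masquerade as collinearity.

**Severity.** Instrument scores are min-max normalized to [0, 1] so
different instruments are comparable; out-of-range raw scores are an error
rather than silently clipped.

## Thresholding and wiring cost

Thresholded weighted graphs retain edges with weight strictly above *t*
(strict inequality handles *t* = 0 sensibly when negative correlations are
present); the unthresholded graph is a distinct object that keeps signed
weights, so negative correlations contribute their sign to strength sums
rather than being silently dropped at 0. The sweep grid starts at 0 with a
constant step of 0.025. The minimum wiring cost bound is the largest grid
threshold at which binary reachability still connects every node — for
bipartite networks, over both node sets jointly, since a disconnected
cortical node disqualifies the threshold too. A two-group sweep ends at the
smaller of the two groups' bounds, so both groups stay connected over the
whole grid.

## Permutation inference

The test statistic is always a case-minus-control difference of a network
measure. Diagnostic labels are shuffled with group sizes preserved, and the
networks are rebuilt from the residual table under each relabeling — the
exchangeable unit is the subject, not the edge weight. Two-sided p-values
compare magnitudes, with the add-one Monte-Carlo estimator
p = (b + 1)/(m + 1), which can never return 0. Vector-valued statistics
(per-node, per-edge, per-threshold) share one set of labelings, and BH-FDR
is applied within each stated comparison family. Reference permutation
counts are 5,000 for graph/node measures and 100,000 for edge families;
both are configuration values, and the validation experiments use smaller
counts (200–500) sized to the precision those experiments need.

## IDSCN (template network perturbation)

For case subject *k*: build the control network SCN_n over the *n*
controls, rebuild over the *n* controls plus subject *k* (SCN_{n+1}), and
take IDSCN_k = SCN_{n+1} − SCN_n. The per-edge standardization is

    Z = IDSCN_k / ((1 − SCN_{n+1}²) / (n − 1))        ("printed" variant)

with an alternative dividing by (1 − r²)/√(n − 1) ("sqrt" variant)
selectable via `z_variant`, because published descriptions of the
denominator are typographically inconsistent about the square root. Neither
variant is exactly unit-normal under the null for one added subject, so
`null_calibration` holds out control subjects and reports the empirical
null SD of both: the printed form scales like (n−1)·delta and lands near SD
1 at n in the hundreds, while the sqrt form is strongly conservative there.
Edges where |SCN_{n+1}| reaches 1 get Z = NaN and are excluded from
calling. Altered edges are called at BH-FDR q = 0.05 across the network's
edges within each subject; severity associations use the Z matrix (the
standardized perturbation) by default, with raw deltas available.

## Clustering

Nuclei are clustered by their SC_diff profile — the row of the
case-minus-control edge matrix restricted to the relevant column set, with
the pair's self-entries excluded pairwise. The default distance is
correlation distance 1 − r (profile *shape*, not magnitude; Euclidean
available by option). Trees are unweighted average linkage (UPGMA) via
SciPy; merge ties follow SciPy's deterministic ordering, and heights are
invariant to leaf order. The cluster count minimizes the
Kelley–Gardner–Sutcliffe penalty with α = 1: mean within-cluster spread per
cut (clusters of ≥ 2 members only), linearly rescaled across cuts onto
[1, L − 1], plus the cluster count; ties take the smallest k, and a
degenerate rescaling (all spreads equal) falls back to k = 2 with a
warning. Clusterings are compared by the Pearson correlation of their
cophenetic distance matrices, and the tanglegram is replaced by a
machine-readable pairing table (first-merge partner agreement per leaf plus
flat memberships at the selected cuts).

## Synthetic cohort generator

The generator emulates the data-generating situation of a pooled multisite
case–control volumetric study:

- **Group covariance.** Controls draw from a base correlation matrix
  (block-structured or equicorrelated; unit diagonal); cases from the same
  matrix with chosen edge shifts. Any non-PSD result of an implant is
  repaired by eigenvalue clipping at 0 followed by re-normalization to unit
  diagonal, and the maximum entry displacement is reported so the implanted
  truth stays auditable.
- **Site effects** are region-wise affine maps (additive shift,
  multiplicative scale) applied after covariance sampling — exactly the
  batch model ComBat assumes.
- **Covariate effects** add linear age (centered at 40 y), quadratic age,
  sex offset and ICV terms per region. Ages are uniform on 18–65 y, ICV
  normal with mean 1.45 × 10⁶ mm³, SD 1.4 × 10⁵ mm³; volumes default to
  mean 1,000 mm³, SD 100 mm³ (region-scale choices are irrelevant to
  correlation-based analyses and exist only to make the tables look like
  volumes).
- **Severity links.** A case subject's latent perturbation score for a
  designated edge is the influence-function value of that edge's
  correlation for one added subject, z_i z_j − r(z_i² + z_j²)/2, evaluated
  at the true control moments. The symptom score is a clamped linear map of
  link·latent + noise, so choosing link = ρ and noise SD = √(1 − ρ²)
  implants a severity–perturbation correlation of ρ. This construction is
  what makes the implanted correlation recoverable through the IDSCN Z: the
  add-one change of an edge correlation *is* (to first order in 1/n) the
  influence-function value, so Z tracks the latent almost deterministically.
  A mean-covariance shift alone could not implant a recoverable ρ = 0.3 —
  a single subject's cross-product has SD ≈ 1, which attenuates any
  feasible mean shift to a far smaller correlation.
- All randomness flows from one spec seed through spawned generator
  streams, giving bitwise reproducibility and stable per-stage streams.

What the generator does **not** emulate: non-Gaussian volume distributions,
missing data, site-by-covariate interactions, spatially structured
segmentation error, or diagnosis-dependent covariate distributions. Passing
tests therefore demonstrate correct recovery under the stated model, not
robustness to those real-data features.

## Validation experiment designs

The `validation` module fixes the study conditions used by the test suite
and the acceptance script:

- **Calibration**: 200 null cohorts of 50 + 50 subjects over 10
  equicorrelated regions (r = 0.3), 500 permutations; the graph-strength
  rejection rate at α = 0.05 should sit in the Monte-Carlo band around the
  nominal level.
- **Power**: 100 cohorts of 500 + 500 subjects over 50 regions with every
  within-network correlation raised 0.3 → 0.4 in cases; 200 permutations.
- **Edge recovery**: 100 cohorts of 500 + 500 subjects, 10 regions at
  r = 0.6, one edge raised to 0.8. The size and base correlation follow a
  power analysis: a sample correlation has SE (1 − r²)/√n, so at n = 500
  the null SC_diff SD is ≈ 0.040 at r = 0.6 and the expected maximum over
  45 correlated null edges (≈ 2.5 SD) stays well below the implanted 0.2,
  giving a per-replicate top-edge probability near 1. On a 1,225-edge
  network with weak base correlation the null maximum (≈ 0.21) would
  swamp a 0.2 implant at this sample size — single-edge localization at
  n = 500 is only informative on a network small enough for the implant to
  clear the null maximum, which is why this experiment uses 10 regions.
- **Severity recovery**: 400 controls + 400 cases over 50 regions
  (1,225 edges), one severity-linked edge at ρ = 0.3; the scan must rank
  that edge first by |severity–Z correlation| and recover ρ within
  sampling error (SE ≈ 1/√400 ≈ 0.05).
- **IDSCN null scaling**: held-out control subjects against control groups
  of 50/200/800; the mean maximum |delta| must fall monotonically (the
  add-one perturbation is O(1/n)), and the calibration harness reports both
  Z variants' null SDs.
- **Cluster recovery**: 60 leaves in 6 profile groups (40-column
  prototypes, noise SD 0.05), 50 replicates; KGS must select k = 6 with
  adjusted Rand index 1.

## Known limitations

- ComBat here is the location/scale parametric-EB form with a polynomial
  covariate basis; spline (GAM) covariate bases and non-parametric priors
  are out of scope.
- The printed IDSCN Z is used as published, not as a calibrated deviate;
  altered-edge counts are therefore comparable within a fixed n but not
  across control groups of different sizes.
- Edge-level permutation families at the reference 100,000 permutations are
  computationally heavy and disabled by default in the pipeline config
  (`n_perm_edge: 0`).
- The pipeline ingests volume tables only; segmentation and image QC are
  upstream concerns.
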