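# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical conventions, and the validation experiments implemented in
`covlink`, together with the reasoning behind the choices that were genuinely
open.

## Voxelwise GLM and cluster-extent correction

Each voxel is modelled by ordinary least squares,
`v = Xβ + ε`, with design `[1, contrast, nuisance...]`. The group contrast is
a two-level indicator; nuisance covariates default to age (sex optional). The
statistic is `t = β̂_c / se(β̂_c)` with `df = n − rank(X)` and a two-sided p
from the t distribution. Voxels constant across subjects are reported as
t = 0 rather than 0/0.

Cluster correction is simulation-based. Null maps are white Gaussian noise
smoothed at the analysis FWHM (`FWHM = 2√(2 ln 2)·σ`; σ = 3 mm ⇒ 7 mm) and
rescaled to unit variance using the exact sum of squared kernel weights of
the truncated separable kernel, measured from its impulse response. Interior
voxels therefore have variance one; voxels near the boundary run slightly hot
under the reflecting boundary, which is immaterial for the per-voxel
probability threshold (thresholding is scale-free at the stated p) and is
absorbed by the empirical calibration check. Null maps are thresholded at the
two-sided cluster-forming p as |z| > z_crit; the analysed t-map is
thresholded at the same p via its own t distribution, so the per-voxel
exceedance probabilities match exactly even though the null fields are
Gaussian rather than t. Positive and negative exceedances are clustered
separately (26-neighbourhood, within the mask) because effects in either
direction are of interest.

**Threshold convention.** From the null distribution of per-iteration maximum
cluster sizes, the returned threshold is the smallest `t` with
`P(max > t) ≤ α`; clusters are significant when their size *strictly
exceeds* `t`. This makes the degenerate cases exact (one iteration returns
that iteration's max; α → 1 returns 0 so everything passes) and empirically
controls FWE (see Validation).

## Link-level interaction networks

Volumes are downsampled by an integer factor: each node is the mean of the
in-mask voxels of a factor³ block, and blocks with under 50% mask coverage
are dropped so edge nodes are not dominated by background. For every ordered
node pair (i, j) the moderated regression
`v_j ~ 1 + v_i + x + v_i·x [+ nuisance]` is fitted; the link statistic is the
t of the product term. The fit is exactly the per-pair OLS (verified against
statsmodels to 1e-10) but computed for all pairs at once with batched normal
equations.

Open choices, and how they were fixed:

- **Symmetrization.** The regression is directional but the network is not;
  the link t is the average of t(i→j) and t(j→i). A deterministic symmetric
  rule is required for reproducibility; averaging is the least-informative
  choice. The averaged statistic is not exactly t-distributed; this does not
  affect error control because the null distribution is built from the same
  symmetrized statistic.
- **Link clusters.** Suprathreshold links (a,b) and (c,d) are cluster-mates
  iff their endpoints pair up as contiguous groups — (a~c and b~d) or
  (a~d and b~c) with ~ meaning identical or 26-adjacent at node resolution.
  Cluster size is the link count. Components are found on the link-adjacency
  graph.
- **Null networks.** Each random network regenerates a full cohort of
  smoothed-noise subject volumes (same grid, smoothness, n, and moderator
  values as the analysis) and runs the identical downsample + fit + cluster
  path. Regenerating rather than permuting real data matches the intent of
  "random networks with the same smoothing properties" and keeps the null
  exchangeable with the analysed statistic.
- **Weighted degree.** Degree(v) = Σ|t| over surviving links incident to v.
  |t| weights preserve the strength information while remaining sign-free;
  binary weights are a trivial special case the user can emulate.

## Synthetic data

The generator produces the study conditions the pipeline is validated under:

- **Cohort**: 16 "senior" + 15 "junior" subjects; ages N(40.5, 7.8²) and
  N(26.5, 4.3²) years, truncated at 18; 2 and 1 women respectively.
  Experience is uniform within group on ranges straddling the 3-year
  seniority cut — seniors U(3, 15), juniors U(0.25, 3) — because groups are
  defined by that cut while the within-group distribution is not known; a
  uniform straddle is the least-committal choice.
- **Volumes**: a smooth baseline (spherical gray-matter-density bump, or a
  uniform cube for calibration grids), a per-subject multiplicative global
  volume factor `1 + u`, `u ~ N(0, 0.1²)`, and smooth Gaussian noise
  (σ = 3 mm at 2 mm voxels) scaled to `noise_sd = 0.05` volume units per
  voxel. The subject factor is essential, not cosmetic: regional volumes
  co-vary across subjects *because* individuals differ in overall gray
  matter, and without that variation structural covariance (and any coupling
  × moderator interaction) is unidentifiable.
- **Planted group effects** add `d · noise_sd` (Cohen's d at the voxel level)
  to one group inside a chosen voxel set.
- **Planted interactions** rewrite target voxels as
  `α + β·s + γ·x̃·s + ε`, where `s` is the subject's mean over the source
  voxels and x̃ the standardized moderator; source voxels are untouched.
  Standardizing x̃ keeps γ comparable across moderators and does not affect
  the interaction t (the design span is invariant to affine changes of x).
- **Expression bundles** mimic the donor-microarray layout: latent gene ×
  region profiles (log-intensity-like, baseline 7, SD 1), where target genes
  use `r·z + √(1−r²)·e` against the standardized degree vector z, so their
  expected spatial correlation is the requested `target_r`; background genes
  are independent spatial noise. Probe values add per-probe offsets
  (SD 0.3) and measurement noise (SD 0.2); samples sit at random voxels of
  their region, 1–3 per region per donor, 6 donors.
- **Toy atlas**: mask voxels in scan order are split into near-equal
  contiguous runs per region, with the category ledger (68 cortical, 16
  subcortical, 2 cerebellar, 3 brainstem = 89 regions by default). The
  regions are slabs, not anatomical shapes — sufficient for exercising
  coordinate lookup, aggregation and regionalization, but nothing about the
  test results speaks to anatomically realistic region geometry.

What the generator does *not* emulate: raw T1 acquisition, registration,
segmentation or modulation (the pipeline consumes already-preprocessed maps);
spatial autocorrelation in gene expression beyond region structure; donor-
specific normalization artefacts; left–right symmetry.

## Transcriptomics stage conventions

Aggregation is mean-over-probes, then median-over-samples within region per
donor, then median-over-donors; the output is invariant to sample and donor
ordering. Samples on background voxels are dropped (with a logged count);
coordinates outside the grid are an error. Regions missing expression are
dropped pairwise per gene rather than imputed. Degree regionalization is the
mean node degree per region (nodes located by their block centres); regions
containing no node are missing. The selection rule is one-sided:
`r > mean(r) + 2·sd(r)` over genes with defined r, sample SD (ddof = 1), raw
r without Fisher transform — the most literal reading of an upper-tail 2-SD
cut. No spatial-autocorrelation-preserving null is applied to the similarity
values; with few regions the null spread of r is wide, which the validation
quantifies.

## Gene sets and interactome

Overrepresentation uses the exact binomial upper tail (no normal
approximation; selected lists are small) with BH FDR across sets; Bonferroni
is available since both corrections are conventional in annotation tools.
Closeness centrality is computed per connected component,
`(n_c − 1)/Σ dist`, hop distances by default and inverse-weight distances for
weighted graphs (stronger interaction ⇒ shorter edge); isolated nodes get 0.
Rankings are invariant to uniform weight rescaling.

## Validation experiments and problem sizes

All experiments live in `covlink.experiments` and are the basis of both the
acceptance tests and `scripts/acceptance.py`.

- **Voxel FWE calibration**: 100 null cohorts (31 subjects, 10³ uniform-mask
  grid, 2 mm voxels), each corrected with its own 200-iteration Monte Carlo
  threshold at α = 0.05; the observed family-wise error should sit within
  the binomial band [0.01, 0.11].
- **Link FWE calibration**: 100 null cohorts on a 12³ grid downsampled to a
  6³ node grid, each corrected with 200 random networks at link p < 0.001,
  α = 0.05; same band.
- **Interaction recovery**: γ = 0.8 planted between two 2×2×2-node blocks,
  n = 31, low-noise regime (volume noise 0.02, interaction residual 0.01 —
  detection should be limited by the correction, not by measurement error),
  100 seeds, 100 null networks per seed; success requires a surviving link
  cluster touching both planted blocks.
- **Gene recovery**: 20 bundles of 200 genes with 10 targets at
  target_r = 0.6 over the 89-region default atlas; sensitivity and false
  positives of the 2-SD selection.
- **Oracle agreement**: voxel and link t vs per-fit normal-equation refits,
  Pearson r vs the explicit formula, binomial tails vs direct summation, BH
  q vs the step-up recursion, link-cluster partitions vs brute-force
  union-find, closeness vs Floyd–Warshall — all on randomized small
  instances.

These desk-scale sizes were chosen so the full validation runs in minutes on
one CPU while leaving each experiment enough replicates for its binomial
bands to be meaningful. The production defaults in the configs (50,000
cluster iterations, 10,000 random networks) are the conventional
full-scale settings and remain the defaults for real analyses.

## Known limitations

- The symmetrized link statistic is compared against thresholds derived from
  its own null distribution; its marginal distribution is not exactly
  Student t, so the per-link p-values are nominal descriptors rather than
  exact tail probabilities.
- Cluster-forming thresholds use Gaussian null fields against t-statistic
  maps with matched exceedance probability; at very small df the cluster
  geometry of the two fields can differ slightly (empirically negligible at
  n ≈ 31).
- Gene–phenotype similarity inherits all the caveats of correlating smooth
  spatial maps: no correction for spatial autocorrelation of expression, and
  with few regions the similarity distribution is wide.
- The toy parcellation and the expression generator are deliberately simple;
  passing tests demonstrates correctness of the pipeline's statistics and
  plumbing, not anatomical or transcriptomic realism.
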