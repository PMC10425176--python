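# Methods

`npbfates` re-implements, as a tested and reusable pipeline, a single-cell
analysis of ectodermal fate segregation at the chick neural plate border:
knowledge-matrix cell-state classification, iterative gene-module detection
with differential-expression filtering, fate-probability inference on a
velocity/kNN Markov chain, fate-weighted spline models of expression
dynamics, and co-expression-based identification of undecided progenitors
(BLUPs).  Every stage is exercised end-to-end on synthetic data with known
ground truth; nothing here requires a download.

## The synthetic-data generator

The generator (`npbfates.simulate`) emulates the statistical structure the
analysis assumes, not any real embryo's gene catalogue.

**Cells.**  Six ordered stages (HH4, HH5, HH6, HH7, ss4, ss8), by default 500
cells per stage.  Each cell carries a mediolateral position `x ~ U[0, 1]`
(0 = medial/neural side, 1 = lateral/non-neural).  Each stage partitions the
axis equally over its allowed cell states (taken from the bundled knowledge
matrix's stage map); a cell's true state is the band containing its position,
and its true fate is the band of the final stage.

**Genes** (2000 by default):

- *State markers* — 12 genes per state, expressed at `baseline_mean x
  marker_effect` inside the state's band (logistic edges, scale
  `1/gradient_steepness`) and at baseline elsewhere, only at stages where the
  state exists.  Defaults: baseline 10 counts, fold-change 2.
- *Fate-module genes* — 12 genes per module (neural, neural-crest, placodal),
  shared across the states of one lineage in the knowledge matrix.  They
  follow a fate-specifier profile: near-off (0.15 x baseline) outside their
  domain, graded logistic bands inside it.  The band width shrinks
  geometrically over stages (`blup_frac x geomspace(0.72, 0.06)`), so cells
  co-expressing two modules above threshold become rarer with developmental
  time, while the in-band amplitude rises linearly (1.0 -> 2.2) as expression
  domains sharpen.  A module-level log-normal factor (sd 0.2) makes module
  genes co-vary beyond their spatial signal.
- *Batch-artifact and flat blocks* — two 8-gene blocks elevated
  `exp(batch_effect_sd)`-fold in one sequencing batch each, and two 8-gene
  blocks driven only by a shared log-normal factor (sd 0.6).  These are the
  planted negatives for the module filter cascade.
- *Confounder genes* — mitochondrial (`MT-`) genes proportional to a per-cell
  mitochondrial fraction `f ~ U(0.02, 0.10)`; stress genes correlated with
  that fraction; W-chromosome genes on in female cells and near-off in males
  (Z genes dosed the other way); cell-cycle genes driven by a per-cell
  normal factor; the remainder is flat housekeeping background.

**Noise.**  All counts are negative binomial with variance
`mu + dispersion * mu^2` (default dispersion 0.2); `dispersion -> 0`
degenerates to Poisson.  One `numpy` generator seeded from `SimConfig.seed`
drives every draw, so identical configs are bit-identical.

**Poor-quality and contaminant cells.**  4% of cells are poor quality, in two
tiers: severe cells (binomial thinning to 3% retention) fall below the
1000-detected-genes threshold and are caught by the per-cell filter; mild
cells (10% retention) additionally look like dying cells — raised
mitochondrial fraction (10–14%) and a flattened expression program — and are
left for cluster-level QC to catch.  3% of cells are contaminants expressing
a disjoint mesoderm-like marker block instead of the ectodermal program.

**Spliced/unspliced layers.**  Fate-module gene layers follow the
transcription–splicing–degradation model `du/dt = a - b u`,
`ds/dt = b u - g s` (closed form in `simulate_kinetics`, with the analytic
limit at `b = g`), evaluated at a per-cell time that increases with stage
(`t = 0.2 (stage + U[0, 1.15])`, rates b = 2, g = 1).  Later cells therefore
sit nearer kinetic steady state and early cells have elevated unspliced
fractions, so estimated velocities point from early toward late cells.  All
other genes are at kinetic equilibrium around their mean (`u/s = g/b`).  The
main count matrix carries the full-strength expression program; only the
layers carry the kinetic ramp — the two are deliberately decoupled so that
classification and module structure are stationary across stages while the
velocity machinery still sees maturation.

**What the generator does not emulate:** doublets, ambient RNA, UMI
collisions, sequencing error, realistic gene-gene regulatory structure, or
continuous state transitions beyond the logistic band edges.  Passing tests
therefore demonstrate that the pipeline recovers structure *of the kind it
assumes*, not that it is robust to everything real data contains.

## QC and preprocessing

The filtering rules are applied exactly as stated in their sources: genes in
fewer than 5 cells removed; cells with fewer than 1000 or more than 6500
detected genes, or more than 15% mitochondrial content, removed (all bounds
keep at equality); clusters whose median detected-gene AND median UMI counts
both fall below the dataset's 25th percentiles flagged as poor; clusters
whose median marker-set score exceeds the 90th percentile for any
contaminant set flagged for removal.  Percentiles use linear interpolation
and removal requires strict inequality.

Normalization is library-size scaling to the median library followed by
`log1p`.  Scaling fits per-gene OLS of normalized expression on the
covariates (mitochondrial %, k-means-called sex, a cycle score, batch
indicators), with collinear columns dropped via pivoted QR and standardised
residuals clipped at ±10.  A numerically-zero residual variance (relative
tolerance 1e-10) yields exact zeros rather than amplified rounding noise.

PCA for clustering is restricted to highly variable genes: per-gene count
variance against a quadratic log-log mean–variance trend, top 300 residuals.
This mirrors the variable-feature step of the standard Seurat/scanpy
workflow and is what makes a ~100-gene signal detectable among ~1900
background genes at 500 cells.  The PC count comes from the elbow heuristic
(`select_pcs`): the larger of "first PC whose successor is below 5% of total
stdev" and "first PC with cumulative stdev above 90%", capped by the first
PC whose successor adds less than 0.1 percentage points; conventions are
fixed and unit-tested because the heuristic exists only as prose.  Louvain
community detection (igraph's multilevel algorithm, seeded) runs on a
Jaccard-weighted shared-nearest-neighbour graph; resolution 2.0 for QC
passes and 0.5 for analysis.

## Knowledge-matrix classification

States are scored per cell as the mean scaled expression of the state's
marker genes (absent genes dropped with a warning); each cluster gets the
allowed state with the highest median score, ties breaking to the earlier
matrix column.  Classification runs per stage on re-normalized, re-scaled,
re-clustered subsets, with stage-restricted candidate states, and the labels
are transferred to the merged dataset.  The bundled 132 x 8 matrix is an
illustrative synthetic stand-in for a literature-derived matrix (the real
analysis used 76 genes x 24 states); its stage map allows 3–4 states per
stage.

## Gene modules

Genes failing to reach Spearman correlation 0.3 with at least 3 partners are
dropped; the survivors are clustered hierarchically (average linkage on
1 − Spearman), cut into `n_modules` groups, filtered for expression (≥ 10
cells with more than half the module's genes on, where "on" means
normalized value > 0, and mean on-fraction ≥ 40% among those cells), and
re-clustered until membership stabilises.

The DE cascade uses one-vs-rest two-sided Wilcoxon rank-sum tests on
normalized expression (exact p-values on small tie-free groups via scipy's
exact method, asymptotic otherwise), Bonferroni adjustment over tested
genes, and natural-log fold changes of *expression-scale* group means
(`expm1` of the log-normalized values, pseudo-count 1e-9) — the convention
of the ecosystem the thresholds come from; computing fold changes on the
log scale would roughly halve them and silently defeat the stated cut-offs.
The cascade keeps modules with > 50% of genes DE across cell states (|logFC|
> 0.5, adjusted p < 0.001), drops modules with > 50% of genes DE between
batches (logFC > 0.25), and optionally keeps modules DE among the three late
lineages (logFC > 0.25) on the last stage's cells.  The NPB variant replaces
the state filters with a single neural-crest-versus-placodal contrast at
logFC 0.25.  Cascade order is fixed; permuting it can change results.

## Fate inference

Moments are per-cell means of the spliced/unspliced layers over the 20
nearest neighbours (plus the cell itself) in the top-20 PC space of
normalized spliced counts.  Velocity uses the steady-state estimator: per
gene, `gamma_hat` is the zero-intercept slope of unspliced on spliced over
the extreme 5% quantiles of spliced, and `velocity = u - gamma_hat * s`.
This deliberately replaces a full dynamical-kinetics fit: the EM machinery
of the dynamical model is out of proportion to its role here, and the
steady-state model preserves the directional signal the Markov chain needs.

The velocity kernel assigns cell *i* transition probabilities over its
neighbour set proportional to `exp(4 x cosine(v_i, x_j - x_i))` (the cell
itself enters with cosine 0; a zero-velocity cell falls back to a uniform
row).  It is mixed 0.8/0.2 with the row-normalized symmetric kNN
connectivity kernel.  Kernel geometry and the latent-time graph live in
covariate-regressed spliced PC space — without regression the strong
W-chromosome signature splits the graph by sex.

Terminal sets are user-declared selectors ("NC@ss8") resolved against the
classified labels.  Absorption probabilities solve `(I - Q) F = R` with a
sparse direct method (iterative fallback), where Q is the
transient–transient block and R the transient-to-terminal block aggregated
by fate; terminal cells carry indicator rows, rows sum to 1, and
unreachable cells are reported by name.  The test-suite oracle simulates
1e5 exchangeable random walks per start cell as multinomial population
counts.

Latent time is diffusion pseudotime from a stage-anchored root (the
earliest-stage cell with the extremal first non-trivial diffusion-map
coordinate), min-max scaled to [0, 1].  This replaces a likelihood-based
latent time: it plays the same ordering role, is closed-form, and is
directly testable against the generator's stage order.  The stated
"diffusion weighting 0.2" of the original latent time interacts with
dynamical-model likelihoods that are out of scope here; it has no direct
analogue in this implementation and is noted rather than emulated.

## Expression dynamics

`WeightedSplineGAM` fits module or gene expression on a cubic B-spline basis
of latent time — `knots` (default 4) interior knots at equally spaced
quantiles — with a log link and negative-binomial variance
`V(mu) = mu + alpha mu^2` used as a quasi-likelihood (the response, an
average of normalized values, is continuous; only the variance function and
link enter the penalized IRLS).  Observations are weighted by one fate's
absorption probabilities; zero-weight cells are excluded exactly, and
weights are normalized to mean 1 so that uniform rescaling cannot interact
with the penalty.  A second-order difference penalty is selected by GCV over
a fixed geometric grid (1e-5..1e3).  Intervals are pointwise 95% Wald bands
propagated through the link (whether the original bands were pointwise or
simultaneous is unstated; pointwise is implemented and labelled).  A
Gaussian-on-log1p fallback family is available.

The mediolateral axis is the negated first principal component of a stage
subset, sign-fixed so that cells scoring high for a designated lateral
(non-neural) marker set lie above cells scoring high for the medial (neural)
set — PC signs are arbitrary, so the orientation is an explicit, testable
rule rather than a visual call.  Spatial smooths are unweighted identity-link
spline fits of scaled expression (which can be negative) along the axis.
HCR intensity tables (gene x {anterior, intermediate, posterior}) are
z-scored per gene with the sample standard deviation over the three levels.

## Co-expression and BLUPs

Module scores (per-cell means of normalized expression over module genes)
are min-max scaled within the cell set being analysed — per stage in the
pipeline, matching per-stage panels.  A cell is a BLUP for a module pair
when both scaled scores are strictly above 0.3 (the threshold applies to
each module, not to the product).  The co-expression statistic is the
per-cell product of the two scaled scores, summarised in 50 fixed bins on
[0, 1]; the two-colour blend assigns `floor(scaled x 99)` indices on a
100 x 100 grid, with sub-threshold cells flagged unassigned.  "Declines from
the earliest to the latest stage" is read as a strict endpoint decrease with
a monotone rank trend; adjacent early stages can tie within noise because
the co-expression zone saturates when the gradient width approaches the band
width.

## Problem sizes and numerical choices

The default synthetic dataset is 6 x 500 cells x 2000 genes; module and
co-expression unit tests use 6 x 250; the pipeline reproducibility check
uses 6 x 120.  These sizes were chosen so the whole suite and the
acceptance script each complete in well under a minute on one core while
leaving every recovery statistic comfortable margins.  Monte-Carlo oracles
use 1e5 walks per start cell.  Sparse linear solves use a direct
factorization with an lgmres fallback at tolerance 1e-12.  Row-stochasticity
is enforced to 1e-10, fate-probability row sums to 1e-8.  All clustering,
k-means and PCA calls take explicit seeds (default 42) and the pipeline is
bytewise reproducible for a fixed config.

## Known limitations

- The generator's band-partition geometry makes state recovery easier than
  real continuous fate transitions; classification accuracy on real data
  would be lower.
- The steady-state velocity estimator is biased for genes far from
  equilibrium everywhere; it suffices for direction, not for rate estimates.
- Early-stage fate probabilities are close to the connectivity prior (the
  early kinetic signal is weak by construction); only late-stage assignments
  are sharply determined.
- Batch effects are handled by covariate regression, not anchor-based
  integration; strong nonlinear batch structure would not be removed.
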