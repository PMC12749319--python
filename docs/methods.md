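# Methods

## The analysis in brief

`lbdgrad` re-implements a cortical-gradient analysis of Lewy body disease
as a fully testable pipeline. The object of study is the principal
gradient of a parcellated connectome: for each subject, a 200-region
connectivity matrix (streamline counts for structural, correlations for
functional data) is row-sparsified to its strongest connections, converted
to a normalised-angle affinity

    A(i, j) = 1 - arccos(cossim(x_i, x_j)) / pi,

and embedded by diffusion maps. With degree `d = sum_j A(i, j)`, the
density-normalised kernel `W = A / (d_i^a d_j^a)` (a = 0.5) is
row-normalised into a Markov operator `P`; the leading non-trivial
eigenvectors of `P`, scaled by `lambda / (1 - lambda)` ("automatic
diffusion time"), are the gradients. G1, the first component, orders
regions along the dominant axis of connectivity differentiation. Each
individual's gradients are aligned to a control-group template by
single-pass orthogonal Procrustes (rotation/reflection only).

Downstream, three families of questions are asked:

1. **Distribution level** — does the per-subject spread of G1 scores (SD
   of regional scores; range and mean absolute deviation are reported
   alongside) differ between groups? Kruskal-Wallis with Dunn post-hoc
   pairwise z tests (BH-corrected).
2. **Regional level** — per-region OLS of the aligned G1 score on group +
   age + sex gives an unthresholded t-map with BH-FDR q values across the
   200 parcels.
3. **Severity** — the composite gradient difference score
   `Gs = sum_regions |x - mu_HC| / sigma_HC` (sample SD, n-1, controls
   only) is Spearman-correlated with clinical scores, optionally as a
   partial correlation computed on rank-transformed variables (the
   covariates are ranked too, so the partialling stays on the rank scale).

Spatial inference against annotation maps (pooled cell-type marker
expression, microarchitectural axes, disease gene sets) and the
imaging-transcriptomics PLS both use spin permutations: one uniform random
rotation per permutation is applied to the left-hemisphere parcel
centroids and its x-mirrored counterpart to the right hemisphere, and
every parcel takes the value of the nearest rotated centroid within its
own hemisphere (duplicates allowed). Two-sided
`p_spin = (1 + #{|rho_null| >= |rho_obs|}) / (n_perm + 1)`; BH-FDR within
a declared family gives `q_spin`. The disease t-map is the map that is
spun; annotation maps keep their empirical spatial structure.

## The synthetic cohort: what it emulates

The restricted imaging data cannot ship, so every stage runs against a
generative model that has the structure the analysis assumes: each region
carries a latent coordinate on one axis (uniform on (-1, 1), centred), and
the expected edge weight decays exponentially with latent distance (unit
length scale). Structural weights are overdispersed integer counts
(negative binomial, dispersion 8, peak mean 200 streamlines); functional
weights are correlations peaking at 0.9. Diffusion-map embedding of such a
connectome recovers the latent axis as G1 (template |rho| ~ 0.95 against
the planted axis at 200 regions).

Disease regimes transform a subject's latent coordinates:

* **expansion** (gamma > 1): coordinates scaled outward — wider G1 score
  distribution (the hypothesised PD-without-dementia pattern; default
  gamma 1.3);
* **contraction** (gamma < 1): the converse;
* **reorganisation**: `ceil(f * n)` randomly chosen coordinates cyclically
  permuted among themselves (default f = 0.3) — regional rankings change
  while the coordinate set, and hence the overall distribution, is
  untouched (the hypothesised dementia pattern). All subjects of a
  reorganised group share one relocation by default: a disease that moves
  the *same* regions in every patient is what makes a group-level t-map
  interpretable. Per-subject relocations are available
  (`shared_reorg=False`) and demonstrably wash the regional signal out.

Two sources of within-group variability are modelled and their magnitudes
matter:

* `noise_sd = 0.8` — per-edge log-normal jitter of the expected count
  (mean-preserving), giving a between-subject edge-weight CV near 95%,
  in line with the heavy-tailed variability of streamline counts;
* `subject_sd = 0.5` — idiosyncratic Gaussian jitter of each subject's
  latent coordinates, giving subject-to-template G1 correlations around
  0.75, the range typically seen for individual structural gradients
  against a group template.

These two values were calibrated jointly (grid search over the generator's
invented parameters) so that the planted regimes reproduce, at the study's
group sizes (23 HC / 46 PD-NC / 62 LBD), the qualitative pattern the
effect taxonomy describes: gamma = 1.3 expansion is detected by the spread
Kruskal-Wallis with power >= 0.8 while a reorganised group leaves the
spread test at its nominal false-positive rate yet shows FDR-significant
regional differences in >= 80% of replicates. The calibration is needed
because Procrustes alignment converts a genuine shared reorganisation into
a small apparent spread change (a cluster-level random bias of ~0.3-1% of
the mean spread, of either sign, caused by chance overlap between the
permuted G1 and higher template components). With unrealistically tight
within-group variability that bias is always detectable; at realistic
variability it drowns, which is the regime the pipeline is meant for.
The same alignment leak is a real property of gradient pipelines, worth
knowing when interpreting small distribution shifts in patient groups.

Clinical scores are planted with a Gaussian copula on ranks: each
subject's deviation `||latent_subject - latent_template||` is mapped to
normal scores, and the synthetic cognitive score is
`r z + sqrt(1 - r^2) e` with `r = 2 sin(pi rho / 6)` (the Pearson value
giving Spearman rho under a Gaussian copula; default target rho = 0.483,
applied within each group). The noise `e` is sample-orthogonalised against
`z`, so the coupling is planted as an exact sample correlation and the
realised Spearman fluctuates only through the rank transform (SD ~0.03 at
n = 62). Because the measured `Gs` is a noisy proxy of the latent
deviation, the observed Gs-to-score correlation is attenuated relative to
the planted coupling — exactly as a real biomarker would be. The motor
score is coupled at rho = 0.

Annotation and expression maps are spatially autocorrelated fields on a
quasi-uniform two-hemisphere sphere (golden-angle lattice, mirrored in x):
white noise smoothed by a geodesic exponential kernel and z-scored.
Length scale 0.2 rad is the default — roughly the autocorrelation of
parcel-level cortical annotation maps, and a regime in which the spin test
is well calibrated (measured false-positive rate ~4-5% at alpha = 0.05).
Far smoother fields (0.5 rad, ~9 effective degrees of freedom across 200
parcels) cannot be calibrated by any permutation scheme and are used only
to demonstrate the anticonservativity of naive permutation. Expression
tables mix per-gene smooth noise with optional planted target maps at a
stated effect size and rescale each gene into [0, 1], mimicking
sigmoid-normalised donor expression.

What the generator does **not** emulate: tractography biases and
distance-dependent false positives, motion artefacts, the donor structure
and spatial sampling of postmortem expression atlases, hemispheric
asymmetries, and any true cytoarchitectural geometry — the
"microarchitectural axes" in the annotation family are synthetic smooth
maps. Passing tests therefore show that the *statistical machinery* is
correct and calibrated under the assumed generative structure, not that
the biological conclusions transfer to real data.

## Numerical and design choices

* **Order of operations**: connectivity rows are sparsified first
  (per-row, zeroing the `floor(sparsity * n)` smallest entries; ties
  broken by zeroing the smaller column index first), then the
  normalised-angle kernel restores symmetry. Default sparsity 0.9;
  0.8 and 0.5 are replication settings.
* **Stable angles**: `arccos` is ill-conditioned at cossim ±1. Pairs with
  |cossim| > 1 - 1e-6 are recomputed from chord lengths by direct vector
  subtraction via arcsin forms, so identical / orthogonal / antiparallel
  profiles give exactly 1 / 0.5 / 0 to 1e-12.
* **Embedding**: the Markov operator is diagonalised through its
  symmetric similarity transform (top `n_components + 1` eigenpairs
  only); the trivial unit eigenvector is discarded, and a second unit
  eigenvalue raises a "disconnected graph" error suggesting lower
  sparsity. Eigenvector sign is fixed by making the largest-magnitude
  entry positive.
* **Procrustes**: single-pass orthogonal alignment to the fixed control
  template; no scaling, no centring, no iterative joint template.
* **Fusion**: structural and functional blocks are rescaled to equal
  Frobenius norm before horizontal concatenation.
* **Dunn post-hoc**: pairwise z on mean ranks with the pooled
  tie-corrected variance, BH across pairs (no installed package provides
  Dunn's test). All-tied input returns a degenerate H = 0 / p = 1 result
  rather than an error.
* **PLS**: NIPALS with deflation (tolerance 1e-12, <= 500 iterations; a
  univariate response converges in one pass), X columns z-scored with the
  population SD (zero-variance genes dropped with a warning), Y z-scored,
  PLS1 sign fixed so region scores correlate positively with Y. Spin
  significance refits only PLS1, which for univariate Y reduces to matrix
  products and is computed for all permutations at once.
* **Gene-level null**: each gene's |PLS1 weight| is compared to the
  *pooled* null distribution of all genes' spin weights (two-sided),
  then BH across genes. A per-gene null is available, but with 1000
  permutations its smallest attainable p is 1/1001, and after BH across
  ~1000 genes no single gene could ever be significant — the pooled null
  restores p-value resolution of ~1/(n_genes x n_perm). Genes differ
  only by exchangeable smooth-noise structure here, so pooling is
  appropriate; with strongly heterogeneous gene variograms the per-gene
  variant is the safer choice.
* **Spin ensembles**: nearest-neighbour reassignment with duplicates.
  Selection frequencies across parcels are *not* uniform (Voronoi-area
  bias is intrinsic to this family); the tests assert hemisphere closure,
  coverage and mirror-consistency instead. Null correlations re-rank the
  spun map (duplicates change ranks), vectorised across permutations.
* **Sex** is a binary indicator in design matrices; subjects with missing
  model covariates are dropped listwise with a logged warning. Missing
  clinical scores are removed pairwise per correlation, with n reported.
* **Partial rank correlation**: if a variable is fully explained by the
  covariates (residual norm < 1e-8 of the centred rank norm), the partial
  correlation is reported as 0 rather than the correlation of rounding
  errors.

## Problem sizes used by the test-suite and acceptance script

Cohort-level Monte-Carlo checks run 100 replicates of full 200-parcel
cohorts at the study group sizes; spin calibration uses 500 independent
map pairs with 1000 spins each; PLS recovery/calibration uses 200 parcels
x 1000 genes x 1000 spins (100 and 200 replicates respectively). The
acceptance script reports one full pipeline run plus a 200-pair spin
calibration, all derived from the single `--seed` argument.

## Known limitations

* The spread statistic feeding the Kruskal-Wallis is a choice (SD is
  primary); the distribution test is sensitive to any distributional
  difference, including the alignment leak described above.
* `Gs` sums |z| over regions, so it grows with parcellation size and has
  a positive null mean under pure noise; it is comparable only within a
  fixed parcellation and control set.
* Spin nulls assume a spherical geometry with parcels of comparable size;
  strongly non-uniform parcellations would need variogram-style nulls,
  which are out of scope.
* The PLS permutation tests spin only the dependent map; gene-gene
  co-expression is preserved, but no donor-level uncertainty is modelled.
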