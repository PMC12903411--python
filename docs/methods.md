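# Methods

`senespat` re-implements, as a tested library, the computational workflow
of a spatial-transcriptomics + single-nucleus study of aging and
senescence in human cortex: laminar differential expression under a
hierarchical Bayesian zero-inflated-Poisson (ZIP) model, coexpression
module discovery, senescence hallmark positivity scoring, neighborhood
enrichment, cell-composition testing, and a simulation power study.
Everything runs on synthetic data with planted ground truth; no download
is required.

## Synthetic data

**Spatial counts.** Arrays are square grids (default 15 x 15) whose rows
form seven horizontal bands mimicking cortical lamination: layers L1..L6
and white matter (WM). Rook (4-neighbor) adjacency stands in for the
Visium hex lattice; all model and enrichment code takes the adjacency as
input, so the lattice choice is isolated in the generator. For spot `s`
and gene `g`,

    y_sg ~ ZIP(lambda_sg, theta),
    log lambda_sg = beta[g, aar(s), group(donor(s))] + psi_sg + eps_sg,

where `beta` is the characteristic natural-log counts/spot of a gene in
an anatomical annotation region (AAR) for a donor age group (young <45,
middle 45-55, old >55 years), `psi` is a spatially autocorrelated field
drawn from a proper conditional-autoregressive model on the grid and
rescaled to `spatial_sd`, `eps` is i.i.d. log-normal spot noise, and
`theta` is the structural dropout probability. Defaults: `beta` at the
MEDIUM characteristic rate of 0.6 counts/spot (the 90th-percentile
expression level of the power-study calibration), `theta = 0.1`,
`spatial_sd = noise_sd = 0`. Sexes alternate within each group for
balance; no per-spot size factors are used (`lambda` is counts/spot).
Planted modules add AAR- and age-group-specific log effects to member
genes' `beta` rows, which is both the fold-change ground truth for DE
and the shared spatial profile that makes member genes co-vary.

**Nuclei counts.** Each broad class (Ast, End, Exc, Inh, Mic, Oli, OPC,
Peri, default mixture roughly matching cortical proportions, excitatory
neurons 35% down to pericytes 4%) shares a log-normal baseline program
with its own elevated marker genes (default 20 markers at 8x). Counts
are Poisson at a log-normal per-nucleus depth (median 4,000 UMIs,
matching typical snRNA-seq depth); mitochondrial genes are pinned near
2% of reads. Donor cell-type proportions receive a logit-scale
perturbation (sd 0.2) so that composition tests face realistic
inter-donor variability. Planted senescent nuclei (default:
oligodendrocytes at 2% / 6% / 12% of young / middle / old donors, rising
with age as p16+ burdens do) multiply the member genes of designated
hallmark lists — and CDKN2A, which sits in the cell-cycle-arrest list —
by the effect size (default 2x).

**Hallmark lists.** Three multi-hallmark and seven individual hallmark
lists (cell-cycle arrest, SASP, apoptosis resistance, DNA-damage
response, cell-surface markers, lysosomal content, p53 targets) are
carved from unflagged genes (default 40 genes each; multi-hallmark lists
borrow half their genes from the individual lists, as curated panels
do). The complement of all lists is the control pool, from which a fixed
2,000-gene control set is sampled once per seed. The real curated lists
are not shipped; these synthetic stand-ins exercise the same code paths.

What the generator does **not** emulate: hexagonal Visium geometry and
fiducials, negative-binomial overdispersion beyond the ZIP-lognormal
family, ambient RNA, doublets, batch chemistry effects on specific
genes. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
artifact of real tissue data.

## Filters

Gene filter: drop mitochondrial/lncRNA/pseudogene biotypes and genes
detected (count > 0) in fewer than 0.67% of spots. Spot filter: keep
spots with >= 100 UMIs over surviving genes (inclusive at 100: "fewer
than 100" are discarded) and a valid AAR, then iteratively remove spots
without a surviving grid neighbor until stable — one pass could leave
newly isolated spots, which would make the spatial prior singular.
Nuclei QC: nUMI > 500 (strict) and mitochondrial fraction < 5% (strict),
then mitochondrial genes are removed and nUMI recomputed. Because of
that recomputation, a second application can in principle drop a nucleus
whose depth fell just below 500 after removing its mitochondrial reads;
at realistic mitochondrial fractions (~2%) this affects only nuclei in a
narrow depth band.

## The spatial model and its inference

Priors: `beta[a, g] ~ N(mu_a, sigma_beta^2)` with `sigma_beta = 1` fixed
and `mu_a ~ N(0, 2^2)` (one hierarchy level: AAR mean -> age-group rate;
sexes are pooled, balanced by design); an intrinsic CAR prior on `psi`
over the within-array spot graph with a soft sum-to-zero constraint per
array; `eps ~ N(0, sigma^2)`; `theta ~ Beta(1, 2)` per gene.

Inference is MAP plus a Laplace (Gaussian) approximation of the
`(beta, mu)` marginal, with two deliberate departures from a naive joint
mode, both forced by the same failure:

* **The spot noise `eps` is marginalized, not optimized.** With one
  observation per spot, jointly maximizing over a free per-spot vector
  is the classic incidental-parameters problem: the fitted noise scale
  inflates, spot effects absorb Poisson variability, and `beta` is
  biased by `-sigma^2/2`. The likelihood is instead a ZIP-lognormal
  mixture with `eps` integrated out by 15-node Gauss-Hermite quadrature.
  `sigma` keeps a half-Normal(0.3) hyperprior: at ZIP rates a large
  noise scale is nearly unidentified against dropout (log-normal zeros
  mimic structural zeros), so the scale must stay informative.
* **The ICAR scale `tau` is a fixed model scale (default 0.3), not a
  free parameter.** At a joint mode a free `tau` escapes any scalar
  prior: the field gains ~0.5 nat for every ZIP zero it carves out,
  driving the dropout estimate to zero and `beta` down by half the
  squared field amplitude (measured on a 50-gene screen: bias -1.3,
  90% interval coverage 69%). With `tau` fixed, spot-wise wiggles cost
  quadratically in the unit-ICAR field while genuinely smooth laminar
  patterns remain cheap. After both changes the same screen shows bias
  -0.04 and coverage 93%.

The `beta` covariance marginalizes over the spatial field through a
Schur complement of the observed information (sparse LU on the
field block); hyperparameters are plugged in at their MAP values.
Posterior draws of `beta` (default 1,000) are Gaussian. Convergence is
flagged from the optimizer status and the scaled gradient norm, never
silently. An ensemble-MCMC backend (emcee) is available for fits without
the latent spatial field and is used in the tests as an audit of the
Laplace approximation; genes are fitted independently with no shared
mutable state.

**Differential expression.** For comparison groups (a, b) in an AAR, the
Savage-Dickey density ratio gives BF = prior density of
`delta = beta_a - beta_b` at 0 over its posterior density at 0, the
posterior density estimated by a Gaussian KDE with Silverman bandwidth
and the ratio clipped to [1e-6, 1e6]. The induced prior on `delta` is
N(0, sqrt(2) * sigma_beta); for an AAR-averaged difference the prior sd
scales as sqrt(2/A). `beta` is natural-log scale, so
log2FC = mean(delta)/ln 2. A gene/AAR is called at BF > 3 with
|log2FC| > 1; evidence tiers at BF > 3/10/30.

## Coexpression modules

Pearson correlation of the spot x gene expression matrix (posterior mean
`lambda` in the full pipeline; zero-variance genes get r = 0), a KNN
graph linking each gene to its k = 10 most-correlated genes (undirected
union; weights = correlation floored at 0), Leiden clustering at
resolution 2, and a 50-gene minimum module size (smaller modules'
genes become unassigned). The Leiden seed is fixed and exposed. The
resolution default follows the full-scale workflow; because the
configuration-model null scales with total edge weight, desk-scale toys
(hundreds of genes) resolve planted blocks at resolution ~1, which the
tests pass explicitly. Submodules re-correlate each module's genes over
depth-normalized (10k), log1p-transformed nuclei expression and
re-cluster at resolution 1, with ids "M<i>.<j>".

Module scores clip each member gene at its 99th percentile (linear
interpolation, "type 7" — documented because the clip value depends on
the convention), z-scale across all spots, and average members per spot.
Age testing uses per-(array, AAR) mean scores, Welch's t, and BH across
the whole (module x AAR x comparison) family, with tiers at
q < 0.05 / 1e-2 / 1e-3 / 1e-4. Correlations pool all spots (no per-array
standardization).

## Nuclei statistics

**MASC composition test.** Mixed-effects logistic regression of
per-nucleus cluster membership on age-group (fixed) and sex (fixed),
with random intercepts for donor and batch (donors nested within
batches) for cell-type abundance, or batch only for senescence
positivity. Membership is aggregated to per-(donor, batch, sex, group)
binomial units; the marginal likelihood integrates the random effects
with 12-node Gauss-Hermite quadrature (inner integral per donor, outer
per batch), the scales carry a weak half-Normal(0, 3) regularizer, and
the fit is Nelder-Mead. The age effect is tested by a likelihood-ratio
test (chi-square, 1 df) and reported as an odds ratio with a Wald 95% CI
from numerical observed information; when a random-effect scale sits at
its boundary and the full information matrix is singular, the
fixed-effect block with plugged-in scales is used. Complete separation
(a cluster absent from one arm) is reported with an infinite-OR flag,
not raised. The tests cross-check the estimator against R/lme4's
`glmer` on a fixture and verify null LRT p-value uniformity and CI
coverage by simulation.

**Pseudobulk DE.** A deliberately simple stand-in for precision-weighted
linear modeling: genes must be expressed in >= 30 nuclei of the class
and detected in >= 75% of young donors or of old donors (middle donors
are ignored by the detection rule); per-donor summed counts on
log2(CPM + 1) are regressed on age in years plus sex and batch by
ordinary least squares; BH correction. Effects are reported as log2FC
over the 35-year young-to-old midpoint span (midpoints 35/50/70 when
exact ages are unavailable). No voom-style precision weights —
heteroscedasticity is handled only through pseudobulking; rank-deficient
designs raise an error naming the confounded columns.

**ROC markers.** Per-gene AUC of expression as a classifier of group
membership, computed from ranks (Mann-Whitney U, ties mid-ranked), genes
ordered by |AUC - 0.5|.

## Senescence scoring

Module scores follow the control-feature scheme of single-cell module
scoring: all genes are binned (24 equal-frequency bins; a common
single-cell default, exposed in the API) by mean normalized expression,
up to 100 controls per set gene are sampled — seeded — from the gene's
bin *within the fixed 2,000-gene control set*, with a whole-pool
fallback for empty bins, and the score is mean(set) minus
mean(controls). Fixing one control set per run and bin-matching within
it reconciles the two descriptions of the procedure (a maintained
control feature set; expression-bin matching). Thresholds are the 95th
percentile (type 7) of young-group scores per (broad class, hallmark);
strata under 20 young nuclei yield missing thresholds. Positivity is
strict (score > threshold), so by construction ~5% of young nuclei are
positive per hallmark, up to ties and finite-sample granularity; "3+
hallmarks" counts positives among the seven individual hallmarks only.
Age differences in positivity rates use the MASC test with batch as the
random effect, plus a one-sided difference-of-proportions z statistic
for display. p16 positivity is CDKN2A transcript count > 0; per-donor
percentages are regressed on age of death by ordinary least squares.

## Cell composition

Per-(type, donor) pseudobulk drops types without >= 10 cells in >= 2
donors, depth-normalizes pseudo-samples to 1e4 and log1p-transforms.
Marker selection rank-tests each gene per type against all other types'
pseudo-samples (Wilcoxon rank-sum, normal approximation with tie
correction, BH), gates at mean logFC > 1.25 (natural-log fold change of
normalized pseudobulk means, matching the upstream transform) and
q < 0.05, discards the global top 1% of genes by dispersion
(variance/mean within type, averaged over types), resolves genes passing
in several types to the type with the largest logFC, and truncates every
list to the smallest surviving count so types are balanced.

Deconvolution is a non-negative least-squares fit of each spot's marker
expression onto per-type mean marker profiles with weights normalized to
sum to 1 — plain plumbing standing in for external probabilistic
deconvolution tools, adequate here because the synthetic programs are
well separated. All-zero spots get a uniform composition and a flag.
Composition-vs-age testing averages spot compositions per donor and
layer and applies the Wilcoxon rank-sum test (exact at small n) with BH
across the (type x AAR x comparison) family.

## Neighborhood enrichment

Spot scores are mean normalized expression of a gene set minus the mean
of 2,000 random non-member control genes (seeded; all available used,
with a log, when fewer exist). Deciles are assigned over all spots
pooled across age groups by stable rank (ties broken by spot order), so
label shares are 10% up to remainders; constant scores collapse to label
1 with a degeneracy flag. For a spot group, the observed count of
adjacent unordered label pairs {i, j} is compared against labels
permuted independently within each array (arrays as batches; 1,000
permutations by default; the sample, n-1, standard deviation).
Pairs with zero permutation sd are flagged degenerate rather than given
a z-score. An exact mode enumerates all distinct within-array label
arrangements for tiny inputs and is verified against brute force in the
tests.

## Power study

Characteristic expression levels follow the study calibration: LOW 0.025
(20th percentile), MEDIUM 0.6 (90th), HIGH 10 counts/spot (99.9th), with
fold changes from 1 to 3 and dropout theta defaulting to 0.1 (the
level-to-theta pairing is a documented free parameter; `mle_zip` can
estimate it from data). Each replicate simulates control and comparison
groups of reduced 15 x 15 arrays (the array size is exposed in the
config and reported with results), fits the ZIP model without latent
spot fields — the simulation has none, and this keeps each of the many
replicate fits fast — and computes Savage-Dickey BFs. Power is reported
per AAR and overall; the headline detection is the AAR-averaged group
difference at BF > 3 with the correct sign (no fold-change gate in the
power criterion). Reduced arrays hold ~32 spots per AAR, about two
orders of magnitude fewer than full-size arrays, so per-AAR power at
small fold changes is structurally lower than at full scale while the
overall (all-AAR) test retains it: at MEDIUM with fold change 1.2 and 20
arrays/group the overall detection rate exceeds 80%, matching the
full-scale design rule. Non-converged replicates are excluded from the
denominator and counted.

## Numerical choices and degenerate inputs

* Percentile convention: linear interpolation (type 7) everywhere
  (clipping, thresholds, deciles).
* BF clipping to [1e-6, 1e6]; KDE underflow far from zero maps to the
  upper clip. At least 500 draws are required.
* Zero-variance genes correlate at 0; constant genes contribute 0 to
  module scores; all-zero spots deconvolve to a uniform, flagged
  composition; all-zero genes fit to a tiny rate without crashing.
* The 100-UMI spot rule is inclusive at the boundary; the 500-nUMI and
  5%-MT nuclei rules are strict.
* BH families: all tests of one run of the respective table builder.
* Seeds: every stochastic routine takes an explicit seed and derives
  independent streams via `numpy` `SeedSequence`; fixed seeds make every
  generator byte-identical across runs.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
the statistical claims are testable rather than merely plausible:
spatial screens of 50-120 genes on 12-40 reduced arrays (1,350-9,000
spots), nuclei datasets of ~3,600 nuclei x 2,500 genes, 50-replicate
power runs, 100-200-replicate calibration studies. The headline
real-data quantities of the original study (tens of thousands of genes
over ~671k spots and ~118k nuclei) require the deposited cohort and are
out of scope here.

## Known limitations

* Laplace posteriors are Gaussian; strongly skewed low-count posteriors
  are approximated, which the Bayes-factor KDE partially absorbs. The
  emcee audit route covers only non-spatial fits.
* Fixed `tau` understates uncertainty about the spatial field's scale;
  `beta` intervals at the default are near-nominal empirically but were
  not derived to be so.
* The MASC quadrature assumes donors nested in batches (true of the
  generator and of per-donor 10x runs); fully crossed designs are not
  supported.
* NNLS deconvolution ignores count noise models and spot heterogeneity;
  it is a stand-in, not a re-implementation of probabilistic
  deconvolution.
* The ZIP family has no extra-Poisson dispersion beyond the optional
  log-normal noise; negative-binomial data would inflate `sigma`.
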