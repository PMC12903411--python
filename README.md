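# senespat

Spatial and single-nucleus analysis of aging and senescence in the human
cortex, as a reusable, synthetic-data-testable Python library.

## Who this is for

Computational biologists who want the bespoke statistical machinery of a
cortical aging study — laminar Bayesian differential expression,
coexpression modules, senescence hallmark positivity, neighborhood
enrichment, composition testing, and the accompanying power analysis —
as importable, unit-tested functions that run end to end on generated
data with planted ground truth, with no cohort download.

## The model at the core

Spot counts follow a hierarchical zero-inflated Poisson (ZIP) spatial
GLM. For spot *s* of one gene,

```
y_s ~ ZIP(λ_s, θ),    log λ_s = β[aar(s), group(s)] + ψ_s + ε_s
```

* **β** — characteristic natural-log counts/spot of the gene in an
  anatomical annotation region (cortical layers L1–L6 or white matter)
  for a donor age group (young <45, middle 45–55, old >55 years), with a
  hierarchical prior β[a,g] ~ N(μ_a, σ_β²), μ_a ~ N(0, 2²);
* **ψ** — spatial autocorrelation with an intrinsic CAR prior on the
  within-array spot adjacency graph;
* **ε** — spot-level noise, integrated out of the likelihood
  (ZIP-lognormal mixture);
* **θ** — per-gene dropout probability, Beta(1,2) prior.

Inference is MAP with a Laplace approximation of the β marginal (an
ensemble-MCMC audit backend covers non-spatial fits). Differential
expression between age groups uses the Savage-Dickey density ratio,
BF = p(Δβ = 0 | prior) / p(Δβ = 0 | posterior), calling a gene at
BF > 3 with |log2FC| > 1 (log2FC = Δβ/ln 2; evidence tiers at 3/10/30).

Around the model: Leiden coexpression modules on the gene–gene Pearson
graph (k = 10, resolution 2, ≥50 genes) with cell-type submodules from
matched nuclei; control-matched hallmark module scores with young-top-5%
positivity thresholds and a "3+ of 7 hallmarks" senescence call;
MASC-style mixed-effects logistic composition tests; pseudobulk DE
against age; marker-based NNLS deconvolution; decile-based permutation
neighborhood enrichment; and the ZIP simulation power study (LOW 0.025 /
MEDIUM 0.6 / HIGH 10 counts/spot). See `docs/methods.md` for the full
account.

## Worked example

```sh
python examples/04_senescence_positivity.py
```

```
young positivity rate: 5.3% (~5% by construction of the young-top-5% threshold)
3+ hallmark oligodendrocytes, young: 3.0%
3+ hallmark oligodendrocytes, middle: 7.2%
3+ hallmark oligodendrocytes, old: 11.2%
The 3+ hallmark rate rises with age, tracking the planted senescent fractions {'young': 0.02, 'middle': 0.06, 'old': 0.12}.

p16+ (CDKN2A>0) oligodendrocyte fraction vs age (24 donors): slope 0.24 %/year, R^2 = 0.63, p = 3.3e-06
```

Nuclei are scored for each hallmark gene list (mean normalized
expression of the list minus bin-matched controls from a fixed
2,000-gene control set); the positivity threshold is the 95th percentile
of young-group scores per broad cell class, so ~5% of young nuclei are
positive by construction. The planted senescent oligodendrocyte
subpopulation (2%/6%/12% of young/middle/old donors) drives the rising
"3+ hallmark" rate and the positive p16+ age slope the script prints.

Other capabilities, one script each, under `examples/`:
simulation + QC filters, spatial DE, coexpression modules,
deconvolution + composition testing, neighborhood enrichment, and the
power study.

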