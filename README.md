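# clipscore

Quantifying where an RNA-binding protein binds, in one cell type, from
cell-type-specific CLIP data. The package implements the analysis framework
used for conditional-tag (cTag) CLIP of FMRP in defined neuronal
populations: CLIP tag counts on coding regions are background-subtracted,
normalized to ribosome-bound transcript abundance (TRAP), and summarized as
a per-transcript **CLIP score**; downstream modules provide a
negative-binomial count-based significance variant, metagene coverage
profiles, knockout-regulation analysis with matched controls, and
cross-cell-type differential binding. A synthetic-data generator with known
ground truth makes every stage testable without any sequencing download.

It is written for computational biologists analyzing CLIP experiments with
paired background libraries and matched abundance measurements
(TRAP/RiboTag or FACS RNA-seq).

## The model

For transcript *i* and replicate *j*, the background-subtracted coding-region
RPKM is

```
RPKM_ij = (CrePos_ij − CreNeg_ij) · 10^9
          ─────────────────────────────────────────────
          CDSLength_i · (TotalCrePos_j − TotalCreNeg_j)
```

with RPKM set to 1 when the background outnumbers the signal or both
libraries are empty. Per replicate, ordinary least squares is fitted to
log₂ CLIP RPKM vs log₂ TRAP RPKM over transcripts with at least one
coding-region tag, and the CLIP score is the residual

```
score_ij = log₂ RPKM_ij − (slope_j · log₂ TRAP_i + intercept_j)
```

i.e. binding relative to similarly expressed transcripts (score 1 ≈ 2-fold
more CLIP signal than expected). Transcripts are classified **stringent**
(score ≥ 2 in every replicate), **high** (mean ≥ 1), **low** (0 ≤ mean < 1)
or **non-target**.

The count-based variant models CLIP CDS counts as NB(μ, α) with
Var = μ + αμ²: μ comes from a per-replicate log-log regression of CLIP on
TRAP CDS counts, α from a mean-dispersion trend α(μ) = a₀/μ + a₁ estimated
across replicates; one-sided tail p-values are combined across replicates
with Fisher's method and converted to FDR by Benjamini–Hochberg.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on the default
synthetic experiment (8000 genes, 3 replicates per cell type, 5% planted
targets with mean 4-fold binding enrichment, two cell types with partially
overlapping targets):

```
$ python analysis/01_simulate.py
simulated 8000 genes, 3 replicates/cell type
planted targets: 400 (A-only 100, B-only 100, shared 200)

$ python analysis/02_score_targets.py
cell A: classes {'non_target': 4495, 'low': 3213, 'high': 174, 'stringent': 118}
  target-vs-background AUC of mean CLIP score: 0.994
  replicate log2-CPM R^2 (pairwise mean): 0.903

$ python analysis/03_nb_significance.py
dispersion trend alpha(mu) = 8.89/mu + 0.0545 (fit on 5826 transcripts)
254 of 7989 transcripts at FDR <= 0.05
Spearman rho between count-based and RPKM-based scores: 0.938 (n=7989)

$ python analysis/05_ko_regulation.py
median LFC by class: {'high': -0.221, 'low': 0.021, 'non_target': -0.0, 'stringent': -0.379}

$ python analysis/06_differential_binding.py
planted A-specific targets recovered as enriched_a: 77.3% of 97
false calls among symmetric transcripts: 0.13%
```

Reading the output: the mean CLIP score ranks truly bound transcripts far
above background (AUC 0.994); the count-based and RPKM-based scores agree
(ρ 0.94, mirroring the agreement seen across normalization variants on real
data); knocking out the protein down-regulates its targets in proportion to
binding (stringent median log₂ fold change −0.38 vs ≈0 for non-targets);
and the moderated cross-cell-type comparison recovers most planted
cell-type-specific targets with almost no false calls.

The same steps are available as a CLI (`clipscore simulate | score |
nb-test | profile | regulation | match-controls | geneset-compare |
diffbind`) operating on TSV/BED files; every run writes a JSON sidecar with
the resolved parameters and input checksums.

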