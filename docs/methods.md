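# Methods

## Scope and coordinates

All computation happens in transcript space: one analysis transcript per
gene, 0-based half-open coordinates (BED-native; GTF's 1-based inclusive
coordinates are converted on read, with CDS intervals projected through the
exon chain, strand-aware). The analysis transcript per gene is the one with
the highest mean WT abundance (RPKM) across replicates, ties broken
lexicographically by transcript id, then filtered for mean RPKM ≥ 1.
A tag counts toward the coding region if its interval overlaps the CDS by
at least 1 nt (the minimum-overlap rule is a package choice; one-nucleotide
overlap is the most permissive reading of "overlapping the coding region").

## CLIP score

Per replicate, background-subtracted CDS RPKM is computed from the
Cre-positive (signal) and Cre-negative (nonspecific background) libraries;
transcripts where background ≥ signal, or with no reads in either library,
receive the sentinel RPKM 1 (log₂ = 0). OLS of log₂ CLIP RPKM on log₂
abundance RPKM is fitted over transcripts with ≥ 1 Cre-positive CDS tag
(sentinel transcripts included by default — whether they belong in the fit
is ambiguous; `include_sentinel=False` excludes them), and the CLIP score
is the residual. Scores are computed for every transcript, tags or not;
transcripts with non-positive abundance get missing scores rather than
invented values, and any missing replicate score forces the non-target
class (flagged).

Classification thresholds: stringent requires score ≥ stringent_min
(default 2) in *every* replicate; high requires mean ≥ high_min (default 1);
low is mean in [0, high_min). The ≥ (rather than >) convention at the
stringent boundary follows the operational description of the method;
both thresholds are configurable and recorded in the run sidecar.

Two controls accompany scoring. Replicate QC computes pairwise Pearson R²
of log₂(CPM + 1) on raw Cre-positive counts (before background
subtraction; the +1 pseudocount stabilizes zeros). The length-bias control
recomputes abundance from reads whose centers fall in a terminal 1-kb
window of each transcript (denominator min(window, length)), so CLIP
scores can be re-derived free of any 3'/5' coverage bias in the abundance
data.

## Count-based variant

CLIP CDS counts (Cre-negative subtracted) are modelled as NB(μ, α),
Var = μ + αμ². Per replicate, μ is exp of an OLS fit of log counts on log
mean WT TRAP CDS counts over transcripts with positive subtracted count,
multiplied by a Duan-type smearing factor Σy/Σŷ over the fit set: the
log-scale fit predicts the conditional median, which underestimates the
mean by ≈ α/2 + 1/(2μ), and the natural-scale recalibration removes that
aggregate bias. Dispersion is estimated without empirical-Bayes
shrinkage: per-transcript method-of-moments α̂ = max(0, (s² − m)/m²) on
size-factor-normalized counts across replicates, then a parametric trend
α(μ) = a₀/μ + a₁ fitted by iteratively reweighted least squares (gamma
weights 1/fit², non-negative coefficients) over transcripts with α̂ > 0;
each transcript's final α is the trend at its mean. One-sided p-values are
the inclusive upper tail P(X ≥ observed) — so p(0) = 1 exactly — with the
Poisson limit at α = 0; negative subtracted observations are tested as 0.
Replicate p-values are combined by Fisher's method (zeros clipped to the
smallest positive float, never dropped) and converted to q-values by BH.

Calibration note: the subtracted counts are a difference of two NB
variables, which NB(μ, α) matches in its first two moments but not in
shape. With a realistic nonspecific background (~10% of signal), null
combined p-values carry a systematic ~2–3% ECDF deviation from uniform —
small enough that the empirical type-I error at 0.05 stays within
[0.04, 0.06], large enough that a KS uniformity test at n = 5000 detects
it for some seeds. This is a property of the subtract-then-model design,
not of the implementation.

## Coverage profiles

Reads are assigned to 5'UTR/CDS/3'UTR by their center, floor((start+end)/2);
densities divide class counts by the class's total length over the
annotation. The meta-transcript profile selects the top-N transcripts by
whole-transcript tag density, keeps reads whose center lies within the
flank of the anchor (offset 0 = first nucleotide of the start codon, or of
the stop codon, i.e. cds_end − 3), weights each read 1/R_t where R_t is
its transcript's kept-read count (so every transcript contributes total
weight 1), bins weights into 10-nt half-open windows registered at the
anchor, and divides each bin by the fraction of selected transcripts whose
structure fully contains that window. Windows no transcript covers are
missing, not zero.

## KO regulation and matched controls

The KO-vs-WT log₂ fold change is a deliberately simple estimator: counts
are scaled by median-of-ratios size factors (factors are defined up to a
global rescaling) and per-pair log₂ ratios with pseudocount 1 are averaged
across replicate pairs. It is antisymmetric under condition swap and
accurate when counts are large; users with externally computed
shrunken-LFC tables can supply them anywhere an LFC vector is accepted.
Class-wise regulation is assessed by two-sided two-sample KS tests of each
class against non-targets and between adjacent classes (exact p for small
groups, asymptotic otherwise; classes under 5 members are skipped).

Matched controls are drawn by stratified sampling: targets are binned into
deciles of log length (and/or log abundance), and one control per target
is drawn without replacement from the pool's same bin, falling back to the
nearest nonempty bin. When abundance matching is on, both sets are first
restricted to a stated RPKM range (default 10–200). Gene-set comparisons
use the two-sided Wilcoxon rank-sum test, exact for tie-free combined
n ≤ 20, normal approximation with tie correction otherwise. The behavioral
discrimination index (displaced − unmoved)/(displaced + unmoved) excludes
animals under 5 s total exploration (configurable).

## Differential binding between cell types

Only transcripts with ≥ 1 Cre-positive tag in every replicate of both cell
types are compared. Replicate CLIP scores are compared with a two-group
moderated t: per-transcript pooled variances (df = n_a + n_b − 2) are
shrunk toward a prior estimated by moment matching on log variances
(digamma/trigamma inversion, the standard scaled-inverse-chi-square
hierarchy), giving s̃² = (d₀s₀² + d·s²)/(d₀ + d) and df d₀ + d; prior df 0
recovers the ordinary pooled t, infinite prior df the common-variance z.
The design is unpaired two-group. Calls require BH-adjusted p ≤ 0.05 *and*
mean CLIP score ≥ 0 in at least one cell type, so transcripts that are
merely "less unbound" are never called.

## Synthetic data generator

The generator emulates the statistical structure of the experiment with a
single seed determining every byte (per-stage RNG streams with stable
spawn keys):

| parameter | default | meaning |
|---|---|---|
| n_genes / n_replicates | 8000 / 3 | transcripts (one per gene), replicates per library |
| length_log_mean, length_log_sd | 7.8, 0.7 | ln-scale transcript length (median ≈ 2.4 kb) |
| cds_fraction_mean | 0.45 | beta-distributed CDS fraction |
| trap_log_mean, trap_log_sd | 1.5, 1.2 | ln-scale abundance RPKM (median ≈ 4.5) |
| depth_clip / depth_trap | 10⁶ / 2·10⁷ | unique CLIP tags / TRAP reads per replicate |
| slope_b | 1.0 | power-law link of CLIP mean to abundance |
| dispersion_alpha | 0.05 | CLIP NB dispersion (replicate log₂-CPM R² ≈ 0.9) |
| trap_dispersion_alpha | 0.005 | TRAP NB dispersion (deep, tightly correlated replicates) |
| background_fraction | 0.10 | Cre-negative mean as a fraction of the binding-free signal mean |
| target_fraction | 0.05 | planted true targets |
| binding_factor_log2_mean/sd/min | 2.0 / 0.8 / 0.25 | log₂ binding enrichment (truncated normal) |
| ko_coupling_gamma, ko_noise_sd | 0.15, 0.05 | KO log₂ down-regulation per unit binding; biological noise |
| shared_target_fraction | 0.5 | targets bound in both cell types |

CLIP counts are NB with mean ∝ s_j · abundance^b · 2^binding · CDS-length,
normalized to the library depth, with log-normal replicate size factors
(sd 0.15); the background library's mean is the binding-free mean times
background_fraction. TRAP counts are NB at full-transcript rates,
binomially thinned to CDS counts; KO means use the WT normalization
constant so the configured KO/WT mean ratio equals 2^lfc exactly per
transcript. A second cell type shares the abundance ground truth but has
its own binding assignment and independently sampled libraries.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: sequence/motif structure, positional
binding within transcripts (counts are placed uniformly when positions are
needed), length- or GC-coupled binding preference, binding-dependent
background, batch effects, and any continuum of weak binding in the
"non-target" pool (non-targets have binding factor exactly 0). The last
point matters for interpretation: with binding exactly zero outside the
planted targets, the low class consists almost entirely of
noise-selected null transcripts, and its fold-change distribution is
dominated by a selection artifact — classification and LFC share the same
WT abundance measurements, so the low class (conditioned on upward score
noise) shows a small *upward* LFC bias rather than the weak down-shift
seen in real data, where low scores reflect genuinely weak binding. The
stringent- and high-class regulation structure is unaffected.

## Numerical choices and degenerate inputs

Log base 2 throughout the scoring path; natural log inside the count
regression (the choice cancels in μ). Ties in principal-transcript
selection and metagene ranking are broken deterministically
(lexicographic / stable sort). Empty CDS annotations are dropped with a
logged count; unknown transcript ids in tag input are skipped with a
warning; a background library at least as deep as the signal library is an
error (the subtracted normalization is undefined). All CLI outputs are
written atomically (temp file + rename) with JSON sidecars carrying
resolved parameters, seed and input checksums; exit codes are 0 (ok),
1 (validation/contract failure), 2 (usage).

Problem sizes in the test suite and acceptance script (8000-gene default
runs, a 5000-gene null calibration, a 200-transcript × 500-read metagene
fixture) were chosen so each stage's statistical claims are testable at
tight tolerances while the whole suite runs in seconds.

## Known limitations

The simplified LFC estimator has no shrinkage, so low-count transcripts
are noisy (mitigated by the pseudocount); the dispersion trend has no
per-gene empirical-Bayes shrinkage, which is adequate for trend-level
testing but weaker than DESeq2 for per-gene dispersion; the moderated t
assumes unpaired groups and a common variance between cell types per
transcript; BAM ingestion is limited to transcript-space intervals, and no
genomic-space or spliced-coordinate analysis is provided.
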