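# Methods

`episcreen` implements the desk-side analysis chain behind an integrative
tumor-suppressor screen in a paired tumor/normal cohort, together with the
diagnostic, prognostic and microscopy read-outs that typically accompany
such a screen. This note documents the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic benchmarks do
and do not demonstrate.

## Differential methylation and expression

Methylation at a CpG probe is summarized as a beta value, the methylated
fraction of signal in [0, 1]. All testing runs on the M-value scale,
M = logit2(beta) = log2(methylated/unmethylated), which stabilizes
variance near the boundaries; betas are clipped to [1e-6, 1 − 1e-6] before
the logit so boundary values stay finite. Gene-level methylation is the
arithmetic mean beta over the gene's probes; probes without a gene symbol
are dropped, and probes with any missing value are excluded before testing
rather than imputed.

Both the methylation and the expression caller use the two-group
Wilcoxon–Mann–Whitney test: exact two-sided p-values when the smaller
group has ≤ 8 samples and the pooled values are tie-free, otherwise the
normal approximation with tie and continuity correction. A row whose
pooled values are all identical carries no ordering information and is
assigned p = 1. This is a deliberate replacement for moderated-t /
NB-GLM machinery (limma, DESeq2): the rank test is distribution-free,
normalization-robust and self-contained, at the cost that per-gene
p-values will not numerically match a shrinkage-based caller on real data.
Multiple testing is controlled by Benjamini–Hochberg throughout.

Effect sizes: expression log2FC = log2((mean_T + c)/(mean_N + c)) on TPM
with pseudocount c = 1e-4 (the same constant used in the log2(FPKM + 1e-4)
display transform); methylation "log2FC" is the difference of group-mean
M-values, which is itself a log2 fold change of methylated/unmethylated
odds.

Significance calls are inclusive: expression p ≤ 0.05 and |log2FC| ≥ 1;
gene-level methylation p ≤ 0.05 and |ΔM| ≥ 0.5. At probe/island level the
fold-change threshold of 1.45 is applied as |ΔM| ≥ log2(1.45); the scale
of that published threshold is ambiguous (beta, M or linear ratio), and
the odds-ratio reading is this package's documented choice.

## The integrative screen

A screen hit is a gene that is simultaneously significantly
hypermethylated (ΔM ≥ 0.5, p ≤ 0.05) and significantly down-expressed
(log2FC ≤ −1, p ≤ 0.05) in tumor versus normal. The down-expression
threshold is read with a negative sign even though summary texts sometimes
print it unsigned — the screen explicitly targets silenced candidate
suppressors, and the hyper/down quadrant is the object of interest.
Hits are intersected across cohorts as plain gene-id sets with Venn
counts. The screen gates on raw p (≤ 0.05), mirroring common published
practice; q-values are reported alongside for the reader. Enrichment of a
hit list against user-supplied GMT gene sets uses the one-sided
hypergeometric upper tail within a stated gene universe, BH-adjusted
across sets; no term database is bundled.

## Diagnostics and survival

ROC curves sweep the unique score values (ties grouped) and integrate by
trapezoid; an independent computation of the tie-corrected Mann–Whitney
probability P(score_pos > score_neg) + ½P(tie) is exposed separately and
agrees to machine precision — the test suite asserts the equivalence on
random instances. The orientation of the marker (whether low values mark
disease) must be stated; `auto` picks the orientation with AUC ≥ 0.5 and
records the choice.

Survival uses the Kaplan–Meier product-limit estimator and the two-group
log-rank test (lifelines supplies chi-square and p). The hazard ratio is
summarized as (O₁/E₁)/(O₂/E₂) from the log-rank observed/expected tallies
rather than a Cox fit — consistent with the online tools this emulates,
and mildly attenuated toward 1 relative to the true HR (the synthetic
benchmark with log-HR 1 typically recovers ≈ 2.4 against e ≈ 2.72).
Best-cutoff dichotomization scans marker quantiles from 10% to 90% in 5%
steps (the grid is configurable; the convention of the popular online
tool is unpublished), drops candidates that empty an arm, and selects the
minimal log-rank p. That minimum is multiplicity-biased by construction;
the result object carries a note saying so, and no correction for cutoff
optimization is applied.

## Microscopy quantification

The lipid-droplet pipeline: (1) nuclei — Gaussian smooth (σ = 2 px), Otsu
threshold, Euclidean distance transform, peak seeds ≥ 10 px apart,
watershed, discard components < 50 px; (2) cytoplasm — the nucleus labels
seed a geodesic Voronoi propagation through the cytoplasm mask, where a
step of length d between pixels differing by ΔI in intensity costs
d·sqrt(λ + ΔI²)/sqrt(λ + ⟨ΔI²⟩) (λ = 1 by default); with uniform
intensity this reduces exactly to the within-mask nearest-seed partition,
which the tests verify against an independent shortest-path oracle;
(3) droplets — white top-hat with a disk of radius 4 px, sigmoidal
contrast (gain 10) centered at the Otsu threshold of the top-hat image,
binarization at 0.5, connected components, discard dots < 2 px or with
centroid outside every cell. Per cell the dot count and summed dot area
are normalized by cytoplasm area; condition summaries average cells
within view field, then across view fields, and report fold change to a
control condition.

Intensity normalization rescales between the 1st and 99th percentiles by
default. For the droplet channel the pipeline rescales between the 1st
percentile and the maximum instead: puncta occupy well under 1% of the
frame, so a 99th-percentile ceiling would clip them to the cytoplasm
level and erase the signal. The pipeline also denoises the droplet
channel (Gaussian σ = 1 px, configurable) before the top-hat; without it,
pixel noise at sd 0.05 fragments and spuriously seeds dots. None of these
pixel-unit defaults comes from a published source; they are calibrated
once to the synthetic scene geometry and are all overridable via
`QuantConfig`.

Stained-area assays (crystal-violet transwell/clonogenic images) reduce to
the foreground pixel fraction after grayscale conversion (luminance for
RGB), normalization, optional inversion for dark stain on light
background, sigmoid at the Otsu midpoint and binarization; view-field
fractions are averaged within replicate, then across replicates.

Conventions: row-major 2-D arrays, 0-based indices, pixel centers at
integer coordinates; label masks use 0 for background and contiguous
labels 1..n; dots are assigned to cells by centroid membership.

## Synthetic data: what it emulates and what it does not

The cohort generator emulates a discovery cohort of 31 tumor and 12
normal samples over 2 000 genes (3–8 CpG probes each). Counts are
negative binomial with gene-specific log2 mean uniform on [3, 9] and
dispersion 0.2 — typical bulk RNA-seq overdispersion; betas are drawn
from a Beta distribution re-parameterized by (mean, precision = 30), with
per-gene baseline means from a bimodal low/high mixture as real
methylomes show. Planted suppressor genes shift the tumor beta mean by
+0.25 and the expression mean by 2⁻² (log2FC = −2); planted baseline
means are kept low enough that the shift never clips, so the realized
mean difference is unbiased. Neither the effect sizes nor the noise
levels come from a published table — they are one-time calibration
choices for a clearly-detectable-but-not-trivial regime. The generator
can pin the planted gene identities so that two cohorts share the same
underlying suppressors, which is what a two-cohort validation design
assumes.

Survival records follow an exponential proportional-hazards model
h(t|x) = h₀·exp(β·x) with h₀ = 0.02/month, independent exponential
censoring at a rate chosen to give the stated censoring fraction under
the baseline hazard. Scenes render cells, nuclei and droplets as
anti-aliased disks (1-px rim ramp) with additive Gaussian noise.

What passing these benchmarks shows: the estimators are correctly
implemented (oracle equivalences), calibrated under the null (rejection
rates at nominal α within ±0.02), and able to recover planted effects of
the stated size. What it does not show: behavior under batch effects,
tumor purity/copy-number confounding, probe cross-reactivity, uneven
illumination, out-of-focus microscopy or cell clumping — none of which
the generators model.

## Problem sizes and determinism

Default benchmark sizes: 2 000-gene cohorts (≈ 11 000 probes), 1 000 null
survival replicates of 60 patients, 512×512 scenes with 8 cells, 256×256
stained images. Everything is driven by a single master seed; each
generator derives an independent substream by a fixed offset, and
identical spec + seed reproduces outputs bit for bit. The analysis
pipeline itself contains no randomness: rerunning a report from the same
config and inputs is byte-identical.

## Known limitations

- Rank tests discard pairing information even when patient ids pair
  tumor/normal samples; a signed-rank paired mode is not implemented.
- The O/E hazard ratio is attenuated for strong effects; a Cox model
  would be the next step if effect estimation (rather than testing) were
  the goal.
- The best-cutoff minimum p is reported uncorrected (flagged in the
  output); permutation correction is out of scope.
- TPM composition effects slightly bias log2FC estimates when many genes
  change in one direction; with ≤ 2% of genes planted this is negligible.
- The imaging pipeline is 2-D only and assumes roughly convex,
  non-overlapping cells.
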