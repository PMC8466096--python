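# Methods

## Analysis model

All methylation statistics operate on β-values (methylated / total signal,
in [0, 1]) of 450K-style array probes. The chain is a sequence of filters,
each with an explicit contract:

**Twin-contrast filter.** With proband-at-diagnosis S1, healthy twin S2 and
proband-at-remission S3, a probe is retained iff

    |β_S1 − β_S2| ≥ δ_min,  |β_S1 − β_S3| ≥ δ_min,  |β_S2 − β_S3| ≤ δ_healthy

with defaults δ_min = 0.30 (inclusive) and δ_healthy = 0.10 (inclusive).
Deltas are signed proband-minus-healthy. A direction label (hyper/hypo)
requires the two proband contrasts to agree in sign; probes passing in
magnitude with opposite signs are retained but labelled `discordant` and
carry no direction — the three inequalities alone do not force a sign, and
only directed probes can match a replication direction. Probes missing in
any of the three samples are excluded and counted rather than imputed: three
samples give no basis for imputation.

**Replication.** Per probe, paired differences d_i = β_diag − β_rem over the
patient pairs; t = d̄/(s_d/√n), df = n − 1, two-sided p from Student's t.
Replication requires |d̄| > 0.30 — strictly greater, versus the inclusive
≥ 0.30 of the twin filter, matching the respective inequality conventions —
and direction agreement with the twin filter. No p-value cutoff is applied
by default (the replication criterion is the effect size); an optional
`rep_alpha` restores one. The degenerate case s_d = 0 with d̄ ≠ 0 is treated
as maximally significant (p := 0, flagged), since the effect criterion, not
p, is decisive; "zero" is assessed at a 1e-12 float tolerance because the
mean of identical float differences need not be bit-exact. The paired test
is computed on all probes and then intersected with the twin set — the
result is identical to testing only the twin survivors, and the full table
is more useful for reporting.

**Annotation.** The Illumina-dialect manifest carries parallel
semicolon-joined gene and region lists; a probe can hit several genes.
Promoter := TSS1500 ∪ TSS200. "Gene regions" is reported both as distinct
gene symbols and as distinct (gene, region) pairs, because the phrase is
ambiguous; downstream logic uses gene symbols (case-sensitive exact match to
the count matrix).

**Differential expression.** Median-of-ratios size factors (genes containing
any zero are excluded from the geometric means), normalization
log2(count/factor + 1), then a paired t-test on diagnosis−remission
differences of normalized values with BH FDR < 0.05. This is a deliberately
transparent paired test rather than a count-model fit; the stage is
pluggable, and an external DE table (gene, log2fc, p_fdr) is used verbatim
when supplied. Note the identifiability of size factors: scaling one sample
scales the *ratios* of factors, not a single factor in isolation, because
the per-gene geometric mean absorbs m-th roots of the scale.

**Correlation signature.** For each replicated CpG annotated to a DE gene,
Pearson ρ between β and normalized log2 expression over the samples with
both assays (six samples from three pairs by default; a probe annotated to
k DE genes contributes k records). Two-sided p via t = ρ√((n−2)/(1−ρ²)),
df = n − 2; zero-variance vectors are flagged degenerate and excluded from
testing. P_corr is BH across **all** tested candidate pairs — the correction
family is not dictated by the design, and a single family across candidates
is the conservative, reproducible choice. A gene enters the signature when
it is DE-significant and carries ≥ 3 CpGs passing both |ρ| ≥ 0.7 and
P_corr ≤ 0.05; with n = 6, |ρ| ≥ 0.7 alone does not imply a small p, so both
criteria apply (each individually toggleable). The gene's correlation sign
is −/+ when all passing ρ share that sign, `mixed` otherwise.

**Structural QC.** Euclidean distances are computed over probes non-missing
in both samples and rescaled by √(P/P_shared) to stay comparable under
missingness. Agglomerative clustering uses complete linkage by default
(deterministic and standard for distance heatmaps; average and Ward are
options), cut at two clusters and scored by majority-label purity. The
targeted PCA runs on β-values directly (the analysis works on β throughout;
an M-value transform log2(β/(1−β)) with β clipped to [0.001, 0.999] is
offered), per-probe centered, unscaled; component signs are fixed by making
the largest-magnitude loading positive, so output is fully deterministic.
The parental check flags a signature CpG as comparable when every parent is
within 0.10 of the healthy-reference mean — 0.10 chosen to match the
healthy-concordance threshold of the twin filter, since no separate numeric
criterion exists for this check.

## Synthetic data generator

The generator emulates the study design, not a particular dataset: a twin
trio plus parents, `n_pairs` diagnosis–remission pairs with methylation and
expression, one extra pair with expression only (correlation uses only the
pairs with both assays), and ≥ 3 reference profiles each of CD34+ and CD19+
cells.

*Methylation.* Healthy per-probe baselines follow a bimodal low/high mixture
as on real arrays; observed β is Beta-distributed with mean = baseline (+
planted shift) and precision φ = 200 by default, i.e. technical SD ≈
0.02–0.04 — typical of array replicates — and values are clipped to
[0.001, 0.999]. Beta noise (not Gaussian) respects the [0, 1] support; the
(mean, precision) parameterization keeps the two knobs interpretable.
Planted disease CpGs shift by ±0.45 in diagnosis samples only; direction is
drawn per signature gene (a promoter's CpGs move together; 85.5% hyper by
default), and per probe for the 500 additional disease CpGs not tied to
expression (real replicated sets are far larger than the expression-linked
signature; these also let the disease signal dominate the structural QC, as
it does in practice).

*Cell composition.* Confounding is modelled as a probe-level offset
(|offset| ~ U(0.20, 0.30), random sign) shared by all blast-rich samples —
every diagnosis sample and, scaled by a per-probe factor, the reference
cells — rather than an explicit cell-mixture deconvolution: the analysis
itself handles composition only through reference-cell QC, so the generator
plants exactly the artifact that machinery must reveal. Offsets sit mostly
below the 0.30 disease threshold: composition probes pass the twin filter
far more often than null probes (noise pushes them over), yet are annotated
to dedicated host genes that are never differentially expressed, so the
correlation stage removes them — the specificity mechanism the design relies
on.

*Expression.* Counts are negative binomial (dispersion 0.05) around log2
means spanning ~3 orders of magnitude, with per-sample depth factors.
Signature-gene expression follows the realized mean promoter β through a
linear link with slope ±|log2FC|/Δβ (negative correlation sign by default;
a configurable fraction of genes, 10%, get a positive link — the analogue of
positively correlated exceptions seen in practice), so diagnosis−remission
log2FC equals ±6 in expectation. Expression noise is split into a
subject-level component (shared by both samples of a pair) plus a residual;
the subject-level SD is calibrated from

    rho_target = 1 / sqrt((1 + q_x)(1 + q_y)),

where q_x, q_y are the noise-to-signal variance ratios of β and expression,
so realized per-CpG |ρ| over the six DNA+RNA samples meets the 0.9 target in
expectation while paired fold-change estimates stay sharp (subject effects
cancel in within-pair differences — which is also how real patient
heterogeneity behaves). Background DE genes (150, |log2FC| ~ U(1.5, 8),
methylation-independent) give the DE stage positives outside the signature.

*Truth.* All planted labels are emitted to `truth.json`, so recovery tests
never re-derive truth from simulation internals; with a fixed seed the whole
dataset is bit-reproducible, and write → read round-trips exactly through
the plain-text formats.

What the generator does **not** emulate: probe-level intensity artifacts
(no IDAT model), SNP/cross-reactive probe masks, array QC attrition from
485k to a working panel, genomic autocorrelation of methylation, and
realistic library-size or GC effects in RNA counts. Passing tests therefore
demonstrate correctness of the analysis logic under the stated statistical
structure, not robustness to every real-data artifact.

## Null runs

A null configuration zeroes the planted structure
(`n_signature_genes=0, n_background_de_genes=0, n_extra_dm_probes=0`) rather
than lowering the planted Δβ below 0.30, which the configuration contract
rejects as unable to pass the filter by construction. Under the null the DE
stage reports essentially no genes at FDR < 0.05 and the pipeline reports
zero signature genes.

## Problem sizes

The default study conditions are 20,000 probes, 2,000 genes, 30 signature
genes × 4 CpGs, 3 DNA+RNA pairs + 1 expression-only pair; the test suite
additionally uses a structurally identical reduced study (2,000 probes,
400 genes, 10 signature genes) where full size adds nothing to the property
being checked. Recovery statistics are averaged over five seeds;
`scripts/acceptance.py` reports them together with single-run stage counts
and a 10-seed null calibration.

## Known limitations

- With only three methylation pairs, the paired t-test has df = 2; the
  replication criterion is therefore effect-size-driven by design, and the
  optional p-value cutoff is conservative.
- With six correlation samples, ρ estimates are coarse; genes whose
  subject-level expression noise draws are unlucky can fall just short of
  the |ρ| ≥ 0.7 / P_corr ≤ 0.05 pair of criteria, which is why planted-truth
  sensitivity is ~0.93, not 1.0, at the default noise.
- The per-gene direction model means a signature gene's CpGs never disagree
  in planted direction; real promoters can be internally heterogeneous.
- `n_pairs ≥ 2` is required (the paired test needs two differences); the
  study default is 3.
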