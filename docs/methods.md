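# Methods

This note documents the models and procedures implemented in `rtmis`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Assay model and read processing

The assay captures each target transcript with a pair of half-probes
hybridised across an exon–exon junction; ligation joins them into a single
amplifiable product, and a random 7-nt UMI embedded in the probe tags the
captured molecule. A read therefore consists of a UMI followed by the
ligated insert. The default `ReadLayout` places the UMI at offset 0
(length 7) and the insert immediately after; adapters are assumed trimmed
by the sequencer, and all offsets are configurable for other layouts.

**Probe matching.** A read is assigned to the probe pair whose left half
best matches at the insert position *and* whose right half best matches
immediately after, each within `max_mismatches` (default 2) Hamming
mismatches — no indels, since ligation products have fixed length and
indel reads are rare and better discarded. If the two halves best-match
*different* probe pairs the read is a chimeric ligation artefact and is
counted as such; if either half has a tied best match the read is
discarded as unassignable (an ambiguous read must never inflate a count).
Two mismatches per ~25-nt half is conservative: the packaged panel's
ligation products are mutually separated by edit distance ≥ 8, so a read
would need ≥ 4 errors concentrated in one insert to be misassigned. Base
qualities are ignored; the Hamming threshold already absorbs sequencing
error at the rates targeted panels run at (≲ 1%/base).

**UMI deduplication.** The molecule count for (sample, marker) is the
number of distinct UMIs observed. Two collapse rules are offered:
`exact` (default) counts distinct 7-mers; `hamming1` additionally merges
a UMI into a neighbour at Hamming distance 1 whose read count is at least
`2·count − 1` (the directional-network rule), absorbing single sequencing
errors in the UMI itself. Exact is the default because PCR-duplicate
removal is the purpose of the UMI and the directional rule only matters at
high per-molecule duplication. UMIs containing non-ACGT characters are
dropped and counted under `below_quality`.

**Reportability.** A sample is interpretable only when ≥ 5000
deduplicated molecules are detected, summed over all markers. The sum
over markers (rather than distinct UMI sequences globally) is used: with
a 4^7 = 16 384-sequence UMI space, global distinctness would saturate
near the threshold and stop tracking molecule number. At the 5000-molecule
floor the panel's per-marker mean counts sit in the 1–40 range.

**Conservation.** For every sample,
`reads_in = assigned + no_match + chimeric + below_quality`, and counts
are invariant to read order and to read duplication.

## Quantification

Counts are converted to `log2(1 + 10^4 · count / total)` per sample,
where the total runs over expression probes only (mutation/virus probes
are excluded from both numerator and denominator). The pre-log relative
abundances therefore sum to 1 per sample and the transform is exactly
invariant to sequencing depth — necessary because the reportability floor
still admits roughly a tenfold depth spread between samples. The 10^4
scale puts typical markers in a convenient 0–14 log2 range. No
housekeeping normalisation or batch correction is attempted.

Genes covered by two probe pairs (AICDA, BCL6, MYC, BCL2) are reported as
the arithmetic mean of the two pair values on the log scale; the mean is
symmetric and predictable, and no probe-dropping rule is applied.
Non-interpretable samples are excluded from normalisation with a warning
(optionally retained for simulation work).

Mutation/virus loci are paired variant/reference probes sharing a locus
name. The variant fraction is `variant / (variant + reference)` UMIs; a
call is positive at fraction ≥ 0.1 with depth ≥ 20 molecules. Both
thresholds are exposed in configuration; the defaults balance sensitivity
against UMI-level noise at the depths the panel reaches and are not tuned
to any dataset.

## Subtype classifier

The predictor is a random forest over the 137 gene-level normalised
expression values with seven classes in the fixed order ABC, GCB, PMBL,
FL, MCL, SLL, MZL (MALT and LPL relabel to MZL on load). Forest
hyperparameters: Gini split criterion, `max_depth=20`,
`min_samples_split=4`, 5000 trees by default, with library defaults for
the rest (√p candidate features per split, bootstrap resampling). A seed
is part of `ForestConfig` and is stored in the model file together with
the feature list, label order and a panel checksum, so a saved model
reproduces its predictions bit-for-bit after reload.

Class probabilities are reported as the fraction of trees voting for each
class (each tree votes for its leaf-majority class); the call is the
argmax, with ties broken by the canonical label order. An optional
"unclassified" band (maximum probability < 0.4) exists but is off by
default — the intended use forces a call on every sample.

Cohort splitting is stratified by label at a configurable training
fraction (default 2/3) and reproducible under its seed. Stratification is
a deliberate choice: it keeps rare classes (SLL at a dozen cases)
represented on both sides of the split.

Tests reduce the forest to 300–500 trees; vote-fraction accuracy is
already stable there, and the full 5000-tree configuration is used by the
acceptance script's classifier run.

## Exploratory statistics

Two-group differential expression uses Welch's unequal-variance t-test on
log-scale values (log-scale testing matches how the expression values are
stored and damps the mean–variance relation of count data), with
Benjamini–Hochberg adjustment across tested genes. Fold changes are
computed on de-logged molecules-per-10k with a pseudo-count of 0.5 so
genes absent in one group remain finite. A gene is significant when
|log2 FC| > 1 and FDR < 0.05. Genes whose test is undefined (zero
variance in both groups) are flagged untested rather than erroring.

PCA standardises each gene to zero mean and unit variance (constant genes
are centred only), then takes the top two components. Loadings are scaled
by the component singular values; each component's sign is fixed so its
largest-|loading| gene is positive, making maps deterministic. The "most
discriminatory markers" of a map are the 40 genes with the largest
Euclidean loading norm over components 1–2.

Wilcoxon rank-sum comparisons use the exact null distribution when both
groups have ≤ 25 tie-free observations and the tie-corrected normal
approximation otherwise.

## Survival analyses

Records are right-censored administratively at 60 months (a capped record
loses its event flag). Kaplan–Meier estimates carry exponential-Greenwood
(log(−log)) 95% intervals clipped to [0, 1]; group differences use the
two-sided log-rank test; multivariable models are Cox proportional-hazards
fits with Efron tie handling and Wald intervals, warning when there are
fewer than 10 events per covariate.

Expression dichotomisation thresholds are scanned over the gene's
quantiles 0.10–0.90 in steps of 0.05 — a bounded, reproducible grid that
avoids tiny strata — keeping the split with the smallest log-rank p
(ties resolve to the lowest quantile). The scan is explicitly
exploratory: the minimum over 17 correlated tests is not corrected, and
the full p-vector is returned so users can correct if they need an
honest p. Scans default to overall survival; the endpoint is the caller's
choice of records. The double-expressor flag is the conjunction
MYC > threshold AND BCL2 > threshold, computed on normalised expression
(the scale the rest of the package reports).

## Synthetic-data generator

The generator exists because no patient-level data are distributable; its
defaults define the study conditions the tests and the acceptance script
run under.

Each subtype has a hand-authored tumour template over the 137 markers:
a B-cell/immunoglobulin baseline modulated by the qualitative signatures
the panel targets — germinal-centre programme for GCB and FL (FL adding
the I-epsilon sterile transcript and BCL2), activated-B programme with
IGHM and AICDA high but the I-mu sterile transcript low for ABC,
PDL1/PDL2/JAK2/CD30/CD23 for PMBL, CCND1/CD5/IGHD for MCL,
CD5/CD23/CD27 for SLL, plasmacytic CD138 with triple-negative surface
markers for MZL. A sample draws a tumour fraction uniformly from a
subtype-specific range (0.3–0.6 for FL, up to 0.5–0.9 for DLBCL), mixes
the template with microenvironment components (T cell, Tfh, macrophage,
cytotoxic) at subtype-dependent weights, perturbs each marker by
lognormal(0, `noise_scale`) noise (default σ = 1.0), renormalises, and
draws molecule counts multinomially at a lognormal depth (median 20 000,
σ = 0.35 — comfortably above the 5000 floor with realistic spread).

Read simulation inverts the parser: each molecule gets a distinct UMI and
Geometric(1/4) ≥ 1 PCR-duplicate reads (mean 4; UMI counts must be
invariant to this multiplicity, which is the property under test),
uniform substitution errors (default 0.5%/base), and chimeric reads —
left half of one probe ligated to the right half of another with a fresh
UMI — injected at 1% by default. At zero error and chimera rate,
`count_fastq ∘ simulate_fastq` is the identity on count vectors.

Survival simulation draws exponential event times whose hazard is
multiplied by a per-covariate ratio (default double-expressor HR 2.0, the
magnitude reported for dual MYC/BCL2 expression in DLBCL), with
independent exponential censoring (default rate 0.006/month, ≈ 20–25%
censored before the 60-month cap).

What the generator does **not** emulate: FFPE RNA degradation and
GC/length bias, probe-specific capture efficiencies, batch and run
effects, correlated marker noise within pathways, index hopping, and
borderline or mixed-histology cases. Passing tests therefore demonstrate
the correctness and calibration of the computational stack under the
assay's idealised statistical model, not clinical performance on real
biopsies.

## Numerical and scale choices

* Problem sizes in tests and the acceptance script: cohorts of 40
  samples/class (280 total), forests of 300–5000 trees, one ≥10 000-read
  FASTQ round-trip per seed, 100 threshold-scan replicates at n=200, and
  20 Cox replicates at n=500. These sizes make every stochastic check
  well-resolved while keeping a full run in minutes on one CPU.
* The classifier noise ladder (σ = 1.0, 2.5, 4.0) spans the regimes from
  cleanly separable to heavily scrambled so the monotone-degradation
  property is resolvable.
* Seeds are explicit everywhere (`SimConfig.seed`, `ForestConfig.seed`,
  split seeds); derived seeds stay below 2^31.
* Degenerate inputs error loudly: empty panels, ambiguous ligation
  products, all-non-interpretable cohorts, constant expression in a
  threshold scan, constant Cox covariates, cohorts with a single class.

## Known limitations

* Indel-tolerant alignment is out of scope; a probe with a common indel
  polymorphism would undercount.
* The packaged probe sequences are placeholders; real assay runs must
  supply the true panel TSV.
* The 137-marker counting convention (distinct expression genes;
  dual probe pairs collapse; mutation/virus loci excluded) is this
  package's own, documented here because the assay's public description
  does not break the arithmetic down.
* The threshold scan's chosen cutpoint is unstable when no true effect
  exists; downstream use should treat it as hypothesis generation.
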