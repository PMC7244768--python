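# rtmis

Analysis toolkit for targeted gene-expression profiling of B-cell
non-Hodgkin lymphoma (B-NHL) by ligation-dependent RT-PCR sequencing
(RT-MLPA read out on a short-read sequencer).

The assay hybridises pairs of half-probes across exon junctions of a
137-marker panel on cDNA, ligates and amplifies them, and sequences the
products. Each read carries a 7-nt unique molecular identifier (UMI), so
PCR duplicates collapse to single molecules. The package takes the
analysis from demultiplexed FASTQ files to:

* a UMI-deduplicated samples × markers molecule-count matrix with QC
  (a run is reportable only when ≥ 5000 molecules are detected),
* normalised expression (log2 molecules-per-10k), dual-probe aggregation,
  and variant-fraction calls for mutation/virus-status probes,
* a 7-class random-forest subtype predictor — ABC DLBCL, GCB DLBCL, PMBL,
  FL, MCL, SLL and a merged MZL category — with per-class probabilities,
* differential-expression statistics (Welch volcano with
  Benjamini–Hochberg FDR, PCA maps, Wilcoxon rank-sum comparisons), and
* survival analyses (Kaplan–Meier, log-rank, expression-threshold scans
  for MYC/BCL2, double-expressor calling, multivariable Cox models).

It is aimed at molecular-diagnostics and hemato-oncology bioinformaticians
who run targeted expression panels and want a reproducible, scriptable
pipeline from reads to subtype calls and outcome analyses.

Because the underlying patient cohorts are not public, the package ships a
first-class synthetic-data generator (`rtmis.simdata`) that emulates the
assay's statistical structure — subtype expression templates, tumour /
microenvironment mixing, molecular sampling, PCR duplication, sequencing
errors and chimeric ligation artefacts — so the entire stack is testable
end to end. The packaged panel carries the marker names and groups with
synthetic placeholder probe sequences (the real sequences are
proprietary), mutually separated by edit distance ≥ 8.

## Model summary

Reads are assigned by Hamming matching of both half-probes (≤ 2
mismatches per half, ties discarded, discordant halves flagged chimeric);
molecule counts are distinct UMIs per sample and marker, optionally with
directional Hamming-1 UMI collapse. Expression is

    x[s, g] = log2(1 + 10^4 · c[s, g] / Σ_g c[s, g])

which is invariant to sequencing depth. The classifier is a random forest
(Gini criterion, `max_depth=20`, `min_samples_split=4`, 5000 trees by
default) over the 137 gene-level expression values; class probabilities
are tree-vote fractions and the call is the argmax. Survival uses the
Kaplan–Meier product-limit estimator with exponential-Greenwood 95% CIs,
the two-sided log-rank test, and Cox proportional-hazards fits with Efron
tie handling; follow-up is right-censored at 60 months.

## Worked example

Simulate a labelled cohort at the default study conditions (7 subtypes,
40 samples per class), split two-thirds / one-third, train, and evaluate
on the held-out third:

```python
from rtmis import classifier as clf, simdata
from rtmis.panel import default_panel

panel = default_panel()
sim = simdata.simulate_cohort(simdata.SimConfig(n_per_class=40, seed=7))
cohort = clf.split_cohort(sim.to_labeled_cohort(panel), seed=7)
model = clf.train(cohort, clf.ForestConfig(n_trees=500, seed=7))
validation = cohort.subset(clf.VALIDATION)
report = clf.evaluate(clf.predict(model, validation.expr),
                      validation.labels)
print(report.summary())
```

Output:

```
samples: 94
accuracy: 94/94 (100.0%)
per-class accuracy:
  ABC   13/13 (100.0%)
  GCB   13/13 (100.0%)
  PMBL  13/13 (100.0%)
  FL    14/14 (100.0%)
  MCL   14/14 (100.0%)
  SLL   13/13 (100.0%)
  MZL   14/14 (100.0%)
confusion matrix (rows = expected):
predicted  ABC  GCB  PMBL  FL  MCL  SLL  MZL
expected
ABC         13    0     0   0    0    0    0
GCB          0   13     0   0    0    0    0
PMBL         0    0    13   0    0    0    0
FL           0    0     0  14    0    0    0
MCL          0    0     0   0   14    0    0
SLL          0    0     0   0    0   13    0
MZL          0    0     0   0    0    0   14
```

The 94 held-out samples are all called correctly: at the generator's
default noise the seven subtype templates are well separated, which is
the regime the assay is designed for. Accuracy degrades monotonically as
the generator's marker-noise scale rises (see `tests/test_acceptance.py`).

The same pipeline is available from the shell:

```
rtmis simulate --out-dir sim --n-per-class 40 --seed 7
rtmis count --samples samples.csv --out counts.tsv --qc-out qc.tsv
rtmis normalize --counts counts.tsv --qc qc.tsv --out expression.tsv
rtmis train --expr expression.tsv --labels labels.csv --out model.joblib
rtmis predict --model model.joblib --expr expression.tsv --out calls.tsv
rtmis survival --expr expression.tsv --clinical clinical.csv --out report.json
```

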