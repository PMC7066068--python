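# scmrmr

Biomarker panel discovery for labelled single-cell expression data:
mutual-information-based **mRMR** gene ranking, **incremental feature
selection** (IFS) with a cross-validated SVM, **MCC-optimal** panel
selection, and hypergeometric overlap testing against reference gene
signatures.

The package is aimed at the tumor-core vs periphery classification setting:
a genes × cells count matrix, a binary per-cell tissue label, strong class
imbalance, sparse counts with dropout zeros, and families of mutually
redundant genes among the markers. It ships a ground-truth synthetic
generator so the whole pipeline is testable end to end without any data
download.

## The method

Genes are discretized (3-level mean ± α·sd by default) and ranked greedily
by the minimum-redundancy maximum-relevance difference criterion: at each
step the candidate gene *g* maximizing

```
I(g, t)  -  (1/m) Σ_{gᵢ ∈ selected} I(g, gᵢ)
```

is appended to the list *S*, where *I* is plug-in mutual information (nats),
*t* is the tissue label and *m* the number of genes already selected (the
redundancy term is 0 for the first pick). A redundant copy of a selected
gene is penalized by their shared information and falls behind weaker but
independent markers.

The IFS stage then evaluates every nested prefix S₁ ⊂ S₂ ⊂ … ⊂ S_K with a
cross-validated SVM (RBF kernel, cost 1, γ = 1/n_features, features
standardized on the training fold; leave-one-out CV by default) and scores
each prefix by the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

which remains informative under class imbalance. The biomarker panel is the
smallest prefix attaining the maximal MCC. Panels can finally be compared
with published signatures via an exact (integer-summation) upper-tail
hypergeometric test over an explicit gene universe.

## Worked example

Simulate a 500-gene, 320-cell two-class experiment (20 informative genes at
4-fold change, five redundant triplet groups, 30 % dropout), rank, select,
and test the panel against a reference set:

```bash
scmrmr simulate --out-prefix syn --seed 20200305
scmrmr rank --matrix syn.matrix.tsv --labels syn.labels.tsv --n-select 40 --out ranked.tsv
scmrmr ifs  --matrix syn.matrix.tsv --labels syn.labels.tsv --ranked ranked.tsv --k-max 40 --plot ifs.png
scmrmr overlap --panel panel.tsv --gmt sets.gmt --universe 500
```

prints

```
wrote syn.matrix.tsv (500 genes x 320 cells)
wrote ranked.tsv (40 genes ranked of 500)
peak MCC 0.9403 at k=33; wrote ifs_curve.tsv, panel.tsv
wrote overlap.tsv (1 sets tested)
```

and the ranking starts

```
rank  gene_id  relevance     redundancy     mrmr_score
1     INF0011  0.1270234179  0              0.1270234179
2     INF0010  0.1262159621  0.02752466647  0.09869129562
```

Reading: the rank-1 gene carries 0.127 nats of information about the tissue
label; the rank-2 gene loses 0.028 nats to redundancy with it. The LOOCV
IFS curve peaks at MCC 0.940 with a 33-gene panel — every panel member is a
planted signal gene — and a 10-gene reference set fully contained in the
panel yields an overlap p-value of 3.8 × 10⁻¹³ in the 500-gene universe.

A single `scmrmr run --seed 5` executes the same chain from one YAML config
into a run directory (ranked list, IFS curve + plot, panel, metrics,
overlap report, log), with every output header recording version, seed and
config.

## Layout

| module | role |
|---|---|
| `scmrmr.io` | dense TSV/CSV and Matrix Market matrices, labels, ranked-list/panel TSVs |
| `scmrmr.information` | discretization and plug-in mutual information |
| `scmrmr.mrmr` | greedy mRMR ranking, relevance scores, pairwise MI cache |
| `scmrmr.classify` | cross-validated SVM, confusion matrix, MCC/sensitivity/specificity/accuracy |
| `scmrmr.ifs` | IFS curve, peak selection, biomarker panel |
| `scmrmr.enrichment` | exact hypergeometric overlap test, GMT parsing |
| `scmrmr.simulate` | negative-binomial + dropout generator with ground truth |
| `scmrmr.pipeline` / `scmrmr.cli` | configured, logged, seeded orchestration |

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
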