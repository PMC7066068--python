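# Methods

## Problem setting

Given a genes × cells expression matrix and a binary per-cell tissue label
(positive = tumor core, negative = periphery), the pipeline produces a
small, non-redundant gene panel that separates the two classes, together
with an estimate of its cross-validated classification quality. The
reference design it targets has a few thousand cells at roughly 2:1 class
imbalance and ~10⁴ genes of which only a minority are class-informative,
often in groups of mutually redundant markers.

## Discretization

Mutual information is estimated on discretized expression. The default is
the classical three-level scheme: values below mean − α·sd map to bin 0,
above mean + α·sd to bin 2, the rest to bin 1, with α = 0.5 and the sample
(n−1) standard deviation. A constant gene maps entirely to the middle bin
and therefore has zero mutual information with everything. An
`equal_frequency` scheme (any number of bins, ties resolved by value order
then index) is available for heavy-tailed data. Binary labels are already
categorical and bypass discretization.

Expression values may be raw counts or pre-transformed reals; the pipeline
applies log1p before discretization and classification by default
(`log1p: true` in the config, recorded in every output header). The
transform changes the mean/sd cutpoints, not the ordering of values, and
stabilizes the SVM's feature scales.

## Mutual information

The estimator is the plug-in formula on the empirical joint distribution of
bin indices, Σ p(a,b)·ln[p(a,b)/(p(a)p(b))] with 0·ln 0 := 0, reported in
nats. The log base rescales every score equally, so rankings are invariant
to it. No bias correction (e.g. Miller–Madow) and no continuous (kNN)
estimator is provided; at the cell counts this pipeline targets the
plug-in bias is shared by relevance and redundancy terms and does not
affect the greedy ordering materially. The implementation is a vectorized
bincount over joint codes; the test suite pins it to an explicit
triple-loop summation at 1e-12 and to `sklearn.metrics.mutual_info_score`.

## mRMR ranking

The difference ("MID") criterion is used exactly as written above — not the
quotient variant. The first pick has redundancy 0 by convention (the mean
over an empty selected set is undefined). The recorded redundancy of each
entry is the mean-MI term at the moment of its selection, so
`mrmr_score = relevance − redundancy` holds row by row.

Ties at a greedy step are resolved by higher relevance, then lexicographic
gene id. Scores and relevances are compared after rounding to 12 decimals:
two scores that are mathematically equal can differ by ~1e-16 depending on
summation order, and without rounding such pseudo-ties would make the
ranking depend on the evaluation order of terms. 1e-12 is far above
float-summation noise and far below any meaningful score gap at realistic
cell counts.

Pairwise MI is computed lazily against selected genes only
(O(n_select · n_genes) evaluations); a full gene × gene table is never
materialized. An optional pre-filter drops genes expressed in fewer than a
configured number of cells before ranking (off by default).

## Classification and metrics

The margin classifier mirrors the default configuration of the classical
SVM distributions: RBF kernel, cost 1, kernel width 1/n_features, features
standardized with training-fold statistics only (scikit-learn
`StandardScaler` + `SVC` in a `Pipeline`). No class weighting is applied
despite the imbalance; imbalance is addressed in the selection metric
(MCC), not by reweighting. All four choices are config-exposed.

Leave-one-out CV predicts every cell exactly once with a model that never
saw it. Seeded stratified k-fold (default k = 5) is offered as a scalable
stand-in for large matrices; the CV scheme is stored in the IFS curve so a
report never mixes schemes. MCC is computed with exact integer arithmetic
in the numerator and under the root, and is defined as 0 whenever a
marginal factor vanishes. Sensitivity, specificity and accuracy raise on
empty margins rather than returning a silent 0/0.

A caveat the test suite documents: under LOOCV with permuted, balanced
labels the held-out cell's class is always the training minority, which
biases chance-level accuracy below the majority rate. Permutation controls
therefore compare against an empirical permutation band, not against a
nominal 50 %.

## IFS and panel selection

The IFS curve evaluates the nested prefixes S₁..S_K independently — no
state is carried between prefixes, so no information leaks. The panel is
the smallest k attaining the maximal MCC (parsimony tie-break). Appending
points below the current maximum never changes the selection. The curve can
be plotted (k vs MCC) to an image; plotting failure never fails a run.

## Hypergeometric overlap

The overlap test computes the exact upper tail P(X ≥ k) for X
hypergeometric(universe, |reference|, |panel|) by integer
binomial-coefficient summation with a single final division — no normal
approximation, and exact agreement with exhaustive enumeration at any size
where enumeration is feasible. The universe size is a required explicit
parameter (the pipeline defaults it to the number of genes in the loaded
matrix) because overlap p-values are not interpretable without it. Gene
identifiers are upper-cased before matching; aliases are not resolved.
Optional Bonferroni adjustment is provided over the sets of one GMT file.

## Synthetic data generator

The generator emulates the statistical shape of a core-vs-periphery
single-cell experiment:

| parameter | default | meaning |
|---|---|---|
| n_pos / n_neg | 200 / 120 | cells per class (≈2:1 imbalance, scaled down) |
| n_genes | 500 | gene universe |
| n_informative | 20 | class-informative genes |
| n_redundant_groups × group_size | 5 × 3 | redundant copies of the first templates |
| log2_fold_change | 2.0 | symmetric between-class split, 2^(±1) around base |
| base_mean | 5.0 | baseline NB mean (counts) |
| dispersion | 0.5 | NB overdispersion, var = μ + 0.5·μ² |
| dropout_prob | 0.3 | independent Bernoulli zeroing |
| seed | 20200305 | frozen for the recovery scenario |

Counts are negative binomial; informative genes shift their mean by
2^(±lfc/2) per class with the direction alternating across genes so both
up- and down-regulated markers occur. Each redundant copy resamples its
template Poisson(template count) cell by cell — highly but not perfectly
correlated after discretization, the regime where the redundancy penalty
actually matters (exact-duplicate fixtures are constructed separately in
tests). Dropout is applied last, independently to every entry. Generation
is byte-identical for identical specs.

What the generator does **not** model: batch effects, library-size
variation between cells, cell-cycle or subpopulation structure, and
mean-dependent dropout. Passing tests on this generator therefore
demonstrate that the ranking and selection machinery recovers planted
signal under overdispersion, sparsity and redundancy — not that any
particular biological dataset will yield a particular panel.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run on 50 random instances of ≤ 10 genes × ≤ 60
cells, where the brute-force greedy re-scan is exact and cheap. The
recovery scenario (500 × 320, frozen seed) is ranked to the top 40 and
evaluated by LOOCV for K = 40 prefixes. The chance-level control uses a
scaled-down no-signal scenario (150 genes, 80 + 50 cells) with stratified
5-fold CV and 20 label permutations, each permutation re-running the full
ranking and peak selection so the optimism of "max over k" is present on
both sides of the comparison; the observed panel MCC is compared to the
permutation mean ± 3.5 sd.

On the frozen recovery scenario the LOOCV curve peaks at MCC 0.940 with a
33-gene panel containing only planted signal genes. Note that the scenario
plants 35 signal genes in total (20 templates + 15 informative redundant
copies), and cross-validated MCC keeps improving until nearly all of them
are included — so the parsimony peak settles just above 30, slightly larger
than the template count alone would suggest.

## Known limitations

* The plug-in MI estimator is biased upward at very small cell counts;
  rankings are robust to this but absolute relevance values should not be
  over-interpreted.
* LOOCV over K prefixes costs K · N classifier fits; for matrices beyond a
  few thousand cells use `stratified_kfold`.
* The hypergeometric test treats gene sets as unordered identifier sets;
  no weighting, no alias mapping, no directionality.
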