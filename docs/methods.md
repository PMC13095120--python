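# Methods

## Units and data model

All ages are post-conception weeks (pcw). Ages measured on other clocks
(embryonic days, days in vitro) are divided by 7 at the interface, so
tempo slopes are weeks-per-week and a tempo ratio of r means one
system's transcriptional clock runs r times faster than the reference.

The universal input is a sparse gene × cell count matrix with per-cell
study, sample, age and broad-class labels (`MultiStudyDataset`),
exchanged on disk as MatrixMarket `.mtx` plus `genes.tsv`/`cells.tsv`.
Author cell-type labels are harmonized to seven broad classes
(Astrocyte, Progenitor, Neuron, Oligodendrocyte, Immune, Vascular,
Others) through an explicit lookup; unmapped labels are an error unless
the caller opts into an "Others" fallback, which is logged.

## Pseudobulk convention

Cells are aggregated by summing raw counts per group (per sample, or per
sample × broad class) and the aggregate column is then normalized as if
it were a single cell. Two normalizations are supported:

* **lognorm** — ln(1 + 10⁴·c/total); invariant to per-cell depth.
* **ranknorm** — each gene's count replaced by its ascending rank within
  the column (ties averaged, zeros included) divided by the number of
  genes, values in (0, 1]; invariant to any strictly monotone per-column
  transform. Ties are averaged and the divisor is the gene count, which
  keeps the statistic deterministic under ties.

Groups below a cell-count threshold, and groups with zero totals, are
dropped with a log entry. The normalization mode is recorded on the
matrix and enforced when a model predicts from it.

## The transcriptomic clock

The clock is an elastic-net regression of age on pseudobulk expression
in the glmnet parameterization (mixing α, strength λ). Predictors are
standardized internally; the model stores standardized-scale
coefficients together with per-gene training means and scales, so a gene
missing at prediction time contributes zero on the standardized scale —
i.e. it is imputed at its training mean — and the coverage of
nonzero-coefficient genes is logged (hard error below 50%).

Observation weights make every study total the same weight, split
equally across the broad classes present in the study and then across
groups within a class, so a deeply sampled study or an abundant class
cannot dominate the meta-analytic fit.

Defaults: α = 0.1; λ chosen from a 30-point geometric grid spanning
three decades below the data-derived λ_max, by internal 3-fold
cross-validation minimizing MAE, taking the largest λ attaining the
minimum. The grid length and fold count are arguments, so denser
schemes (e.g. 100 points, 5 folds) are available by configuration; the
defaults keep a full leave-study-out run at the package's default
problem size in the tens of seconds. The ridge limit (α = 0) is solved
in closed form rather than by coordinate descent. Fits along the λ path
reuse warm starts; the weakly regularized end of the path may not fully
converge on near-collinear inputs, which is harmless because those
points lose the internal CV.

Validation is by held-out context: leave-study-out CV measures
cross-laboratory generalization, leave-cell-type-out measures
independence from cell identity. Held-out predictions are bit-identical
under permutation of held-out age labels (no leakage); this also holds
for the composition models below because their hyperparameter selection
is nested inside each CV fold.

## Compositional models

Per-sample class proportions feed three predictors:

* **Study-specific models**: elastic net on the 7 proportions with a
  small (α ∈ {0.1, 0.5, 1}) × (20 λ) grid scored by leave-one-sample-out
  MAE under a one-standard-error rule — the most regularized pair within
  one SE of the minimum — so uninformative compositions fall back to the
  null (mean-age) model instead of overfitting. Studies with fewer than
  4 distinct time points are skipped with a log entry.
* **PCA models**: genes centered and unit-scaled on the training study;
  among the top 5 components the one with the largest |Pearson r|
  against age is kept with a least-squares score-to-age line. Projection
  onto another study reuses the training centering/scaling and imputes
  missing genes at the training mean; it requires ≥50% gene overlap.
  The ablation probe removes one class, recomputes per-sample pseudobulk
  and PCs, and reports whether the age-correlated component index
  changed — the fragility that makes PC-based staging study-specific.
* **Meta-analytic feature selection**: ordinary least squares on every
  class singleton and pair, ranked by mean leave-study-out MAE. The
  reported held-out predictions use nested selection (the candidate for
  a held-out study is picked by inner leave-study-out over the
  remaining studies). Significance of the best set comes from a null of
  ages permuted within study (default 1000 permutations,
  p = (1 + #better)/(1 + N)).

## Interpretation

* **Permutation importance**: mean MAE increase over independent
  permutations of one gene's expression across groups; zero-coefficient
  genes are 0 by definition.
* **Feature stability**: selection frequency across clock refits on
  group subsamples (without replacement) at the λ selected once on the
  full data.
* **Age-correlated genes**: per-study Pearson r with a two-sided t-test
  p and Benjamini–Hochberg q within study; genes constant within a
  study are excluded from that study's FDR.
* **Aggregate co-expression**: per study, Spearman correlations between
  genes over pseudobulk groups; off-diagonal entries rank-standardized
  into (0, 1] (average ties, divided by the number of pairs); matrices
  averaged across studies with per-pair support tracking; diagonal set
  to 1.
* **Modules**: complete-linkage agglomerative clustering of Euclidean
  distances between network rows, cut at a height (default 2.0). Cut
  heights are configuration, not promises about module counts.
* **Enrichment**: hypergeometric upper tail or two-sided Fisher exact
  per (module, gene set) with BH correction across all pairs of a call;
  an optional set-size filter (e.g. 10–200 genes) for annotation scans.
  Hypergeometric p-values are exactly valid but discrete: under a null
  they look uniform only when the margins are large enough for the
  support to be dense (uniformity is checked at genome-scale margins).
* **Neighbor voting**: k-fold hiding of module members; candidates are
  scored by the sum of network weights to retained members divided by
  node degree (a flag disables degree normalization); recovery of the
  hidden members is summarized by a midrank Mann–Whitney AUROC, averaged
  over folds and repeats. On small instances the implementation equals
  explicit pair-counting enumeration exactly.

## Cross-context application

One-to-one ortholog maps rename and subset genes (for matrices and for
trained models, so a human-trained clock can score mouse pseudobulk);
orthogroup maps average expression across member genes, producing
orthogroup-level features on which a model must be retrained. Tempo
slopes are per-system OLS fits of mean predicted age per sample against
actual age in weeks, with t-based slope CIs; tempo ratios get
delta-method CIs. The synchrony ANOVA is a Type-II test of
cell-autonomous age ~ compositional age × system. The similarity AUROC
ranks Spearman correlations between all group pairs and asks whether
pairs closer in (predicted or observed) age are more similar, per
age-difference threshold and optionally stratified into same-class and
cross-class pairs; self-pairs are excluded and each unordered pair
counts once.  On synthetic data, where only 10% of genes carry the age
program, the whole-transcriptome similarity signal is weak at tight
thresholds; the acceptance script therefore reports the AUROC at a
10-week threshold, where the near/far split is well populated.

## The synthetic generator

Per cell, counts are multinomial over genes with probabilities
softmax(baseline + slope·(age·tempo − age_center) + class profile +
batch + module factor + noise) and a library size uniform on
`depth_range`.  The age program is anchored at `age_center` (default 18
pcw, mid-gestation), so baselines describe mid-development expression
and a cell class carrying no program reads as an age-18 sample rather
than an extrapolated age-0 one; the anchor also makes cross-species
effective ages line up exactly (a · tempo − c is the same for species B
sampled at ages a/tempo). Defaults
emulate a mid-sized meta-analytic collection: 6 studies × 8 samples
spanning 6–30 pcw, 300 cells/sample, 2,000 genes of which 100 rise and
100 fall with age (|slope| ~ U(0.03, 0.08) per pcw), 6 modules whose
members share a per-sample latent factor (sd 0.3), per-study log-scale
batch effects (sd 0.15), per-class expression profiles (sd 0.5),
residual log-noise sd 0.1, depths 1,000–5,000. Composition follows
logistic curves per class with one balance class absorbing the
remainder, which guarantees proportions sum to 1; configurations whose
balance goes negative are rejected. Progenitors fall (~0.55 → 0.08),
astrocytes (0 → 0.25) and oligodendrocytes (0 → 0.10) rise, small
classes stay flat.

Optional knobs, inert by default: per-sample compositional jitter and
per-study compositional offsets (with a list of "stable" classes exempt
from both, emulating well-defined classes annotated consistently across
laboratories — necessary for any feature-selection experiment, because
proportions sum to 1 and the balance class is otherwise an exact linear
combination of the rest); study-specific module activity (probability a
module's age program is expressed in a study); a class-private age
program (`signal_class`); and the tempo factor. Cross-species
simulation reuses the same gene parameters for a second species whose
clock runs `tempo_factor_b` times faster, with sample ages and
composition-curve midpoints rescaled so both species traverse the same
program range, and emits a one-to-one ortholog map over a configurable
gene fraction.

What the generator does **not** emulate: real marker genes, doublets and
ambient RNA, spatial structure, UMI saturation, nonlinear (stage-wise)
programs. One consequence of the multinomial count model worth knowing:
library normalization leaks a weak, shared age drift into every gene
(the softmax normalizer changes with age), so even zero-slope genes are
not perfectly age-free — negative controls that need literally
uninformative features should be built at the matrix level rather than
from counts. Passing tests on this generator demonstrate correctness of
the estimators and recovery of the planted structure, not performance on
real tissue.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 6-study scale for clock
validation (≈14k cells, 2,000 genes, ≈310 pseudobulk groups; a full
leave-study-out pass takes ~30 s on one core) and smaller constructions
for the compositional, ablation and tempo experiments. Module recovery
is demonstrated on a simulation with strongly planted factors (module
sd 0.8), where the default detector settings recover the planted
partition (adjusted Rand > 0.8); at the default generator's module sd of
0.3 the shared age trend dominates the co-expression network and module
boundaries are not identifiable — a real ambiguity of co-expression
modules, not a detector failure. Degenerate inputs (constant genes,
constant PC scores, zero-total cells) are either excluded with logging
or produce flagged NA statistics rather than exceptions, except where an
operation would be meaningless (empty datasets, single-class CV), which
raises.
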