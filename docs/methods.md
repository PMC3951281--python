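# Methods

This note documents the models and procedures implemented in `mihc`, the
choices made where the method family leaves details open, and what the
synthetic benchmark does and does not demonstrate.

## Problem setting

Given a time-course gene expression matrix (genes × ordered time points,
log-ratio values), a Gene Ontology `is_a` DAG and gene→term annotations
(biological process namespace), the goal is to predict which functional
classes an unannotated gene belongs to from its expression profile alone.
Because most GO terms annotate very few genes, raw terms are unlearnable
as classes; the pipeline first denoises the annotations and then
aggregates terms into classes large and coherent enough to train on.

## Preprocessing

Each expression row is (1) imputed, (2) baseline-shifted so its first
value is 0, and (3) smoothed with a centred moving average.

* **Imputation.** Missing cells are linearly interpolated along the time
  axis; leading/trailing gaps take the nearest observed value. Genes
  missing more than 30 % of their points are dropped with a warning.
  Microarray time courses routinely contain gaps, and interpolation is
  the mildest assumption consistent with slowly varying profiles.
* **Baseline.** Subtracting the first value makes profiles comparable by
  their change over time; the step is idempotent.
* **Smoothing.** Window width 3 by default (must be odd); edge windows
  are truncated to the available neighbours so series length is
  preserved. Width 3 is the smallest window that removes single-point
  spikes without flattening cell-cycle oscillations. Note that smoothing
  runs after the baseline shift, so the first smoothed value need not be
  exactly zero (it is the mean of the first truncated window).

## Non-noise gene selection

For each annotated term, build a graph over its genes with an edge
wherever the two profiles' Pearson correlation is significant, and keep a
greedy maximal clique.

* **Significance.** Two-sided t-test on `t = r·sqrt((n−2)/(1−r²))` with
  `n−2` degrees of freedom, default `alpha = 0.05`; `|r| = 1` is always
  significant; a constant profile has undefined correlation and
  contributes no edges. No multiple-testing correction is applied across
  pairs by default (an optional per-term Bonferroni flag exists), since
  the clique requirement itself is already a strong conjunction of
  per-pair tests.
* **Greedy clique.** Maximum clique is NP-hard; the greedy rule starts
  from the highest-degree vertex and repeatedly adds the candidate
  (adjacent to all current members) of highest degree within the
  candidate subgraph, ties broken lexicographically by gene id. The
  result is always a valid maximal clique, deterministic, and bounded
  above by the exact maximum (checked against exhaustive search on small
  graphs).
* **Retention.** Terms whose clique is smaller than `min_clique`
  (default 2 — a singleton carries no co-expression evidence) are
  dropped. The union of retained cliques restricts the expression matrix
  and annotation map to the non-noise system.

## Learning-system construction

All three constructors output classes (sets of terms with member genes)
and a binary genes × classes label matrix.

* **GNC** (`lam`, default 10): working bottom-up by DAG level
  (recomputed each pass), a term with fewer than `lam` genes hands its
  genes to all of its parents and is removed, its children re-wired to
  those parents. Roots that still fall short of `lam` are dropped and
  their genes reported unplaced — so GNC may lose genes, which is why
  its gene totals can differ from the other systems.
* **GOLC** (`iota`, default 1): every (gene, term) pair is re-assigned
  to each ancestor of the term (itself included) sitting exactly at
  level `iota`, where a term's level is its shortest `is_a` distance
  from the namespace root. A DAG term may have several level-`iota`
  ancestors, in which case the gene joins all of them.
* **MIHC**: each retained term is a multi-instance bag whose instances
  are its clique genes' profiles. Bags are merged agglomeratively under
  a Hausdorff-family bag distance with instance distance
  `d(x, y) = 1 − pearson_r(x, y)`; the merged cluster's instance set is
  the union (clusters remain bags, not linkage abstractions). Merging
  stops when the closest pair is farther apart than the terminal factor
  `tau`. Each final class's gene set is the union of its member cliques,
  so MIHC conserves the non-noise gene set exactly.

### Bag distance

With cross-distance matrix `D` between bags `a` and `b`, row minima
`m_x` and column minima `m_y`:

* `avg_hausdorff` (default): `(Σ m_x + Σ m_y) / (|a| + |b|)` — robust,
  zero on identical bags;
* `max_hausdorff`: `max(max m_x, max m_y)` — the classical Hausdorff
  distance;
* `min_hausdorff`: the single closest cross pair.

The average variant is the default because single aberrant instances
should not dominate a bag-to-bag comparison. Constant profiles get the
maximal instance distance 2.0 (logged).

### Terminal factor

`tau = None` uses the mean of the initial pairwise bag-distance matrix.
This keeps MIHC parameter-free: within-module bag distances concentrate
well below the matrix mean and between-module distances above it, so the
adaptive threshold separates the two regimes without tuning. Merge
tie-breaks take the lowest pair of cluster indices, making the whole
agglomeration deterministic.

## Classifiers

Both are binary-relevance multi-label classifiers emitting continuous
per-class scores (required for ROC analysis).

* **MLSVM**: one soft-margin SVM per class (scikit-learn `SVC`), RBF
  kernel with bandwidth `1/n_features`, `C = 1` by default. Class
  imbalance is countered by amplifying the hinge loss of positives with
  the coefficient `N_neg/N_pos` (negatives keep weight 1); with all
  coefficients forced to 1 the model reduces to the plain SVM. Classes
  with a single label value in training are skipped with a warning and
  scored at a sentinel minimum.
* **MLKNN**: neighbour search under `1 − pearson_r`, `k = 5` by default,
  ties broken by training-sample index. A test profile's candidate
  classes are the union of its k neighbours' labels; each candidate's
  score is the summed similarity `(1 + r)/2` of the neighbours belonging
  to it; a class is predicted when its score exceeds half the total
  neighbour similarity mass (strict inequality, so an exact split
  predicts nothing). This reduces to majority voting when all
  similarities are equal.

## Evaluation protocol

Per class: draw `round(n·P)` training positives (half-up rounding,
clamped to `[1, P−1]` so both splits keep a positive — this realises the
gradual-increase handling of classes with few positives) and the same
number of negatives uniformly without replacement; everything else is
the test set. The grid of `n` runs 10 %–90 %; each cell is repeated
(20 repetitions by default) with per-(class, n, repetition) RNG streams
derived deterministically from one master seed. Classes with fewer than
2 positives are skipped with a warning.

AUC is computed by the rank (Mann–Whitney) formulation with ties counted
½; the ROC sweep over distinct score thresholds integrates (trapezoid)
to the same value to numerical precision. Summaries average per class
first and then across classes and repetitions (macro); a pooled variant
is available. TPR/FPR are reported at the classifier's operating point
(decision value 0 for MLSVM, the similarity-mass majority for MLKNN).

## Synthetic data

The generator plants `n_modules` co-expression modules: module *m*
follows `sin(2π·k·j/n + φ)` with `k = 1 + ⌊m/2⌋` cycles over the series,
modules sharing a frequency sit a quarter period apart, and each
frequency receives one random global phase. This harmonic family keeps
distinct modules near-orthogonal (between-module correlation ≈ 0 up to
noise) while staying periodic like cell-cycle expression; purely
independent random phases were rejected because two modules drawn close
in phase are indistinguishable in correlation geometry, which makes any
correlation-based clustering of them ill-posed rather than merely hard.
Genes add i.i.d. Gaussian noise (sd 0.3 by default against unit
amplitude); background genes are pure noise and carry no annotations.

The ontology has one root, one mid-level term per module and
`terms_per_module` leaves per module, each leaf annotated with
`genes_per_term` genes of its module. A leaf's mid-level parent is
assigned round-robin across modules, so the DAG's level-1 neighbourhoods
deliberately mix expression modules — as in the real GO, where being
siblings under a broad term does not imply co-expression. This is what
gives the three constructors different class structures on synthetic
data: GNC and GOLC aggregate by DAG position (mixed classes), MIHC by
expression (coherent classes).

Defaults (4 modules × 3 terms × 8 genes, 18 time points, sd 0.3, 30
background genes) are sized like one arm of a small microarray
time-course study. Deterministic given the seed.

**What the benchmark does not show.** Real annotation data have
overlapping gene sets across terms, evidence-code heterogeneity,
deeper/multi-parent DAGs, and expression noise that is neither Gaussian
nor stationary; the synthetic AUC levels (MIHC near 1.0) therefore say
that the implementation separates separable structure, not that similar
AUCs are attainable on biological data.

## Reproduction checks

`scripts/acceptance.py` recomputes, from scratch: the balanced-split
train/test ladder of a 49-positive, 212-negative class across the 10–90 %
grid; greedy-clique validity/maximality/boundedness on 200 random graphs;
agreement of the agglomeration with a naive from-scratch oracle; the
three constructors' postconditions on 20 random synthetic DAGs; MLKNN
agreement with an exhaustive reimplementation plus the MLSVM
separability/amplification checks; the rank-AUC error against pairwise
brute force; and the synthetic comparison (median over 20 generator
seeds, 3 repetitions per grid cell) of MIHC against GNC(λ=10) and
GOLC(ι=1) with both classifiers at n = 50 %, the Spearman trend of
MIHC's AUC in n, and planted-module recovery (adjusted Rand index).
Three repetitions per cell keep a full run around a minute while the
median over 20 seeds stabilises the comparison.

## Known limitations

* The greedy clique can under-shoot the exact maximum clique (it is a
  heuristic by design); only its validity, maximality and determinism
  are guaranteed.
* Bag-distance merge heights are not guaranteed monotone (the union
  metric is not reducible), so the dendrogram may contain height
  inversions; the Newick writer clips negative branch lengths at zero.
* `part_of` and other non-`is_a` GO relations are ignored throughout.
* The MLKNN neighbour search is exact (no indexing) and quadratic in the
  training size — adequate at learning-system scale, not for
  genome-wide feature spaces.
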