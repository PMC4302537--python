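# Methods

## The model

A bicluster is a submatrix (row set *I*, column set *J*) of a real-valued
expression matrix *A* (rows = genes, columns = conditions) whose values
follow a coherency model:

- **constant on rows**: `a_ij = c_j` — every row shows the same profile
  across the bicluster's columns;
- **additive (shifting)**: `a_ij = c + alpha_i + beta_j` — rows are
  offset copies of one profile;
- **multiplicative (scaling)**: `a_ij = c' * alpha'_i * beta'_j` — rows
  are scaled copies (equivalently additive after a log transform);
- **symmetric**: `a_ij = c_i * v_ij`, `c_i ∈ {-1, +1}` — rows may be
  sign-flipped versions of a base pattern, capturing joint activation and
  repression.

The package discovers all such submatrices above a minimum row count by
frequent-itemset mining (FIM). The matrix is *itemized*: values are
discretized into an ordinal alphabet of `|L|` symbols and each row becomes a
transaction of `(column, symbol)` items. An itemset `P` with coverage
`phi(P)` (the transactions containing it) is exactly the bicluster
`(phi(P), columns(P))`, perfectly constant on rows in the itemized matrix.
Closed itemsets (no superset with equal support) correspond to maximal
biclusters — no row or column can be added without breaking the pattern —
and are the default representation.

Non-constant coherencies reduce to constant mining by *alignment* against a
reference column `j`: shift row `i` by `max(y_j) - a_ij` (additive), scale
it by `max(y_j) / a_ij` (multiplicative), or flip its sign when negative in
`j` (symmetric). Any bicluster of that coherency containing `j` becomes
constant on rows after the alignment, so running the miner once per
candidate reference column and de-duplicating finds all of them. Scaled
values are gathered into items of relative width `delta` (default 0.1) by
logarithmic binning; log bins are used instead of single-linkage chaining
because chaining collapses long runs of closely spaced ratios into one item.
The phrasing of the scaling adjustment in terms of least common multiples is
the integer special case of the ratio `max/a_ij` (they coincide exactly when
every symbol divides the column maximum, as in the usual two-level
illustration); the ratio form is used because it renders the reduction exact
for arbitrary symbol values.

## Mapping parameters

- `alphabet_size` (`|L|`, default 7): more symbols mean stricter coherency
  per item and smaller biclusters. Discretizers: equal-width bins over the
  observed range (default), equal-frequency (quantile) bins that never split
  ties, or equal-probability cuts of a moment-fitted normal.
- `boundary_multi_item` / `epsilon` (default 0.055 bin widths): a value
  within `epsilon` of a cutoff also receives the adjacent bin's symbol,
  countering the fragmentation of biclusters whose cells straddle a bin
  boundary. On uniform data a fraction `2*eps*(|L|-1)/|L|` of the cells is
  affected; the default yields 9–10% transaction growth.
- `missing_strategy`: `remove` (missing cells contribute no item),
  `relaxed` (all symbols), or `delta_replace` — impute by the mean of the 4
  nearest-neighbour rows (Euclidean over shared observed columns, normalized
  by the shared count, ties by row index) and assign the 2–3 bins whose
  centroids are nearest the estimate (the third only if within one bin
  width).
- Normalization (off by default; per row/column/overall, optional zero
  mean) standardizes to unit population dispersion; zero-mean plus a
  zero-centered alphabet is required for symmetric mining. Missing and
  outlier-masked cells never enter the statistics.

## Mining parameters and the adaptive loop

Support `theta` is the minimum number of rows. The adaptive loop starts at
25% of the rows and multiplies by `decay` (0.9) per rung until either the
biclusters cover `coverage_target` of the matrix area or the support floor
is reached. Because closedness does not depend on the threshold and support
is anti-monotone, the ladder is evaluated by mining once at the floor and
taking per-rung subsets — identical output, one mining pass. The pipeline
default is to run to the floor (`coverage_target = 1.0`): with planted-area
fractions of a few percent, an area-based stop triggers before the smallest
biclusters are found and was measured to cost 0.2–0.3 of the hidden-recovery
match score.

**The support floor is the central statistical control.** Two estimates are
combined:

1. an analytic Poisson bound on the expected number of chance patterns,
   from the database's empirical per-column collision probabilities
   (near-constant columns, e.g. an aligned reference column, are excluded
   from the background model and credited against pattern length);
2. a permutation null: every column is permuted independently (preserving
   marginal item frequencies while destroying row structure), the full
   alignment + mining machinery is run on the null, and the floor is set two
   above the strongest null pattern (+2 because the observed null maximum is
   one draw of an extreme-value statistic). The null maximum is found by
   branch-and-bound (the strongest pattern with ≥ c items has an equally
   strong c-item subset, so the search is depth-limited and pruned by the
   incumbent), avoiding enumeration of the chance flood.

Chance support falls steeply with the number of columns, so floors are
calibrated per column-count tier (base and base+1): a wide pattern may keep
a support below the base floor. The minimum pattern length is data-driven,
capped at 4 columns (5 for multiplicative, where any proportional row pair
collides, making scale coherency far more prone to chance agreement).

## Closing

Order: merge → (significance filters) → containment filter → optional
extension → optional reduction → structure composition.

- **Merging** (70% of the smaller bicluster's area) rejoins fragments split
  by boundary noise, missing values or overlap damage. Candidates are
  quality-guarded: the merged submatrix is re-aligned on its own columns and
  must keep ≥ tau modal agreement in every row and column — without the
  guard, merging folds in "hybrid" patterns (a bicluster's columns plus one
  coincidentally agreeing background column) and the consensus score
  collapses.
- **Row trimming** removes rows whose aligned profile agreement falls below
  the homogeneity floor (rows recruited by a narrow fragment and
  inconsistent with the full column set).
- **Independent-support filtering** discounts rows borrowed from a larger
  bicluster sharing ≥ 2 columns; the remainder must clear the chance floor.
- **Containment filtering** (30%) drops biclusters covered by the union of
  higher-ranked survivors. Rank is calibrated significance — support
  relative to the (geometrically extrapolated, ≥ 3) chance floor for the
  bicluster's column count. Raw area and raw column count were both tested
  and rejected: area prefers row-diluted narrow fragments, column count
  prefers hybrids; each ordering measurably destroyed recovery.
- **Extension** re-admits rows/columns matching the bicluster profile on a
  `homogeneity_min` fraction of positions (default 0.75), re-checked as
  `1 - MSR/range^2` on the real values; or re-mines at a decayed support and
  absorbs enclosing patterns.
- **Reduction** greedily removes the row/column that most improves
  `1 - MSR_norm` until the homogeneity floor is met (never below 2x2).
- **Structures**: free (default), exhaustive (hierarchical merging until
  the matrix is covered), or exclusive on rows/columns/both (merge
  well-overlapping pairs, otherwise drop the smaller, until no sharing).

## Synthetic benchmark

Backgrounds are U(1, |L|) or N(|L|/2, |L|/6) clipped to [1, |L|]. Planted
biclusters draw their row/column counts uniformly from preset ranges
(100x30/3, 500x60/5, 1000x100/10, 2000x200/15, 4000x400/20 with the
published shape ranges); values are integer alphabet levels following the
configured model, with parameters sampled so products/sums always stay in
[1, |L|] (no clipping). Uniform noise of up to ±15% of `|L|` is added to
background cells only (a flag extends it to planted cells). Corruption
replaces a fraction of cells by values at distance > 25% of the observed
range; missing injection blanks an exact cell count. Overlapping biclusters
are allowed; overlapping cells take the later bicluster's values, so
overlaps damage earlier biclusters — real recovery scores are capped below
1 on crowded settings (at 100x30, an oracle recovering every row with at
most one damaged column averages ≈ 0.93 hidden-recovery match score).

What passing recovery tests do **not** show about real data: planted cells
are noise-free and exactly model-coherent, backgrounds are independent
across cells, and missingness is uniform — real expression data violates
all three, so absolute scores here are upper bounds on practical behaviour.

## Evaluation

- Match score MS(B, H): mean over B of the best row-set Jaccard against H
  (an element-area variant is available behind a flag; the printed form is
  row-based). MS(found, hidden) measures correctness, MS(hidden, found)
  completeness.
- Consensus FC: Hungarian one-to-one assignment between the two sets
  maximizing element-overlap Jaccard, summed and divided by the larger
  set's size — surplus or missing biclusters are penalized.
- MSR: Cheng–Church mean squared residue (zero for constant and additive
  blocks); `MSR_norm` divides by the squared matrix value range.

## Numerical and degenerate-input choices

- Values exactly on a discretization cutoff go to the lower bin; the upper
  bin arrives only via boundary multi-items (determinism).
- Zero-dispersion normalization units map to zeros with a warning.
- Equal-depth cutoffs move forward past ties so identical values never
  split across bins.
- A symbol of zero is its own symmetric partner: sign +1.
- Merge pair selection: descending overlap ratio, then combined area, then
  insertion order; guard-rejected pairs are memoized. All stages are
  deterministic given input and configuration; the recorded seed feeds the
  generator only.

## Problem sizes used in the shipped checks

Recovery checks run 20 datasets of the 100x30 preset, 3 each of the 500x60
preset per coherency, and 1000x100 for the constant-coherency and
robustness checks; these sizes keep a full run in the tens of minutes on
one core while leaving the mean scores within a point of larger
replications. The acceptance script reports the same three quantities
(constant/additive/multiplicative recovery as percentages) recomputed from
scratch: 3 datasets for the stable constant setting and 4 for each aligned
coherency, whose score variance is higher.

## Known limitations

- The multiplicative path assumes positive symbols; combined
  sign-plus-scaling re-maps to a positive alphabet first and its item
  arithmetic is a documented approximation.
- Literal re-mining is used for the `maximal` representation in the
  adaptive loop (threshold-dependent), making it slower than `closed`.
- The 4-nearest-neighbour imputation is weakly informative when bicluster
  columns are a small fraction of all columns (estimates regress to column
  means); `delta_replace` then cannot improve much over element removal,
  whose fragments the closing stage already reassembles well.
- Efficiency: desk-scale throughput handles the 1000x100 preset in about a
  minute per dataset for constant coherency and a few minutes for aligned
  coherencies; the 4000x400 preset and genome-scale (10,000-row) matrices
  are out of scope for the shipped checks.
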