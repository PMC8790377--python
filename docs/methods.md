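# Methods

## Problem and model

Single-cell DNA sequencing requires one library per cell, so the cost of
profiling copy-number variation (CNV) across a tumour grows linearly with
the number of cells.  When the subclonal structure is already known — a
reference subset of cells has been sequenced individually and clustered into
T types with distinct copy-number genotypes — the remaining cells do not
need accurate per-cell profiles, only a correct type assignment.  `poolcnv`
implements an overlapping-pooling design for this setting: c cells are
distributed into p < c pools (each cell possibly in several pools), one
library is sequenced per pool, and the per-cell types are recovered by
solving two linear systems.

Five matrices are involved:

- **PC** (p × c, binary): the pooling design, `PC[i,j] = 1` iff cell j is in
  pool i.  No row or column is all-zero.
- **TB** (T × B′, integer): consensus copy number of each type over the B′
  informative bins.
- **PB** (p × B′, continuous): observed copy-number profile of each pool.
- **PT** (p × T, continuous): estimated type mixture of each pool.
- **CT** (c × T, binary one-hot): the recovered cell-type assignment.

**Step 1 (mixtures).**  Each pool's profile is approximately a convex
combination of the type profiles, `PT · TB ≈ PB`.  The system is solved in
the least-squares sense with the Moore–Penrose pseudoinverse,
`PT = PB · TB⁺`, computed by SVD with singular values below `sv_rtol = 1e-10`
times the largest treated as zero.  Negative entries are kept: clamping
would bias the least-squares geometry the next step assumes.  If TB has row
rank below T the mixtures are non-unique and a warning is raised.

**Step 2 (assignments).**  PT rows are rescaled from proportions to cell
counts (multiplying row i by the pool size n_i), so they are comparable to
`PC · CT`, which counts member cells per type.  The assignment is the exact
minimiser of

    Σ_t Σ_i ( Σ_j PC[i,j] · CT[j,t] − PT[i,t] )²

over one-hot CT rows.  The scale-reconciliation step is made explicit and
isolated in `scale_mixture_to_counts` so both readings (proportion vs count
scale) can be tested independently.

## Branch and bound

The assignment problem is solved by best-first branch and bound:

- **Relaxation / bound.**  At each node, fixed cells keep their one-hot
  rows; free rows are relaxed to the probability simplex, giving a convex
  quadratic.  It is attacked with Frank–Wolfe iterations (exact line
  search); the Frank–Wolfe duality gap g = ⟨∇f, X − S⟩ satisfies
  f(X) − g ≤ f*, so f − g is a certified lower bound at every iterate.  The
  best bound over the run is kept, and a child inherits its parent's bound
  when that is tighter.  Effort is 100 iterations at the root node and 2 at
  every subsequent node (configurable).
- **Incumbent.**  The relaxed solution is rounded row-wise to its largest
  entry and polished by coordinate descent: sweeps over cells in index
  order, evaluating all T reassignments per cell through an incremental
  residual update costing O(pools containing the cell), applying the best
  strictly improving move.  The objective never increases across sweeps.
- **Branching.**  The free cell with the smallest maximum relaxed weight
  (most fractional) is fixed to each type in turn, children ordered by
  relaxed weight descending.  Ties everywhere break toward the lowest type
  index; the node queue breaks bound ties by insertion order.  The solver is
  fully deterministic.
- **Termination.**  Exhausting the queue (or popping a node whose bound
  cannot beat the incumbent) proves optimality; `gap_tol > 0` allows early
  stopping with a certified gap; hitting the node or time budget returns the
  incumbent with the gap to the best remaining bound
  (status `budget_exhausted`).  A floating-point safety margin of
  `1e-9 · (1 + |incumbent|)` guards pruning.

At the 80-cell scale with noisy mixtures the simplex relaxation is weak
(fractional rows absorb residual noise), so certifying optimality is rarely
possible within a desk-scale budget; the returned assignment is then the
coordinate-descent-polished incumbent, whose quality — not the certificate —
is what the restoration accuracy measures.  On small instances (T^c up to
~3^10) the solver provably matches exhaustive enumeration, which the test
suite checks on 50+ random instances.

## Reference typing

- **Clustering:** agglomerative hierarchical clustering (Ward linkage,
  Euclidean distance) of the reference cells' integer CN vectors, cut at
  exactly T clusters.  T is an input: the premise is that the subclones were
  characterised in advance.  Cluster labels are renumbered by first
  occurrence, so type identities are deterministic.
- **Informative bins:** a bin is kept iff the most common copy number among
  all reference cells (jointly, not per type) is shared by at least
  θ = 0.8 of them.  The comparison is inclusive (≥), which keeps boundary
  cases such as 64 of 80 cells representable.  Note a consequence of the
  threshold being > 0.5: a bin whose top two values tie can never be kept.
- **Consensus:** `TB[t,b]` is the modal copy number of type-t cells at bin
  b.  Modal ties break toward the value nearest the diploid 2, then toward
  the smaller value — a conservative bias toward calling bins normal.
  Columns where every type is 2 are dropped (no signal); if none remain the
  method is inapplicable and an error is raised.

One structural consequence worth knowing: with equal-sized types, a bin
altered in two or more types has mode frequency ≤ 1 − 2/T·(cells per type),
so the kept informative bins are dominated by bins altered in exactly one
type.  This makes TB rows near-orthogonal and the mixture estimation well
conditioned — a property inherited from the informative-bin filter, not
imposed separately.

## Pooling

Each of the p pools receives a uniform random subset of exactly
round(k·c) cells (fixed pool size, matching the stated member counts
8/12/16/20/24 at c = 80); designs leaving any cell unpooled are rejected and
redrawn.  Cells appearing in fewer than 2 pools are reported as weakly
constrained diagnostics — they are the dominant source of restoration
errors, because two singleton cells sharing their only pool are provably
interchangeable.

Pool profiles are synthesized two ways:

- **Profile space:** the equal-weight arithmetic mean of member-cell CN
  profiles, kept continuous (rounding a mixture average would destroy the
  proportion information).  An idealisation used for noiseless analyses.
- **Count space (default):** member read counts are summed per bin and
  rescaled by the pool's ploidy (mean of member ploidies), emulating the
  merging of equal-depth libraries.  Because each cell's reads spread in
  proportion to `cn / ploidy`, the merged profile is a 1/ploidy-weighted
  mean of member profiles; it equals the profile-space mean only when member
  ploidies coincide.  This small, realistic bias is retained deliberately
  and is absorbed by the least-squares mixture fit.

## Synthetic data generator

The generator emulates the structure of a medium-scale single-cell tumour
CNV study: T = 7 types, 80 cells (12/12/12/11/11/11/11), a diploid genome
tiled into B = 10,000 bins of 100 kb, 1 million reads per cell.

- **Type profiles:** each type receives 6–12 CNV segments of 50–400 bins on
  a diploid background; a segment is an amplification (CN 3–6) with
  probability 0.6, else a deletion (CN 0–1).  Profiles are redrawn until all
  pairwise Hamming distances reach 5% of B.  These ranges were chosen once
  as representative of chromosome-arm-scale tumour CNVs; they are fully
  configurable.
- **Within-type noise:** each cell copies its type profile and flips each
  bin by ±1 (clamped to [0, 8]) independently with probability
  `flip_rate = 0.02`.  The real-data magnitude of within-type heterogeneity
  is not reported anywhere we could anchor to, so 2% is a default chosen to
  leave types clearly separated (clustering recovers them exactly) while
  exercising the consensus and least-squares machinery; the evaluation suite
  checks that accuracy degrades monotonically as it grows.
- **Read counts:** multinomial per cell with bin probabilities proportional
  to the true copy number; totals are exactly `reads_per_cell`, giving every
  cell equal weight when pools are merged.  Cells with median reads/bin
  below 50 are QC-flagged.  The default B = 10,000 (rather than the
  full-scale 28,416 bins of a 100-kb hg19 tiling) keeps the median around
  100 reads/bin at 1M reads, above the QC floor; the full scale is
  configurable and the generator reproduces the fact that 1M reads over
  28,416 bins yields a median ≈ 35 < 50.
- **Integer CN calling:** per-bin `round(count / mean(count) × ploidy)`, with
  ploidy taken from ground truth (mean true CN).  Segmentation and GC
  correction are deliberately not modelled: they sit upstream of the method
  (the pipeline consumes integer CN matrices however produced), and per-bin
  rounding at ~100 reads/bin already recovers ≥ 97% of bins (the analytic
  Poisson rate; amplified bins dominate the misses).

What passing tests on this generator do **not** show: robustness to GC and
amplification bias, to segmentation artefacts, to misspecified T, or to
cells whose true type is absent from the reference — all properties of real
data the generator does not emulate.

## Evaluation

Restoration accuracy is the exact-match fraction against the reference
clustering labels — the types cells are "restored" to are the clusters found
when the reference cells were typed, so no permutation matching is applied.
The grid runner repeats the pipeline for every (p, k, replicate) with child
seeds spawned deterministically from a base seed, drawing a fresh population
and design per run; per-(p, k) summaries are replicate means and per-p
summaries average those.  Failures of individual runs are recorded, not
fatal.

Identifiability is handled operationally: a run reports, alongside its
accuracy, the number of *certified ties* — misassigned cells whose
assignment yields exactly the same fitted pool counts `PC · CT` as the
truth.  Such cells are information-theoretically unrecoverable under that
design (typically singleton-pool cells sharing a pool), and the zero-noise
completeness property is asserted modulo exactly these ties.

## Problem sizes and budgets

The default grid (two pool counts × five k values × three replicates, 80
cells, 10,000 bins) is the package's standard evaluation; each instance is
solved with a branch-and-bound budget of 2,000 nodes or 10 s, after which
the coordinate-descent incumbent and its certified gap are reported.  The
budget reflects where the quality actually comes from at this scale (the
root incumbent; the tree mostly tightens the certificate) and keeps a full
grid in the minutes range.  The solver-level default budget (10⁵ nodes /
60 s) remains available for single instances where a certificate matters.

## Known limitations

- Real pools are sequenced libraries; here they are synthetic count sums.
  Library-preparation artefacts shared within a pool are not modelled.
- The method assumes every pooled cell belongs to one of the T reference
  types; rare or novel subclones will be silently forced into the nearest
  type.
- With p approaching c/3 and small k, many cells are weakly constrained and
  the accuracy loss is dominated by design ambiguity rather than noise —
  consistent with the qualitative finding that more pools beat fewer.
- Automatic selection of T and statistical comparison across grid settings
  are out of scope.
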