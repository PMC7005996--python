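# Methods

## Stochastic model of a two-gene network

Each of two symmetric genes X, Y is described by its mRNA copy number
(n ∈ {0, …, M−1}) and a four-valued promoter state recording which
transcription-factor dimers occupy its two binding sites: neither
(`00`), the gene's own product (`self`), the other gene's product
(`other`), or both (`both`). Reactions and propensities:

| reaction | propensity | note |
|---|---|---|
| synthesis | g(s) | g(s) ∈ {g_lo, g_hi} from the logic table; 0 at n = M−1 |
| degradation | k·n | first order |
| self-site binding | h_a·n_self²/2 | TFs bind as homodimers |
| cross-site binding | h_r·n_other²/2 | |
| self/cross unbinding | f_a / f_r | |

Protein is not an explicit species: TF levels are taken proportional
to mRNA counts, with the proportionality constant absorbed into h.
Consequently **binding does not sequester a transcript** — promoter
transitions change only (s_x, s_y), never (n_x, n_y). The two sites of
a promoter bind and unbind independently (no site-interaction terms),
each using its own (h, f) pair regardless of what the other site holds.

A regulatory logic is a map from the four promoter states, ordered
(`00`, `self`, `other`, `both`), to {lo, hi}, applied mirror-
symmetrically to both genes. All 16 maps are enumerable ("Two-Gene
Flex"); the two constant maps encode no gene-gene interaction and are
excluded from sweeps. MISA is {lo, hi, lo, lo}. Motif classes are
assigned from the sign of the cross-gene effect evaluated in both
self-contexts (`other` vs `00`, and `both` vs `self`): consistently
negative → mutual repression (5 variants, including MISA),
consistently positive → mutual activation (5), both zero → no mutual
interaction (2 after exclusion), opposite signs → incoherent
dual-effect (2).

## Master-equation solution

States are linearized as i = s_y + 4·s_x + 16·(n_y + M·n_x) — any
fixed bijection works; this one is frozen for reproducibility — and
the generator K (off-diagonal K[l, m] = rate m→l, diagonal = negative
column sums) is assembled sparsely, vectorized over the whole state
space. The stationary distribution is computed by pinning the last
state's probability and solving the remaining (N−1)-dimensional sparse
linear system with SuperLU (MMD-on-A+Aᵀ column ordering, which roughly
halves fill-in for this quasi-banded pattern versus COLAMD), then
normalizing. A shift-invert eigensolve near eigenvalue zero is the
fallback. The solution contract is numerical, not algorithmic:
‖Kπ‖_∞ ≤ 10⁻⁸ × max|K_ii|, entries nonnegative after clipping
round-off no larger than 10⁻¹² of the peak, Σπ = 1. Violations raise
rather than degrade silently.

Defaults: M = 21 (counts 0–20), satisfying g_hi/k ≤ 7 ≪ M−1; a
boundary-mass diagnostic reports the probability at the reflecting
edge (≈10⁻⁹ for default parameters), and tests verify that raising M
to 36 moves every landscape metric by far less than 1%.

The quasipotential transform applies a 10⁻⁶ probability floor before
the log. The same floor is used for model and empirical landscapes so
both kinds of feature vectors are commensurable in one PCA basis; it
is below the smallest estimable frequency at the ~10⁵-cell sample
sizes the empirical landscapes target.

An exact-SSA (Gillespie) simulator over the same reaction set provides
an independent Monte-Carlo estimate of the stationary occupancy
(time-weighted dwell times, first 10% of simulated time discarded as
burn-in to remove initial-condition bias). It exists purely as a
cross-check of the deterministic solver and is seeded for
reproducibility.

## Sweeps and the shape-space

Sweep grids cross logic variants with log-spaced binding/unbinding
rates and linear g_hi levels inside the catalogued ranges (fast
regime: h ∈ [10, 500], f ∈ [10, 10⁵] per hour; slow regime: both in
[10⁻⁶, 10]). The shipped defaults are scaled-down versions of the
original tens-of-thousands-of-models sweeps, whose exact grids were
never published; sizes were chosen once to keep a full regeneration in
the tens of minutes on one CPU:

- **Flex**: 14 interacting motifs × g_hi ∈ {0.8, 1.4} (symmetric) ×
  3 log points each for h_a, h_r over [10⁻⁶, 500] and f_a, f_r over
  [10⁻⁶, 10⁵] → 2,268 probability landscapes.
- **MISA**: fast regime only, g_hi pairs from {0.8, 1.1, 1.4}
  (all 9 ordered pairs, so gene asymmetry is represented) × 3 log
  points for each h × 4 log points for each f → 1,296 quasipotential
  landscapes.

Libraries are exact-solver output: a pure function of the sweep
configuration, identical for any worker count, persisted to HDF5 with
their descriptor tables.

The shape-space is a mean-centered PCA (scikit-learn) on the library
matrix — each model a replicate, each of the M² grid cells a feature,
raw covariance with no per-feature scaling. Following the convention
that each training representation matches its downstream use, the
Flex space is trained on probability landscapes and the MISA space on
quasipotential landscapes (quasipotentials amplify rare-state
structure, which matters when projecting staged data). Because
eigenvector signs are arbitrary, components 1 and 2 are flipped so the
hi/hi archetype (product of truncated Poisson marginals with mean
g_hi/k) scores nonnegatively; deeper components get their largest
loading made positive. Three components are kept by default: on the
MISA space they read as overall expression level, coexpression versus
antagonism, and X/Y asymmetry — verified in tests by projecting four
hand-built archetype landscapes (lo/lo, hi/hi, a 50/50 hi/lo + lo/hi
mixture, and hi/lo alone). With the scaled-down defaults the Flex
space concentrates ~98% of covariance in two components and the MISA
space ~71/15/5% in components 1–3; these numbers are recomputed, not
stored, by `scripts/acceptance.py` and the acceptance tests.

The "data-driven" alternative (training the PCA on empirical
landscapes instead of model ones) is available simply by fitting
`fit_shape_space` to an empirical library, but the theory-driven space
is the supported analysis path.

## Empirical landscapes and trajectories

Annotated count tables are tab-delimited with one row per cell: gene
count columns plus `stage`, `cell_type`, `parent_cell_type`. Counts
are used as provided (the upstream atlas ships corrected counts); no
further normalization is applied, and rows with unparseable or
negative counts are skipped with a logged tally. A lineage is a
per-stage set of cell types (parents before the branch point,
daughters after). For one gene pair and stage, counts are truncated at
M−1 (cells beyond the cap are dropped and the fraction reported) and
binned into an M × M frequency grid — the sampled estimator of the
stationary distribution — then floored at 10⁻⁶ and log-transformed
when the target space is quasipotential.

A trajectory is the stage-ordered matrix of shape coordinates
(m stages × n components). Stages with no retained cells are dropped,
not imputed; clustering requires shape-consistent trajectories, so
pairs missing stages are excluded by default (alignment on a common
stage subset is possible by construction). Pairwise trajectory
distance is the Frobenius norm of the coordinate difference;
clustering is scipy average-linkage agglomeration on that distance
matrix (ward/complete selectable), cut either at a fixed cluster count
or a distance threshold — the original 24-cluster analysis printed no
threshold, so the cut is a user input.

## Synthetic cells

`simulate_cells` draws i.i.d. (n_x, n_y) pairs per stage from given
probability landscapes and emits an annotated table with a dummy
lineage, reproducible per seed. It emulates the *sampling* process
that turns a stationary distribution into a finite-cell count table —
nothing more: no dropout or other technical noise, no extrinsic
(cell-to-cell parameter) variability, no asynchrony within a stage,
and stages are independent draws rather than one continuous process.
Passing round-trip tests therefore demonstrates estimator and
projection consistency under ideal sampling, not robustness to
scRNA-seq artifacts. Sample-size defaults in tests (10²–10⁵ cells per
stage) bracket the per-lineage cell counts typical of embryo atlases.

## Numerical choices and degenerate inputs

- Eigensolve residual and clipping tolerances as above; the original
  workflow stated none, so these are engineering choices.
- Metrics use natural logarithms throughout (consistent with
  φ = −ln π); 0·ln 0 ≡ 0; mutual information skips zero-mass cells.
- Pearson correlation is computed on plain counts (not transformed);
  zero marginal variance raises a typed `UndefinedMetricError` instead
  of propagating NaN, as does a coexpression index with all mass at
  (0, 0). `metric_report` maps undefined metrics to NaN explicitly.
- A PCA fit on a zero-variance (all-identical) library is rejected.
- M = 1 collapses the landscape to a single cell with probability 1;
  the solver handles the promoter-only chain it leaves behind.
- Ties in hierarchical clustering follow scipy's linkage ordering.

## Known limitations

- Only symmetric two-gene logics; no explicit protein stage, no
  3-gene or higher interactions (the master equation becomes
  intractable), no time-dependent solutions or basin-transition
  kinetics.
- The scaled-down default sweeps cannot reproduce the exact
  full-scale library counts (~34k Flex / ~23k MISA) because the
  original grids are unpublished; variance fractions at reduced grid
  density differ from full-scale values by a few percentage points.
- Empirical-landscape quality degrades below a few hundred cells per
  stage; the package reports retained-cell counts but does not model
  estimator uncertainty.
- Whether the source models sequester a bound regulator is not
  documented; the no-sequestration contract here is a modeling
  decision.
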