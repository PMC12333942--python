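# Methods

This note documents the models, procedures, defaults, and design choices
behind `lesionscape`, and what the synthetic benchmarks do and do not show.

## Coordinate and data conventions

All coordinates are continuous micrometres in the image convention (origin
top-left, y downward); areas are mm². Cell tables are tidy DataFrames
(`cell_id`, `x_um`, `y_um`, `region_id`, one column per marker, optional
`phenotype`). Regions are simple polygons with a lesion-class label
(normal / PanIN / PDAC / CP), exchanged as GeoJSON. Spot data are dense
gene × spot count matrices on a hexagonally packed array with 100 μm
centre-to-centre spacing and even-parity `(row, col)` occupancy, exchanged
as MatrixMarket plus TSV/CSV sidecars.

## Phenotyping

Marker intensities are variance-stabilized with `arcsinh(x / 5)` (the
mass-cytometry convention). Positivity is intensity above a threshold —
either explicit per marker, or a per-marker quantile (default q = 0.75)
when thresholds are unknown. Phenotypes come from ordered boolean gates
(e.g. regulatory T cell = CD3+CD4+FOXP3+PD1−); more-specific gates take
precedence and ties follow declaration order, so labelling is a pure
function of the positivity matrix. The bundled `data/gates.yaml` encodes
the full panel of lymphoid, myeloid, and structural phenotypes. A k-means
path (k = 50 human-scale, 30 mouse-scale) with gate-based cluster
annotation (cluster-level positive ⇔ ≥ 50% of member cells positive)
stands in for self-organizing-map or graph clustering of imaging panels;
it is a deliberately simple, seeded surrogate, not a re-implementation of
those tools.

## Densities and statistics

Density is count / region area (cells per mm²), one record per
(region, phenotype), with declared-but-absent phenotypes at zero so counts
are conserved. The two-group test is the two-sided Wilcoxon rank-sum:
exact enumeration when both groups have n ≤ 12 and the pooled sample is
tie-free, otherwise the normal approximation with tie and continuity
correction (scipy's Mann-Whitney backend). Kruskal-Wallis covers more
than two groups. Density tests are reported unadjusted by design — the
analysis treats each region (ROI) as the unit and runs few tests — with a
Benjamini-Hochberg helper available for users who want adjustment.
Degenerate inputs (all values identical) return p = 1 rather than erroring.

## Interaction structure

"Shortest distance" is read as the per-cell nearest-neighbour distance,
averaged per ordered phenotype pair: `M[A][B]` = mean over A cells of the
distance to the nearest B cell, with self-exclusion on the diagonal. The
asymmetric matrix is kept; the network view symmetrizes edge lengths as
`(M[A][B] + M[B][A]) / 2` with node weight = abundance. The top-2
contact matrix increments `N[type(cell)][type(neighbour)]` for each cell's
two nearest other cells (Euclidean centroid distance, ties broken by
smaller `cell_id` for determinism), so row sums are exactly twice the
focal type's abundance. Phenotypes under 1% abundance are excluded before
computation. Normalization divides by the most abundant phenotype's count
in the region (the alternative reading — largest matrix entry — is
selectable). Nearest-neighbour queries use a k-d tree and are tested for
exact agreement with O(n²) scans.

## Tertiary lymphoid structures

Aggregates are DBSCAN clusters over lymphoid cells only (T- and B-lineage
gates), with defaults eps = 40 μm, min_samples = 10, min_cells = 50. The
40 μm reach (a 3–4 lymphocyte neighbourhood) is chosen so the sparsest
aggregate the pipeline is expected to resolve — about 200 cells in a
150 μm disc — carries ≈ 14 expected neighbours per cell, comfortably above
min_samples; at 30 μm the expectation is 8 and such aggregates fragment.
The aggregate boundary is the convex hull of member cells, a computable
stand-in for a pathologist-drawn boundary.

Association assigns the nearest lesion polygon (PanIN / PDAC / CP) whose
boundary lies within 250 μm of the hull boundary, else "excluded"; the
band width is configurable because lesion-adjacency analyses in this
domain use 200–250 μm. Maturity is called mature when at least
`gc_min_cells = 10` germinal-centre B cells (CD20+CD21+CD23+) are members
*and* their centroid lies inside the hull eroded by 10% of the equivalent
radius — a count-plus-interiority proxy for a distinct germinal-centre
zone. A B/T radial separation index and the densities of dendritic cells
and HEV inside the hull (these are not lymphoid, so they are counted
spatially, not as clustering members) are reported as metrics but never
used in the call.

## Spot transcriptomics

Spot QC: a spot is labelled by its predominant tissue class when that
class reaches 70% of its composition; fat-labelled and predominantly
non-tissue spots are removed, as are whole segments with median UMI below
200. TLS labelling is point-in-hull for spot centres plus a breadth-first
hex expansion of depth 2 for neighbours ("within 2 spots" is implemented
as graph depth on the lattice adjacency, treating the ~150 μm phrasing as
an approximation of two 100 μm steps).

The factorization input is `D = log2(counts + 1)`. The decomposition is
L1-penalized NMF by multiplicative updates (α = 0.01 on both factors,
tolerance 1e-6 on the relative objective change, up to 5000 iterations,
best of 3 seeded restarts; objective trace recorded and non-increasing by
construction). `P` rows are rescaled to maximum 1 with the inverse scale
absorbed into `A`, making spot weights comparable across patterns. This
deterministic desk-scale solver replaces Bayesian sparse NMF by design:
the downstream marker statistic depends only on (A, P). K is a user
choice; no automatic rank selection is attempted.

**Pattern markers.** With `r_k = Σ_j P_kj`, total reconstructed expression
is `T_g = Σ_k A_gk r_k` and fractional expression `f_gk = A_gk r_k / T_g`.
Genes are stratified into tertiles of `T_g` (strata under 5 genes merge
into a neighbour); within each (stratum, pattern) cell a gene is flagged
when `f_gk > Q3 + 1.5·IQR`, and its robust score is
`(f_gk − median) / (MAD + 1e−12)`. Flags are independent per pattern, so
dual-pattern genes arise naturally. The stratification-over-genes and
Tukey-fence choices are explicit, recovery-validated stand-ins; the
upstream literature does not pin them down.

**Module score.** Genes are ranked by mean expression and cut into 24
equal-size bins; each signature gene contributes 100 control genes sampled
from its bin (with replacement when the bin is small; seeded). The score
is the signature mean minus the pooled-control mean per spot. The score
contract is transform-agnostic; `log2(counts+1)` or log2 CP10K are both
provided.

**Pattern statistics.** Pattern weights vs module score uses Pearson
correlation with the t-distributed p and R² = r² from simple linear
regression. Across TLS classes, Kruskal-Wallis plus unadjusted pairwise
rank-sums. Preranked GSEA ranks genes by pattern-marker score and uses
the weighted Kolmogorov-Smirnov statistic (weight exponent 1); the null
permutes gene labels (equivalently, draws random same-size sets), the
p-value is two-sided on |ES| with the +1 convention (chosen so null
p-values are uniform and the α = 0.05 rejection rate calibrates), NES
normalizes by the mean same-sign permutation ES, and BH adjustment is
applied across sets within a pattern.

## The synthetic generator

The generator defines the study conditions the tests run under; all of its
distributional choices are stand-ins, since no generative model of the
real tissue exists.

**Cell maps.** Background cells follow homogeneous Poisson point
processes per region and phenotype, with an optional per-(region,
phenotype) lognormal density multiplier (CV 0.3 in the demo) emulating
ROI-level heterogeneity. Marker intensities are lognormal around median
2.0 (positive markers) or 0.2 (negative), σ = 0.4 on the raw scale, which
separates cleanly at the geometric-midpoint threshold. Planted immature
aggregates are uniform B/T mixtures in a disc; mature aggregates place
germinal-centre B cells in the inner half-radius disc with T cells,
dendritic cells, and HEV in the annulus. The 20-aggregate benchmark
plants 10 mature / 10 immature aggregates of 300 cells at boundary
distances of 150/200 μm (associated) and 300/400 μm or far-field
(excluded) from PanIN / PDAC / CP rectangles.

**Spot data.** Log2 mean expression is `M = A_true P_true` with spot
weights being Gaussian spatial bumps (row-max 1); pattern 0 is a tight
bump whose high-weight spots are the TLS spots. Each pattern owns 40
exclusive anchor genes (the planted markers); the remaining genes load on
all patterns with Dirichlet(5) shares — a minority-marker architecture
that is both realistic and what makes the factorization identifiable.
The 12-chemokine signature genes are background-distributed and elevated
by δ log2 units in TLS spots; counts are Poisson around
`s_j (2^M − 1)` with lognormal library factors (negative-binomial and
noise-free options exist). Module-score fidelity is measured on a
spatially flat variant (constant per-gene mean, 500 spots) where the
planted δ is the only TLS-vs-other difference; in the patterned world the
signature's baseline spatial profile cannot be cancelled exactly by
mean-matched controls at 10 TLS spots, and that coupling is instead
validated through the pattern-vs-module correlation.

**What passing does not show.** The generator emulates planted effects
under idealized noise: no segmentation errors, no marker spillover, no
batch effects, no spatial autocorrelation beyond the planted structure,
no dropout, and convex aggregates. Recovery on it demonstrates the
correctness and calibration of the operations, not performance on real
tissue.

## Problem sizes and numerics

Default benchmark sizes — 600 genes × 300 spots with K = 3, 20 planted
aggregates over a 8 × 6.4 mm section, 200 power replicates, 1000-replicate
null calibrations, oracle checks up to 2000 cells — are chosen to give
stable estimates on a single CPU within minutes. Distance ties break by
cell_id; equidistant lesion ties break by region order (logged); NMF
restarts derive seeds from the user seed; all stochastic operations are
reproducible bit for bit under a fixed seed.

## Known limitations

Convex hulls overestimate concave aggregate boundaries. The maturity call
is a threshold proxy and inherits the gc_min_cells choice. The rank-sum
exact/asymptotic switch at n = 12 follows standard practice, not an
optimality argument. The NMF solver finds local optima; restarts mitigate
but do not eliminate that. GSEA uses gene-label permutation, which
ignores inter-gene correlation. The CLI covers the bundled formats only.
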