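# Methods

## Input model

Every analysis consumes tab-separated text with a fixed header dialect
(upper-case column tokens, see `io_tables`). The universal input currency
is the pair `(marker ID, −log10 association p-value)`; the pipeline never
touches genotypes, raw intensities or coordinates, so any omics platform
whose summary statistics can be expressed this way is supported. Readers
canonicalize aggressively — duplicate association rows keep the maximum
value (conservative toward the stronger signal and deterministic),
dependency pairs are stored symmetrically with self-pairs dropped,
undirected reciprocal edges collapse to the maximum weight — so ingestion
is order-independent and write∘read is the identity.

## Marker dependency filtering

Dependent markers (LD blocks, adjacent CpGs) would otherwise be counted
repeatedly by set enrichment. MDF first keeps the top `top_fraction` of
markers by value (default 0.5; the weak-association tail is mostly noise),
then prunes greedily: markers are visited in descending value (ties by ID)
and kept iff no already-kept marker is linked to them with strength
strictly above `dependency_cutoff` (default 0.7, the conventional LD r²
threshold). The strict inequality makes the cutoff itself acceptable
("maximum acceptable" semantics), so `cutoff = 1` keeps everything.
Filtering precedes pruning — that matches the noise-reduction purpose of
the fraction parameter and shrinks the pruning graph. Dependency is not
treated as transitive: a marker linked only to *removed* markers is
retained. The greedy keep-best rule guarantees (a) no retained pair above
the cutoff, (b) every removed marker is dependent on a retained marker of
greater or equal value, and (c) maximality — re-adding any removed marker
would violate the cutoff. Both properties are asserted by full-scan
property tests.

## Enrichment statistic

With the marker universe of size `N` (all markers that are both scored and
mapped), cutoffs `c_q` are chosen per quantile level `q` as the smallest
observed value whose top-tail fraction is ≤ 1 − q (falling back to the
largest value under heavy ties; a constant universe is rejected). For a
gene set with `m` unique mapped markers — markers shared between member
genes count once —

    X = Σ_q (O_q − E_q) / √(E_q + κ),   E_q = m · M_q / N,

over levels `{0.5, 0.75, 0.9, 0.95, 0.99}` with stabilizer `κ = 1`. The
multi-threshold form rewards sets enriched anywhere along the strong tail
rather than at one arbitrary cutoff; `κ` keeps the sparse top levels
(`E_0.99` is small) from dominating through their denominators. A set
equal to the universe gives `X = 0` identically, and under marker
exchangeability `E[O_q] = E_q` exactly, so `E[X] = 0` — both are tested.

## Permutation null and p-values

Gene-level permutation is the default: null sets of the same gene count
are drawn uniformly from the indexed genes, each gene carrying its marker
complement intact, which preserves per-gene marker-count structure and is
robust to uneven coverage. Marker-level permutation (shuffling the value
column, equivalently sampling `m` values without replacement) is available
for more sensitive screening. Null samples depend only on the set's size,
so they are drawn once per distinct size and shared across same-size sets;
this is exact under the null and makes testing hundreds of sets cheap.
When no marker is shared between genes (true of the synthetic studies and
of typical pruned GWAS inputs), the gene-mode null is computed from a
per-gene count matrix by vectorized subset sums; the shared-marker case
falls back to explicit unions.

The primary p-value is the upper tail of a normal fitted to the null
sample — it resolves p below `1/n_permutations`, which the FDR ranking
needs — and the plus-one empirical estimator `(1 + #{X* ≥ X})/(1 + n)` is
reported alongside. The Gaussian tail is an approximation: for the MSEA
statistic at realistic set sizes its rejection rate at α = 0.05 measures
≈ 0.05–0.06; for wKDA hubs with small, skewed neighborhoods it can
overshoot (≈ 0.075 measured on a random-label fixture), so calibration
invariants are asserted on the empirical p, which is exact by
construction, while the Gaussian p remains the ranking quantity.
FDR is Benjamini–Hochberg across all tested sets. Defaults: 10,000
permutations for MSEA, 2,000 for wKDA; the test-suite and acceptance runs
use 500–2,000 to keep single-CPU runtimes in seconds, which is ample for
the rates and ranks they assert.

## Superset merging

Among sets with FDR < 0.25, the pair with the highest overlap coefficient
`|A∩B|/min(|A|,|B|)` is merged repeatedly while the coefficient is at
least `merge_overlap` (default 1/3); merged IDs join the constituents with
`+`. The output supersets are pairwise below the threshold (asserted) and
are re-scored with the ordinary MSEA machinery.

## Meta-analysis

Per-study MSEA results are combined per gene set with an unweighted
Stouffer z over one-sided p-values; `k = 1` reduces to the single-study
result exactly (special-cased rather than round-tripped through Φ). Sets
failing the size filter in some studies are combined over the studies
where they were tested, with `k` adjusted — cross-platform studies rarely
share full marker coverage. Every study is analyzed with the same
permutation seed: this makes the analysis invariant to study order and
duplicated studies exactly √k-amplifying, and does not affect the marginal
validity of any single study's p-values.

## Weighted key driver analysis

Candidate hubs are nodes whose depth-limited neighborhood (default depth
1; direction ignored by default, `outgoing` restricts to downstream
neighbors) holds between `min_neighbors = 5` and
`max_neighbor_fraction · |V|` (default 0.2) nodes — tiny neighborhoods
carry no signal and near-global ones are uninformative. The observed score
of a disease set is the summed within-subnetwork strength of its genes
inside the neighborhood, where a node's strength is the total weight of
subnetwork edges incident to it; at unit weights this reduces to
degree-weighted overlap counting, and doubling all weights scales score
and null identically, leaving p-values unchanged (tested). The null
reassigns the disease labels uniformly over all non-hub nodes; the
permutation is *not* degree-stratified — a deliberate simplicity/testability
trade-off, since the exact small-instance enumeration and hypergeometric
expectations used as oracles hold only for uniform relabeling. Fold
enrichment is the observed score over the null mean. Significant key
drivers within a gene set are single-linkage grouped as co-hubs wherever
their neighborhoods' overlap coefficient is ≥ 0.5, labelled by the
smallest-p member, and the top 5 drivers per set are flagged for the
summary table and the Cytoscape export.

## Synthetic studies

The generators emulate exactly the features the pipeline's contracts
depend on, with defaults describing a scaled-down GWAS-style study:
5,000 markers with `−log10 U(0,1)` values mapped round-robin onto 500
genes (10 markers per gene), 100 gene sets of 20 random genes,
adjacent-marker dependency blocks (block size 2, full strength), a planted
set whose member markers carry a `+2` location shift with probability 0.5
(p-values ~100× stronger than background — a strong but realistic
polygenic pathway signal), and a planted network hub wired to 80 % of the
disease genes over an Erdős–Rényi background of density 0.02 on 200 nodes
with `U(0.5, 4)` weights. Round-robin assignment gives uniform gene sizes,
separating size-bias effects from signal effects. What the generators do
*not* emulate: realistic LD decay (the block model suffices for the
pruning contract), marker-count heterogeneity across genes, gene-set size
distributions, scale-free network topology, or correlated gene sets —
passing tests therefore demonstrate the machinery's correctness and
calibration under exchangeability, not field performance on real cohorts.
All generators are pure functions of `(spec, seed)`.

## Numerical choices and degenerate inputs

Sorting ties anywhere break lexicographically by ID, so outputs are
byte-reproducible. Gaussian p-values are clamped to `(0, 1]`. Zero null
variance raises rather than silently returning p = 1. A gene set as large
as the indexed gene pool cannot be gene-permuted and raises; a disease set
with no genes in the network raises; empty results produce headers-only
output tables. Random subsets are drawn by arg-partitioning uniform keys,
chunked to bound memory.

## Known limitations

- The Gaussian-tail p is anti-conservative in the extreme tail for skewed
  nulls; ranking is unaffected, but very small p-values should be read as
  ranks, not calibrated probabilities.
- Shared nulls across same-size sets induce weak dependence among
  p-values (not bias); FDR control is unaffected in expectation.
- The uniform relabeling null for wKDA ignores degree structure; hubs in
  degree-heterogeneous networks whose neighborhoods contain other hubs may
  be flagged for topology rather than biology.
- No ortholog or ID harmonization: gene identifiers must already agree
  across the association mapping, gene sets and network.
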