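"""Marker-set enrichment analysis (MSEA).

Tests whether the markers mapped to a gene set are over-represented among
strong associations.  Marker -log10 p-values are mapped to genes, a
multi-threshold enrichment statistic is computed per gene set, and its
significance is assessed against a permutation null (resampled gene sets by
default, or shuffled marker values), with Benjamini-Hochberg FDR across all
tested sets.  Significant, overlapping sets can be merged into
non-redundant supersets.

The enrichment statistic for a gene set with m unique mapped markers is

    X = sum_q (O_q - E_q) / sqrt(E_q + kappa)

where, at each quantile level q of the marker-value distribution, O_q is
the number of the set's markers at or above the corresponding value cutoff,
E_q = m * M_q / N its expectation under uniform sampling from the N-marker
universe (M_q markers at or above the cutoff), and kappa a small stabilizer
guarding the sparse top quantiles.  A set equal to the whole universe gives
X = 0 exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import (
    GeneSetCollection,
    MarkerAssociation,
    MarkerGeneMap,
)

log = logging.getLogger(__name__)

DEFAULT_QUANTILE_LEVELS = (0.5, 0.75, 0.9, 0.95, 0.99)


@dataclass(frozen=True)
class MseaConfig:
    """Parameters of marker-set enrichment analysis.

    permutation_type
        ``"gene"`` resamples gene sets of equal gene count (each gene keeps
        its own markers); ``"marker"`` shuffles the value column over the
        marker universe.  Gene-level permutation is the default: it
        preserves the per-gene marker structure and is more robust to
        uneven marker coverage.
    quantile_levels / kappa
        Value cutoffs of the enrichment statistic and its variance
        stabilizer.
    min_genes / max_genes
        Size filter on the number of *indexed* genes a set must have to be
        tested.
    fdr_cutoff / merge_overlap
        Significance cutoff for reporting / superset merging, and the
        minimum overlap coefficient at which two significant sets merge.
    """

    permutation_type: str = "gene"
    n_permutations: int = 10_000
    quantile_levels: tuple[float, ...] = DEFAULT_QUANTILE_LEVELS
    kappa: float = 1.0
    min_genes: int = 10
    max_genes: int = 500
    fdr_cutoff: float = 0.25
    merge_overlap: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.permutation_type not in ("gene", "marker"):
            raise ValueError("permutation_type must be 'gene' or 'marker'")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        levels = tuple(self.quantile_levels)
        if any(not 0.0 < q < 1.0 for q in levels) or list(levels) != sorted(levels):
            raise ValueError("quantile_levels must be ascending reals in (0, 1)")


@dataclass(frozen=True, eq=False)
class GeneMarkerIndex:
    """Genes with their mapped, scored markers over a common universe.

    ``marker_ids``/``marker_values`` define the universe (every distinct
    marker that is both scored and mapped); ``gene_marker_idx[i]`` holds
    the universe positions of gene ``genes[i]``'s markers.  A marker may
    appear under several genes.
    """

    marker_ids: np.ndarray
    marker_values: np.ndarray
    genes: np.ndarray
    gene_marker_idx: list[np.ndarray]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def has_shared_markers(self) -> bool:
        return sum(len(ix) for ix in self.gene_marker_idx) > self.n_markers


@dataclass(frozen=True, eq=False)
class EnrichmentResult:
    """Per-gene-set enrichment outcome."""

    module_id: str
    statistic: float
    p_value: float
    empirical_p: float
    fdr: float
    n_genes: int
    n_markers: int
    density_ratio: float
    top_genes: tuple[str, ...]
    top_markers: tuple[tuple[str, float], ...]
    description: str = ""
    gene_details: pd.DataFrame | None = None  # GENE, NMARKERS, TOP_MARKER, TOP_VALUE


def build_index(
    assoc: MarkerAssociation, mapping: MarkerGeneMap
) -> GeneMarkerIndex:
    """Join association values onto the marker-gene mapping.

    The universe is the set of distinct markers that are both scored and
    mapped; genes with no scored marker are absent from the index.
    """
    pairs = mapping.pairs
    scored = pairs[pairs["MARKER"].isin(assoc.markers)]
    if scored.empty:
        raise ValueError("no overlap between association markers and mapping")
    marker_ids = np.sort(scored["MARKER"].unique())
    pos = pd.Series(np.arange(len(marker_ids)), index=marker_ids)
    marker_values = assoc.values.loc[marker_ids].to_numpy(dtype=float)
    by_gene = scored.groupby("GENE")["MARKER"]
    genes = np.array(sorted(by_gene.groups))
    gene_marker_idx = [
        np.sort(pos.loc[by_gene.get_group(g)].to_numpy()) for g in genes
    ]
    return GeneMarkerIndex(marker_ids, marker_values, genes, gene_marker_idx)


def quantile_cutoffs(
    index: GeneMarkerIndex, quantile_levels: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Value cutoffs c_q and top-tail counts M_q for each quantile level.

    c_q is the smallest observed value v such that the fraction of universe
    markers >= v is at most 1 - q; M_q is the count of markers >= c_q.
    When heavy ties leave no qualifying value the largest observed value is
    used.  Cutoffs are non-decreasing in q.
    """
    values = index.marker_values
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("degenerate marker universe: constant values")
    n = len(values)
    sorted_vals = np.sort(values)
    first_idx = np.searchsorted(sorted_vals, uniq, side="left")
    cutoffs = np.empty(len(quantile_levels))
    counts = np.empty(len(quantile_levels), dtype=int)
    for j, q in enumerate(quantile_levels):
        ok = np.flatnonzero(first_idx >= n * q)
        i = ok[0] if len(ok) else len(uniq) - 1
        cutoffs[j] = uniq[i]
        counts[j] = n - first_idx[i]
    return cutoffs, counts


def _statistic_from_counts(
    m: np.ndarray | float,
    o: np.ndarray,
    tail_counts: np.ndarray,
    n_universe: int,
    kappa: float,
) -> np.ndarray | float:
    expected = np.multiply.outer(np.asarray(m, dtype=float), tail_counts / n_universe)
    x = ((o - expected) / np.sqrt(expected + kappa)).sum(axis=-1)
    return x if getattr(x, "ndim", 0) else float(x)


def _module_marker_idx(
    module_genes: Sequence[str], index: GeneMarkerIndex
) -> np.ndarray:
    pos = {g: i for i, g in enumerate(index.genes)}
    parts = [index.gene_marker_idx[pos[g]] for g in module_genes if g in pos]
    if not parts:
        raise ValueError("gene set has no indexed genes")
    return np.unique(np.concatenate(parts))


def enrichment_statistic(
    module_genes: Sequence[str],
    index: GeneMarkerIndex,
    cutoffs: np.ndarray,
    tail_counts: np.ndarray,
    kappa: float = 1.0,
) -> float:
    """Multi-threshold standardized excess of strong markers in a gene set.

    Markers shared between the set's genes are counted once.
    """
    idx = _module_marker_idx(module_genes, index)
    vals = index.marker_values[idx]
    o = (vals[:, None] >= cutoffs[None, :]).sum(axis=0)
    return float(
        _statistic_from_counts(len(idx), o, tail_counts, index.n_markers, kappa)
    )


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def _gene_count_matrix(
    index: GeneMarkerIndex, cutoffs: np.ndarray
) -> np.ndarray:
    """Per-gene [marker count, counts >= each cutoff]; valid for summing
    across genes only when no marker is shared between genes."""
    a = np.empty((index.n_genes, 1 + len(cutoffs)))
    for i, idx in enumerate(index.gene_marker_idx):
        vals = index.marker_values[idx]
        a[i, 0] = len(idx)
        a[i, 1:] = (vals[:, None] >= cutoffs[None, :]).sum(axis=0)
    return a


def _sample_subsets(
    rng: np.random.Generator, n_draws: int, pool: int, k: int
) -> np.ndarray:
    """(n_draws, k) index matrix of uniform subsets without replacement."""
    r = rng.random((n_draws, pool))
    if k >= pool:
        return np.tile(np.arange(pool), (n_draws, 1))
    return np.argpartition(r, k, axis=1)[:, :k]


def permutation_null(
    size: int,
    index: GeneMarkerIndex,
    config: MseaConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null sample of the enrichment statistic for a set of given size.

    ``size`` is the gene count of the set under gene-level permutation and
    its unique marker count under marker-level permutation.  Gene mode
    draws random gene sets from all indexed genes, each gene carrying its
    markers intact; marker mode redistributes the value column over the
    marker universe while gene membership is fixed.
    """
    nperm = config.n_permutations
    if nperm < 100:
        raise ValueError("n_permutations must be >= 100")
    cutoffs, tail_counts = quantile_cutoffs(index, config.quantile_levels)
    n = index.n_markers
    kappa = config.kappa
    if config.permutation_type == "gene":
        if size >= index.n_genes:
            raise ValueError(
                "gene permutation needs the set's gene count below the "
                "number of indexed genes"
            )
        if not index.has_shared_markers:
            counts = _gene_count_matrix(index, cutoffs)
            out = np.empty(nperm)
            done = 0
            chunk = max(1, min(nperm, 20_000_000 // max(index.n_genes, 1)))
            while done < nperm:
                c = min(chunk, nperm - done)
                picks = _sample_subsets(rng, c, index.n_genes, size)
                sums = counts[picks].sum(axis=1)
                out[done : done + c] = _statistic_from_counts(
                    sums[:, 0], sums[:, 1:], tail_counts, n, kappa
                )
                done += c
            return out
        # markers shared between genes: form the union explicitly
        out = np.empty(nperm)
        for i in range(nperm):
            picks = rng.choice(index.n_genes, size=size, replace=False)
            idx = np.unique(
                np.concatenate([index.gene_marker_idx[j] for j in picks])
            )
            vals = index.marker_values[idx]
            o = (vals[:, None] >= cutoffs[None, :]).sum(axis=0)
            out[i] = _statistic_from_counts(len(idx), o, tail_counts, n, kappa)
        return out
    # marker-level permutation: the set keeps m marker slots, values are
    # shuffled over the universe, i.e. m values sampled without replacement
    m = size
    if not 1 <= m <= n:
        raise ValueError("marker count outside the universe size")
    out = np.empty(nperm)
    done = 0
    chunk = max(1, min(nperm, 20_000_000 // n))
    while done < nperm:
        c = min(chunk, nperm - done)
        picks = _sample_subsets(rng, c, n, m)
        vals = index.marker_values[picks]
        o = (vals[:, :, None] >= cutoffs[None, None, :]).sum(axis=1)
        out[done : done + c] = _statistic_from_counts(
            float(m), o, tail_counts, n, kappa
        )
        done += c
    return out


def pvalue_from_null(
    observed: float, null_sample: np.ndarray
) -> tuple[float, float]:
    """Gaussian-tail and plus-one empirical p against a permutation null.

    The Gaussian p (upper tail of a normal fitted to the null) resolves
    values below 1/n_permutations, which the FDR ranking needs; the
    empirical p is the (1 + #{null >= obs}) / (1 + n) estimator.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if len(null_sample) < 100:
        raise ValueError("null sample too small (< 100)")
    mean = float(null_sample.mean())
    sd = float(null_sample.std(ddof=1))
    if sd == 0.0:
        raise ValueError("null sample has zero variance")
    gauss = float(stats.norm.sf((observed - mean) / sd))
    gauss = min(max(gauss, np.nextafter(0.0, 1.0)), 1.0)
    empirical = (1.0 + int((null_sample >= observed).sum())) / (
        1.0 + len(null_sample)
    )
    return gauss, empirical


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------


def _gene_detail_frame(
    module_genes: Sequence[str], index: GeneMarkerIndex
) -> pd.DataFrame:
    pos = {g: i for i, g in enumerate(index.genes)}
    rows = []
    for g in module_genes:
        idx = index.gene_marker_idx[pos[g]]
        vals = index.marker_values[idx]
        ids = index.marker_ids[idx]
        # top marker: max value, ties broken by marker ID
        order = np.lexsort((ids, -vals))
        rows.append((g, len(idx), ids[order[0]], float(vals[order[0]])))
    return pd.DataFrame(
        rows, columns=["GENE", "NMARKERS", "TOP_MARKER", "TOP_VALUE"]
    )


def run_msea(
    assoc: MarkerAssociation,
    mapping: MarkerGeneMap,
    genesets: GeneSetCollection,
    config: MseaConfig | None = None,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Score every gene set passing the size filter; permutation p + FDR.

    Null samples are drawn once per distinct set size and reused across
    sets of that size (the gene-permutation null depends only on the gene
    count, the marker-permutation null only on the marker count).
    Results are sorted by ascending p, ties broken by module ID.
    """
    config = config or MseaConfig()
    rng = np.random.default_rng(seed)
    index = build_index(assoc, mapping)
    cutoffs, tail_counts = quantile_cutoffs(index, config.quantile_levels)
    indexed = set(index.genes)

    tested: list[tuple[str, list[str]]] = []
    for module in genesets:
        genes = sorted(g for g in genesets[module] if g in indexed)
        if config.min_genes <= len(genes) <= config.max_genes:
            tested.append((module, genes))
    if not tested:
        raise ValueError(
            "no gene set passes the size filter "
            f"[{config.min_genes}, {config.max_genes}]"
        )
    log.info("testing %d of %d gene sets", len(tested), len(genesets))

    null_cache: dict[int, np.ndarray] = {}
    stats_rows = []
    for module, genes in tested:
        idx = _module_marker_idx(genes, index)
        vals = index.marker_values[idx]
        o = (vals[:, None] >= cutoffs[None, :]).sum(axis=0)
        x = float(
            _statistic_from_counts(
                len(idx), o, tail_counts, index.n_markers, config.kappa
            )
        )
        size = len(genes) if config.permutation_type == "gene" else len(idx)
        if size not in null_cache:
            null_cache[size] = permutation_null(size, index, config, rng)
        p, emp = pvalue_from_null(x, null_cache[size])
        stats_rows.append((module, genes, idx, x, p, emp))

    fdr = benjamini_hochberg([row[4] for row in stats_rows])
    results = []
    for (module, genes, idx, x, p, emp), q in zip(stats_rows, fdr):
        vals = index.marker_values[idx]
        ids = index.marker_ids[idx]
        order = np.lexsort((ids, -vals))[:3]
        top_markers = tuple((ids[i], float(vals[i])) for i in order)
        details = _gene_detail_frame(genes, index)
        gorder = details.sort_values(
            ["TOP_VALUE", "GENE"], ascending=[False, True], kind="mergesort"
        )
        results.append(
            EnrichmentResult(
                module_id=module,
                statistic=x,
                p_value=p,
                empirical_p=emp,
                fdr=float(q),
                n_genes=len(genes),
                n_markers=len(idx),
                density_ratio=len(idx) / index.n_markers,
                top_genes=tuple(gorder["GENE"].head(3)),
                top_markers=top_markers,
                description=genesets.description(module),
                gene_details=details,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.module_id))
    return results


def merge_supersets(
    results: Sequence[EnrichmentResult],
    genesets: GeneSetCollection,
    fdr_cutoff: float = 0.25,
    merge_overlap: float = 1.0 / 3.0,
) -> GeneSetCollection:
    """Merge significant, overlapping gene sets into non-redundant supersets.

    Among sets with FDR below ``fdr_cutoff``, the pair with the highest
    overlap coefficient |A∩B| / min(|A|, |B|) is merged repeatedly while
    that coefficient is at least ``merge_overlap``; the returned supersets
    are pairwise below the threshold.  Merged IDs join the constituent IDs
    with '+'.  Re-score the merged collection with :func:`run_msea`.
    """
    current: dict[str, frozenset[str]] = {
        r.module_id: genesets[r.module_id]
        for r in results
        if r.fdr < fdr_cutoff and r.module_id in genesets
    }
    if not current:
        return GeneSetCollection.from_dict({})

    def coefficient(a: frozenset[str], b: frozenset[str]) -> float:
        return len(a & b) / min(len(a), len(b))

    while len(current) > 1:
        best: tuple[float, str, str] | None = None
        names = sorted(current)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                c = coefficient(current[a], current[b])
                if best is None or c > best[0]:
                    best = (c, a, b)
        if best is None or best[0] < merge_overlap:
            break
        _, a, b = best
        merged_id = "+".join(sorted(a.split("+") + b.split("+")))
        merged = current.pop(a) | current.pop(b)
        current[merged_id] = merged
    info = {
        m: ("merged", f"superset of {m.count('+') + 1} gene sets")
        if "+" in m
        else (genesets.source(m), genesets.description(m))
        for m in current
    }
    return GeneSetCollection.from_dict(current, info)
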