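"""Weighted key driver analysis (wKDA).

Screens a weighted molecular network for candidate hub genes and tests
whether each hub's depth-limited neighborhood is enriched for disease
genes, honoring edge weights and (optionally) edge direction.

For a hub h with neighborhood N(h), define the within-subnetwork strength
of a node g as the summed weight of edges with both endpoints inside
{h} ∪ N(h) that touch g.  The observed score of a disease gene set D is

    O = sum_{g in D ∩ N(h)} s(g),

which at unit weights reduces to counting disease neighbors weighted by
their within-subnetwork degree.  Significance comes from re-assigning the
|D| disease labels uniformly at random over all non-hub nodes and refitting
a normal to the resulting null scores (upper-tail p); fold enrichment is
O divided by the null mean.  Key drivers with highly overlapping
neighborhoods are grouped into co-hub clusters so independent regulators
can be read off directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .io_tables import GeneSetCollection, WeightedNetwork
from .msea import benjamini_hochberg

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WkdaConfig:
    """Parameters of weighted key driver analysis.

    depth
        Number of edge layers expanded from a hub to form its neighborhood.
    direction_mode
        ``"both"`` ignores edge direction; ``"outgoing"`` requires the hub
        to be upstream of its neighbors (directed networks only).
    min_neighbors / max_neighbor_fraction
        Hub screening bounds on neighborhood size (absolute lower bound,
        upper bound as a fraction of the node count) — tiny neighborhoods
        carry no signal, near-global ones are uninformative.
    cohub_overlap
        Minimum neighborhood overlap coefficient at which two significant
        key drivers are grouped as co-hubs.
    top_k
        Number of best key drivers reported per gene set (summary and
        Cytoscape export).
    """

    depth: int = 1
    direction_mode: str = "both"
    n_permutations: int = 2_000
    min_neighbors: int = 5
    max_neighbor_fraction: float = 0.2
    fdr_cutoff: float = 0.25
    cohub_overlap: float = 0.5
    top_k: int = 5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.direction_mode not in ("both", "outgoing"):
            raise ValueError("direction_mode must be 'both' or 'outgoing'")
        if not 0.0 < self.max_neighbor_fraction <= 1.0:
            raise ValueError("max_neighbor_fraction must lie in (0, 1]")


@dataclass(frozen=True, eq=False)
class KDResult:
    """Per (candidate hub, gene set) outcome."""

    kd_gene: str
    module_id: str
    neighborhood_size: int
    overlap_count: int
    observed_score: float
    fold_enrichment: float
    p_value: float
    empirical_p: float
    fdr: float
    cohub_group: str | None = None
    is_top: bool = False
    neighborhood: frozenset[str] = frozenset()


def build_neighborhood(
    network: WeightedNetwork,
    node: str,
    depth: int = 1,
    direction_mode: str = "both",
) -> frozenset[str]:
    """Nodes reachable from ``node`` within ``depth`` edges (node excluded).

    ``outgoing`` follows edge direction only; ``both`` ignores it.
    """
    g = network.to_networkx()
    if node not in g:
        raise ValueError(f"node {node!r} not in network")
    if direction_mode == "both" and g.is_directed():
        g = g.to_undirected(as_view=True)
    reach = nx.single_source_shortest_path_length(g, node, cutoff=depth)
    return frozenset(n for n in reach if n != node)


def screen_hubs(
    network: WeightedNetwork, config: WkdaConfig | None = None
) -> list[str]:
    """Candidate hubs: nodes whose neighborhood size lies inside the
    screening bounds; sorted by node ID."""
    config = config or WkdaConfig()
    nodes = network.nodes
    if not nodes:
        raise ValueError("network is empty")
    upper = config.max_neighbor_fraction * len(nodes)
    out = []
    for node in nodes:
        size = len(
            build_neighborhood(network, node, config.depth, config.direction_mode)
        )
        if config.min_neighbors <= size <= upper:
            out.append(node)
    if not out:
        raise ValueError(
            "no candidate hubs; relax min_neighbors / max_neighbor_fraction"
        )
    return out


def _subnetwork_strengths(
    network: WeightedNetwork, hub: str, neighborhood: frozenset[str]
) -> dict[str, float]:
    """Within-subnetwork node strength over {hub} ∪ neighborhood."""
    sub = set(neighborhood) | {hub}
    strengths: dict[str, float] = {n: 0.0 for n in sub}
    inside = network.edges["TAIL"].isin(sub) & network.edges["HEAD"].isin(sub)
    for tail, head, w in network.edges.loc[inside].itertuples(index=False):
        strengths[tail] += float(w)
        strengths[head] += float(w)
    return strengths


def kd_score(
    network: WeightedNetwork,
    hub: str,
    neighborhood: frozenset[str],
    disease_genes: Iterable[str],
) -> tuple[float, int]:
    """Observed score: summed within-subnetwork strength of the disease
    genes inside the hub's neighborhood; also the plain overlap count."""
    strengths = _subnetwork_strengths(network, hub, neighborhood)
    overlap = set(disease_genes) & set(neighborhood)
    return sum(strengths[g] for g in overlap), len(overlap)


def kd_permutation_null(
    network: WeightedNetwork,
    hub: str,
    neighborhood: frozenset[str],
    n_disease: int,
    config: WkdaConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, float]:
    """Null score sample: disease labels re-assigned uniformly at random
    over all nodes except the hub.  Returns (sample, mean, sd)."""
    config = config or WkdaConfig()
    rng = rng if rng is not None else np.random.default_rng()
    nodes = [n for n in network.nodes if n != hub]
    if n_disease > len(nodes):
        raise ValueError("more disease labels than non-hub nodes")
    strengths = _subnetwork_strengths(network, hub, neighborhood)
    svals = np.array(
        [strengths.get(n, 0.0) if n in neighborhood else 0.0 for n in nodes]
    )
    nperm = config.n_permutations
    out = np.empty(nperm)
    done = 0
    chunk = max(1, min(nperm, 20_000_000 // max(len(nodes), 1)))
    while done < nperm:
        c = min(chunk, nperm - done)
        r = rng.random((c, len(nodes)))
        if n_disease >= len(nodes):
            picks = np.tile(np.arange(len(nodes)), (c, 1))
        else:
            picks = np.argpartition(r, n_disease, axis=1)[:, :n_disease]
        out[done : done + c] = svals[picks].sum(axis=1)
        done += c
    mean = float(out.mean())
    sd = float(out.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate null: zero variance in permuted scores")
    return out, mean, sd


def run_wkda(
    network: WeightedNetwork,
    genesets: GeneSetCollection,
    config: WkdaConfig | None = None,
    seed: int | None = None,
) -> list[KDResult]:
    """Score every (candidate hub, gene set) pair; permutation p + FDR.

    Disease genes absent from the network are dropped (logged); a gene set
    with zero network overlap raises.  The null for a hub is drawn once per
    distinct disease-set size and reused.  Per gene set, the ``top_k`` best
    key drivers among those passing the FDR cutoff are flagged for the
    summary, and co-hub groups are filled in.
    """
    config = config or WkdaConfig()
    rng = np.random.default_rng(seed)
    node_set = set(network.nodes)

    module_genes: dict[str, frozenset[str]] = {}
    for module in genesets:
        present = genesets[module] & node_set
        dropped = len(genesets[module]) - len(present)
        if dropped:
            log.info(
                "gene set %s: %d of %d genes absent from the network",
                module, dropped, len(genesets[module]),
            )
        if not present:
            raise ValueError(
                f"gene set {module} has no genes in the network"
            )
        module_genes[module] = frozenset(present)
    if not module_genes:
        raise ValueError("no disease gene sets supplied")

    hubs = screen_hubs(network, config)
    log.info("screened %d candidate hubs", len(hubs))
    neighborhoods = {
        h: build_neighborhood(network, h, config.depth, config.direction_mode)
        for h in hubs
    }

    rows = []
    null_cache: dict[tuple[str, int], tuple[float, float, np.ndarray]] = {}
    for hub in hubs:
        nbh = neighborhoods[hub]
        for module in sorted(module_genes):
            disease = module_genes[module]
            observed, overlap = kd_score(network, hub, nbh, disease)
            key = (hub, len(disease))
            if key not in null_cache:
                sample, mean, sd = kd_permutation_null(
                    network, hub, nbh, len(disease), config, rng
                )
                null_cache[key] = (mean, sd, sample)
            mean, sd, sample = null_cache[key]
            p = float(stats.norm.sf((observed - mean) / sd))
            p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
            emp = (1.0 + int((sample >= observed).sum())) / (1.0 + len(sample))
            if mean > 0:
                fold = observed / mean
            else:
                fold = float("inf") if observed > 0 else 0.0
            rows.append((hub, module, nbh, overlap, observed, fold, p, emp))

    fdr = benjamini_hochberg([r[6] for r in rows])
    results = [
        KDResult(
            kd_gene=hub,
            module_id=module,
            neighborhood_size=len(nbh),
            overlap_count=overlap,
            observed_score=observed,
            fold_enrichment=fold,
            p_value=p,
            empirical_p=emp,
            fdr=float(q),
            neighborhood=nbh,
        )
        for (hub, module, nbh, overlap, observed, fold, p, emp), q in zip(rows, fdr)
    ]
    results.sort(key=lambda r: (r.p_value, r.module_id, r.kd_gene))

    # flag the top_k significant KDs per gene set for the summary
    flagged = []
    per_module_rank: dict[str, int] = {}
    for r in results:
        if r.fdr < config.fdr_cutoff:
            rank = per_module_rank.get(r.module_id, 0)
            if rank < config.top_k:
                per_module_rank[r.module_id] = rank + 1
                r = replace(r, is_top=True)
        flagged.append(r)
    return group_cohubs(flagged, network, config)


def group_cohubs(
    results: Sequence[KDResult],
    network: WeightedNetwork,
    config: WkdaConfig | None = None,
) -> list[KDResult]:
    """Single-linkage co-hub grouping of significant KDs per gene set.

    Two key drivers join a group whenever their neighborhoods' overlap
    coefficient is at least ``cohub_overlap``; each group is labelled by
    its smallest-p member (ties broken by gene ID).
    """
    config = config or WkdaConfig()
    out = list(results)
    by_module: dict[str, list[int]] = {}
    for i, r in enumerate(out):
        if r.fdr < config.fdr_cutoff:
            by_module.setdefault(r.module_id, []).append(i)

    def coefficient(a: frozenset[str], b: frozenset[str]) -> float:
        if not a or not b:
            return 0.0
        return len(a & b) / min(len(a), len(b))

    for module, idxs in by_module.items():
        # union-find over the significant KDs of this gene set
        parent = {i: i for i in idxs}

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                if (
                    coefficient(out[i].neighborhood, out[j].neighborhood)
                    >= config.cohub_overlap
                ):
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in idxs:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            rep = min(members, key=lambda i: (out[i].p_value, out[i].kd_gene))
            label = out[rep].kd_gene
            for i in members:
                out[i] = replace(out[i], cohub_group=label)
    return out
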