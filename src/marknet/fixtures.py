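"""Seeded synthetic study generators with known ground truth.

Emulates the shape of the data the pipeline consumes — GWAS-like
association summaries (uniform p-values under the null, an additive
-log10 shift for planted signal markers), block-structured marker
dependencies standing in for LD blocks, gene-set collections with one
planted enriched module, and networks with a planted disease hub — so
every stage is testable without external downloads.  All generators are
pure functions of their spec (seed included): reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .io_tables import (
    GeneSetCollection,
    MarkerAssociation,
    MarkerDependency,
    MarkerGeneMap,
    WeightedNetwork,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study-generation parameters.

    The defaults describe a scaled-down GWAS-style study: 5,000 markers
    mapped round-robin onto 500 genes (10 markers per gene), 100 gene sets
    of 20 genes, adjacent-marker dependency blocks of 2 at full strength,
    and a planted module in which half the markers carry a +2 shift on the
    -log10 p scale (p-values ~100x stronger than the null background).
    """

    n_markers: int = 5_000
    n_genes: int = 500
    n_modules: int = 100
    module_size: int = 20
    block_size: int = 2
    block_strength: float = 1.0
    signal_fraction: float = 0.5
    signal_shift: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_markers, self.n_genes, self.n_modules, self.module_size) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if not 0.0 <= self.block_strength <= 1.0:
            raise ValueError("block_strength must lie in [0, 1]")
        if self.signal_shift < 0:
            raise ValueError("signal_shift must be >= 0")


@dataclass(frozen=True)
class PlantedModuleTruth:
    """Ground truth of a planted-module study."""

    module_id: str
    signal_markers: frozenset[str]
    assoc: MarkerAssociation  # association data with the signal injected


@dataclass(frozen=True)
class PlantedHubTruth:
    """Ground truth of a planted-hub network."""

    hub: str
    wired_disease_genes: frozenset[str]


def _marker_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"rs{i:0{width}d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def gen_null_study(spec: FixtureSpec) -> tuple[MarkerAssociation, MarkerGeneMap]:
    """Null study: -log10 of i.i.d. uniform(0,1) p-values, markers assigned
    to genes round-robin (uniform gene sizes)."""
    rng = np.random.default_rng(spec.seed)
    markers = _marker_ids(spec.n_markers)
    genes = _gene_ids(spec.n_genes)
    values = -np.log10(rng.uniform(size=spec.n_markers))
    assoc = MarkerAssociation.from_records(markers, values)
    mapping = MarkerGeneMap.from_pairs(
        (markers[i], genes[i % spec.n_genes]) for i in range(spec.n_markers)
    )
    return assoc, mapping


def gen_dependency_blocks(spec: FixtureSpec) -> MarkerDependency:
    """Block dependency structure: consecutive markers grouped into blocks
    of ``block_size``; every within-block pair carries ``block_strength``,
    no between-block pairs."""
    if spec.block_size < 2:
        raise ValueError("block_size must be >= 2")
    markers = _marker_ids(spec.n_markers)
    pairs = []
    for start in range(0, spec.n_markers, spec.block_size):
        block = markers[start : start + spec.block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                pairs.append((block[i], block[j], spec.block_strength))
    return MarkerDependency.from_pairs(pairs)


def gen_planted_module(
    spec: FixtureSpec, study: tuple[MarkerAssociation, MarkerGeneMap]
) -> tuple[GeneSetCollection, PlantedModuleTruth]:
    """Gene-set collection with one planted enriched module.

    All modules are random gene draws of ``module_size``; in the planted
    one, each member gene's markers independently receive a +signal_shift
    on the -log10 scale with probability ``signal_fraction``.  The truth
    record carries the modified association data.
    """
    if spec.module_size > spec.n_genes:
        raise ValueError("module_size exceeds n_genes")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    assoc, mapping = study
    genes = _gene_ids(spec.n_genes)
    width = len(str(spec.n_modules))
    sets = {
        f"mod{i:0{width}d}": [
            genes[j] for j in rng.choice(spec.n_genes, spec.module_size, replace=False)
        ]
        for i in range(1, spec.n_modules + 1)
    }
    planted_id = f"mod{1:0{width}d}"
    planted_genes = set(sets[planted_id])
    member = mapping.pairs["GENE"].isin(planted_genes)
    candidate_markers = sorted(set(mapping.pairs.loc[member, "MARKER"]))
    hit = rng.uniform(size=len(candidate_markers)) < spec.signal_fraction
    signal = frozenset(m for m, h in zip(candidate_markers, hit) if h)
    values = assoc.values.copy()
    values.loc[sorted(signal)] += spec.signal_shift
    shifted = MarkerAssociation(values)
    truth = PlantedModuleTruth(planted_id, signal, shifted)
    return GeneSetCollection.from_dict(sets), truth


def gen_planted_hub_network(
    spec: FixtureSpec,
    disease_genes: Iterable[str],
    hub_fraction: float = 0.8,
    background_density: float = 0.02,
) -> tuple[WeightedNetwork, PlantedHubTruth]:
    """Undirected network with a planted disease hub.

    One designated hub node is wired to ``hub_fraction`` of the disease
    genes; background edges are Erdős–Rényi over all node pairs at
    ``background_density``.  Weights are uniform(0.5, 4.0).
    """
    disease = sorted(set(map(str, disease_genes)))
    if len(disease) < 5:
        raise ValueError("need at least 5 disease genes")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    genes = _gene_ids(spec.n_genes)
    non_disease = [g for g in genes if g not in set(disease)]
    if not non_disease:
        raise ValueError("no non-disease gene available to act as hub")
    hub = non_disease[0]
    n_wired = int(round(hub_fraction * len(disease)))
    wired = [disease[i] for i in rng.choice(len(disease), n_wired, replace=False)]
    edges: dict[tuple[str, str], float] = {}
    for g in wired:
        a, b = min(hub, g), max(hub, g)
        edges[(a, b)] = float(rng.uniform(0.5, 4.0))
    if background_density > 0:
        n = len(genes)
        # vectorized Bernoulli over the upper triangle
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.uniform(size=len(iu)) < background_density
        weights = rng.uniform(0.5, 4.0, size=int(mask.sum()))
        for (i, j), w in zip(zip(iu[mask], ju[mask]), weights):
            key = (genes[i], genes[j])
            edges.setdefault(key, float(w))
    network = WeightedNetwork.from_edges(
        [(a, b, w) for (a, b), w in edges.items()],
        directed=False,
        extra_nodes=genes,
    )
    return network, PlantedHubTruth(hub, frozenset(wired))
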