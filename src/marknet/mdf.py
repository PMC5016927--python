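"""Marker dependency filtering (MDF).

Summary-level association data over dependent markers (SNPs in linkage
disequilibrium, adjacent methylation sites, correlated transcripts) inflates
downstream set-enrichment counts.  MDF restricts the association file to its
strongest markers and then greedily prunes dependent markers so that no two
retained markers exceed a pairwise dependency cutoff; the surviving
association/mapping pair feeds directly into enrichment analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .io_tables import MarkerAssociation, MarkerDependency, MarkerGeneMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MdfConfig:
    """Parameters of marker dependency filtering.

    dependency_cutoff
        Maximum acceptable pairwise dependency (e.g. LD r^2) between any
        two retained markers; pairs strictly above it are pruned.
    top_fraction
        Share of markers (by association value) kept before pruning, to
        raise the signal-to-noise ratio of the weak-association tail.
    """

    dependency_cutoff: float = 0.7
    top_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dependency_cutoff <= 1.0:
            raise ValueError("dependency_cutoff must lie in [0, 1]")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")


def filter_top_fraction(
    assoc: MarkerAssociation, top_fraction: float
) -> MarkerAssociation:
    """Keep the ceil(top_fraction * n) markers with the largest values.

    Boundary ties are broken by marker ID (lexicographic) so the result is
    deterministic.
    """
    if len(assoc) == 0:
        raise ValueError("association data is empty")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    k = math.ceil(top_fraction * len(assoc))
    order = assoc.values.sort_index().sort_values(
        ascending=False, kind="mergesort"
    )
    kept = order.iloc[:k].sort_index()
    return MarkerAssociation(kept.rename("VALUE").rename_axis("MARKER"))


def prune_dependencies(
    assoc: MarkerAssociation, deps: MarkerDependency, cutoff: float
) -> MarkerAssociation:
    """Greedy keep-best pruning of dependent markers.

    Markers are visited in descending association value (ties broken by
    ID); a marker is retained iff no already-retained marker is linked to
    it with strength strictly above ``cutoff``.  Hence no retained pair
    exceeds the cutoff and every removed marker is dependent on a retained
    marker of greater or equal value.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    markers = set(assoc.markers)
    strong = deps.pairs[deps.pairs["STRENGTH"] > cutoff]
    known = strong["MARKER"].isin(markers) & strong["MARKER2"].isin(markers)
    n_unknown = len(strong) - int(known.sum())
    if n_unknown:
        log.info(
            "%d dependency pairs reference markers absent from the "
            "association data; ignored",
            n_unknown,
        )
    adj: dict[str, set[str]] = {}
    for a, b in strong.loc[known, ["MARKER", "MARKER2"]].itertuples(index=False):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    order = assoc.values.sort_index().sort_values(
        ascending=False, kind="mergesort"
    )
    kept: set[str] = set()
    for marker in order.index:
        if adj.get(marker, frozenset()).isdisjoint(kept):
            kept.add(marker)
    result = assoc.values.loc[sorted(kept)]
    log.info("pruning kept %d of %d markers", len(result), len(assoc))
    return MarkerAssociation(result.rename("VALUE").rename_axis("MARKER"))


def run_mdf(
    assoc: MarkerAssociation,
    mapping: MarkerGeneMap,
    deps: MarkerDependency,
    config: MdfConfig | None = None,
) -> tuple[MarkerAssociation, MarkerGeneMap]:
    """Top-fraction filter, then dependency pruning; restrict the mapping.

    Returns the pruned association data and the marker-gene mapping
    restricted to the surviving markers, both directly consumable by
    enrichment analysis.
    """
    config = config or MdfConfig()
    filtered = filter_top_fraction(assoc, config.top_fraction)
    pruned = prune_dependencies(filtered, deps, config.dependency_cutoff)
    if len(pruned) == 0:
        raise ValueError(
            "no markers survive filtering; relax dependency_cutoff or "
            "top_fraction"
        )
    return pruned, mapping.restrict_markers(pruned.markers)
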