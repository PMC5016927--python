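from io import StringIO

import pytest

import marknet as mk


def table(*rows: str) -> StringIO:
    """Build an in-memory tab-separated table from readable row specs."""
    return StringIO("\n".join(r.replace(" ", "\t") for r in rows) + "\n")


@pytest.fixture
def ladder_index() -> mk.GeneMarkerIndex:
    """Ten one-marker genes with values 1..10 (the hand-checkable universe)."""
    assoc = mk.MarkerAssociation.from_records(
        [f"rs{i:02d}" for i in range(1, 11)], [float(i) for i in range(1, 11)]
    )
    mapping = mk.MarkerGeneMap.from_pairs(
        [(f"rs{i:02d}", f"g{i:02d}") for i in range(1, 11)]
    )
    return mk.build_index(assoc, mapping)


@pytest.fixture
def star_network() -> mk.WeightedNetwork:
    """Unit-weight star (center h, 4 spokes) plus 5 isolated extras."""
    return mk.WeightedNetwork.from_edges(
        [("h", f"s{i}", 1.0) for i in range(1, 5)],
        directed=False,
        extra_nodes=[f"x{i}" for i in range(1, 6)],
    )
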