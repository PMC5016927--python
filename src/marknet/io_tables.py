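"""Tab-delimited I/O for the marker-set enrichment / key-driver pipeline.

Every file the pipeline touches is plain tab-separated text with a single
header row.  The dialects are:

=====================  =======================================
object                 columns
=====================  =======================================
marker associations    MARKER, VALUE        (VALUE = -log10 p)
marker-gene mapping    MARKER, GENE
marker dependencies    MARKER, MARKER2[, STRENGTH]
gene sets              MODULE, GENE
gene-set descriptions  MODULE, SOURCE, DESCR
weighted network       TAIL, HEAD[, WEIGHT]
=====================  =======================================

Readers canonicalize on ingestion (sorting, de-duplication, symmetry) so
that a write/read round trip is the identity and row order of the input
never matters.  Result writers emit the pipeline's fixed output file set
(``MSEA_*.txt``, ``wKDA_*.txt``) plus Cytoscape-importable node/edge tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import networkx as nx

log = logging.getLogger(__name__)

Source = Union[str, Path, IO[str]]

ASSOCIATION_HEADER = ("MARKER", "VALUE")
MAPPING_HEADER = ("MARKER", "GENE")
DEPENDENCY_HEADER = ("MARKER", "MARKER2", "STRENGTH")
GENESET_HEADER = ("MODULE", "GENE")
DESCRIPTION_HEADER = ("MODULE", "SOURCE", "DESCR")
NETWORK_HEADER = ("TAIL", "HEAD", "WEIGHT")

MSEA_FILES = (
    "MSEA_modules_pval.txt",
    "MSEA_modules_full_results.txt",
    "MSEA_top_modules_details.txt",
    "MSEA_genes_details.txt",
)
WKDA_FILES = (
    "wKDA_kd_pvalues.txt",
    "wKDA_kd_full_results.txt",
    "wKDA_kd_tophits.txt",
    "wKDA_hub_structure.txt",
)


class FormatError(ValueError):
    """Raised when an input table violates its dialect."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class MarkerAssociation:
    """Marker IDs with -log10 association p-values.

    ``values`` is a float Series indexed by unique marker ID, sorted by ID;
    all entries are finite and non-negative.
    """

    values: pd.Series

    @classmethod
    def from_records(
        cls, markers: Iterable[str], values: Iterable[float]
    ) -> "MarkerAssociation":
        s = pd.Series(
            np.asarray(list(values), dtype=float),
            index=pd.Index([str(m) for m in markers], name="MARKER"),
            name="VALUE",
        )
        if s.empty:
            raise FormatError("association data is empty")
        if not np.all(np.isfinite(s.to_numpy())):
            raise FormatError("association values must be finite")
        if (s < 0).any():
            raise FormatError("association values (-log10 p) must be >= 0")
        if (s.index == "").any():
            raise FormatError("empty marker ID")
        # duplicate markers keep the strongest signal
        n0 = len(s)
        s = s.groupby(level=0).max().sort_index()
        if len(s) < n0:
            log.info("collapsed %d duplicate marker rows (kept max)", n0 - len(s))
        return cls(s)

    @property
    def markers(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerAssociation) and self.values.equals(
            other.values
        )


@dataclass(frozen=True, eq=False)
class MarkerGeneMap:
    """Many-to-many marker -> gene mapping (deduplicated, sorted)."""

    pairs: pd.DataFrame  # columns MARKER, GENE

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MarkerGeneMap":
        df = pd.DataFrame(list(pairs), columns=list(MAPPING_HEADER), dtype=str)
        if ((df["MARKER"] == "") | (df["GENE"] == "")).any() or df.isna().any().any():
            raise FormatError("empty marker or gene token in mapping")
        n0 = len(df)
        df = (
            df.drop_duplicates()
            .sort_values(list(MAPPING_HEADER), kind="mergesort")
            .reset_index(drop=True)
        )
        if len(df) < n0:
            log.info("dropped %d duplicate mapping rows", n0 - len(df))
        return cls(df)

    def restrict_markers(self, markers: Iterable[str]) -> "MarkerGeneMap":
        keep = self.pairs["MARKER"].isin(set(markers))
        return MarkerGeneMap(self.pairs.loc[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerGeneMap) and self.pairs.equals(other.pairs)


@dataclass(frozen=True, eq=False)
class MarkerDependency:
    """Symmetric pairwise marker dependencies (e.g. LD r^2) in [0, 1].

    Stored in canonical form: each pair once with the lexicographically
    smaller marker first, rows sorted, self-pairs removed.
    """

    pairs: pd.DataFrame  # columns MARKER, MARKER2, STRENGTH

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, float]]
    ) -> "MarkerDependency":
        rows = list(pairs)
        df = pd.DataFrame(rows, columns=list(DEPENDENCY_HEADER))
        df["MARKER"] = df["MARKER"].astype(str)
        df["MARKER2"] = df["MARKER2"].astype(str)
        df["STRENGTH"] = df["STRENGTH"].astype(float)
        if len(df) and (((df["STRENGTH"] < 0) | (df["STRENGTH"] > 1)).any()):
            raise FormatError("dependency strength must lie in [0, 1]")
        selfpairs = df["MARKER"] == df["MARKER2"]
        if selfpairs.any():
            log.warning("dropped %d self-pair dependency rows", int(selfpairs.sum()))
            df = df.loc[~selfpairs]
        a = df[["MARKER", "MARKER2"]].min(axis=1)
        b = df[["MARKER", "MARKER2"]].max(axis=1)
        df = pd.DataFrame(
            {"MARKER": a, "MARKER2": b, "STRENGTH": df["STRENGTH"]}
        )
        df = (
            df.groupby(["MARKER", "MARKER2"], as_index=False)["STRENGTH"]
            .max()
            .sort_values(["MARKER", "MARKER2"], kind="mergesort")
            .reset_index(drop=True)
        )
        return cls(df)

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerDependency) and self.pairs.equals(other.pairs)


@dataclass(frozen=True, eq=False)
class GeneSetCollection:
    """Named gene sets (pathways / modules) with optional annotations."""

    sets: Mapping[str, frozenset[str]]
    info: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def from_dict(
        cls,
        sets: Mapping[str, Iterable[str]],
        info: Mapping[str, tuple[str, str]] | None = None,
    ) -> "GeneSetCollection":
        canon: dict[str, frozenset[str]] = {}
        for module in sorted(sets):
            members = frozenset(str(g) for g in sets[module])
            if not members:
                log.warning("gene set %s has no genes; excluded", module)
                continue
            canon[str(module)] = members
        info = dict(info or {})
        extra = set(info) - set(canon)
        if extra:
            log.warning(
                "descriptions for %d unknown modules ignored: %s",
                len(extra),
                ", ".join(sorted(extra)[:5]),
            )
            for m in extra:
                del info[m]
        return cls(canon, info)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(sorted(self.sets))

    def __contains__(self, module: str) -> bool:
        return module in self.sets

    def __getitem__(self, module: str) -> frozenset[str]:
        return self.sets[module]

    def description(self, module: str) -> str:
        return self.info.get(module, ("", ""))[1]

    def source(self, module: str) -> str:
        return self.info.get(module, ("", ""))[0]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GeneSetCollection)
            and dict(self.sets) == dict(other.sets)
            and dict(self.info) == dict(other.info)
        )


@dataclass(frozen=True, eq=False)
class WeightedNetwork:
    """Weighted gene-gene edge list, directed or undirected.

    Undirected networks are canonicalized with the lexicographically
    smaller endpoint in TAIL; reciprocal duplicates collapse to the maximum
    weight.  ``extra_nodes`` carries nodes with no incident edge (they
    cannot be expressed in the edge-list file dialect but are legal in
    memory, e.g. for null-model universes).
    """

    edges: pd.DataFrame  # columns TAIL, HEAD, WEIGHT
    directed: bool
    extra_nodes: tuple[str, ...] = ()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        directed: bool,
        extra_nodes: Iterable[str] = (),
    ) -> "WeightedNetwork":
        df = pd.DataFrame(list(edges), columns=list(NETWORK_HEADER))
        df["TAIL"] = df["TAIL"].astype(str)
        df["HEAD"] = df["HEAD"].astype(str)
        df["WEIGHT"] = df["WEIGHT"].astype(float)
        if len(df) and (df["WEIGHT"] <= 0).any():
            raise FormatError("edge weights must be > 0")
        if not directed:
            a = df[["TAIL", "HEAD"]].min(axis=1)
            b = df[["TAIL", "HEAD"]].max(axis=1)
            df = pd.DataFrame({"TAIL": a, "HEAD": b, "WEIGHT": df["WEIGHT"]})
            df = df.groupby(["TAIL", "HEAD"], as_index=False)["WEIGHT"].max()
        else:
            df = df.groupby(["TAIL", "HEAD"], as_index=False)["WEIGHT"].max()
        df = df.sort_values(["TAIL", "HEAD"], kind="mergesort").reset_index(drop=True)
        return cls(df, directed, tuple(sorted(set(map(str, extra_nodes)))))

    def to_networkx(self) -> "nx.Graph | nx.DiGraph":
        g = nx.DiGraph() if self.directed else nx.Graph()
        for tail, head, w in self.edges.itertuples(index=False):
            g.add_edge(tail, head, weight=float(w))
        g.add_nodes_from(self.extra_nodes)
        return g

    @property
    def nodes(self) -> list[str]:
        ns = set(self.edges["TAIL"]) | set(self.edges["HEAD"]) | set(self.extra_nodes)
        return sorted(ns)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, WeightedNetwork)
            and self.directed == other.directed
            and self.edges.equals(other.edges)
            and self.extra_nodes == other.extra_nodes
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_raw(source: Source) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            source, sep="\t", dtype=str, header=0, keep_default_na=False,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise FormatError("empty file") from None
    if df.empty and df.columns.empty:
        raise FormatError("empty file")
    return df


def _numeric(col: pd.Series, what: str) -> pd.Series:
    # parse via numpy: exact round trip of repr-formatted floats
    def parse(token: str) -> float:
        try:
            return float(token)
        except ValueError:
            return np.nan

    out = col.map(parse)
    bad = out.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise FormatError(f"non-numeric {what} at line {line}")
    return out.astype(float)


def read_association(source: Source) -> MarkerAssociation:
    """Read a MARKER/VALUE table of -log10 association p-values."""
    df = _read_raw(source)
    if df.shape[1] != 2:
        raise FormatError(
            f"association file needs 2 columns, found {df.shape[1]}"
        )
    if df.empty:
        raise FormatError("association file has no data rows")
    values = _numeric(df.iloc[:, 1], "association value")
    neg = values < 0
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 2
        raise FormatError(f"negative -log10 p-value at line {line}")
    assoc = MarkerAssociation.from_records(df.iloc[:, 0], values)
    log.info("read %d markers (%d rows)", len(assoc), len(df))
    return assoc


def read_mapping(source: Source) -> MarkerGeneMap:
    """Read a MARKER/GENE mapping table (many-to-many)."""
    df = _read_raw(source)
    if df.shape[1] != 2:
        raise FormatError(f"mapping file needs 2 columns, found {df.shape[1]}")
    return MarkerGeneMap.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_dependency(source: Source) -> MarkerDependency:
    """Read pairwise marker dependencies; a missing third column means 1.0."""
    df = _read_raw(source)
    if df.shape[1] not in (2, 3):
        raise FormatError(
            f"dependency file needs 2 or 3 columns, found {df.shape[1]}"
        )
    if df.shape[1] == 2:
        strength = pd.Series(1.0, index=df.index)
    else:
        strength = _numeric(df.iloc[:, 2], "dependency strength")
        if ((strength < 0) | (strength > 1)).any():
            bad = (strength < 0) | (strength > 1)
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(f"dependency strength outside [0, 1] at line {line}")
    return MarkerDependency.from_pairs(
        zip(df.iloc[:, 0], df.iloc[:, 1], strength)
    )


def read_genesets(
    source: Source, descriptions: Source | None = None
) -> GeneSetCollection:
    """Read a MODULE/GENE gene-set table, optionally with a description table."""
    df = _read_raw(source)
    if df.shape[1] != 2:
        raise FormatError(f"gene-set file needs 2 columns, found {df.shape[1]}")
    sets: dict[str, set[str]] = {}
    for module, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sets.setdefault(str(module), set())
        if str(gene):
            sets[str(module)].add(str(gene))
    info: dict[str, tuple[str, str]] = {}
    if descriptions is not None:
        dd = _read_raw(descriptions)
        if dd.shape[1] != 3:
            raise FormatError(
                f"description file needs 3 columns, found {dd.shape[1]}"
            )
        for module, src, descr in zip(dd.iloc[:, 0], dd.iloc[:, 1], dd.iloc[:, 2]):
            info[str(module)] = (str(src), str(descr))
    return GeneSetCollection.from_dict(sets, info)


def read_network(source: Source, directed: bool = False) -> WeightedNetwork:
    """Read a TAIL/HEAD[/WEIGHT] edge list; a missing weight column means 1.0."""
    df = _read_raw(source)
    if df.shape[1] not in (2, 3):
        raise FormatError(f"network file needs 2 or 3 columns, found {df.shape[1]}")
    if df.shape[1] == 2:
        weight = pd.Series(1.0, index=df.index)
    else:
        weight = _numeric(df.iloc[:, 2], "edge weight")
        if (weight <= 0).any():
            line = int(np.flatnonzero((weight <= 0).to_numpy())[0]) + 2
            raise FormatError(f"non-positive edge weight at line {line}")
    return WeightedNetwork.from_edges(
        zip(df.iloc[:, 0], df.iloc[:, 1], weight), directed=directed
    )


# ---------------------------------------------------------------------------
# writing the input dialects (round-trip partners of the readers)
# ---------------------------------------------------------------------------


def write_association(assoc: MarkerAssociation, path: Source) -> None:
    assoc.values.rename("VALUE").rename_axis("MARKER").reset_index().to_csv(
        path, sep="\t", index=False
    )


def write_mapping(mapping: MarkerGeneMap, path: Source) -> None:
    mapping.pairs.to_csv(path, sep="\t", index=False)


def write_dependency(deps: MarkerDependency, path: Source) -> None:
    deps.pairs.to_csv(path, sep="\t", index=False)


def write_genesets(
    genesets: GeneSetCollection,
    path: Source,
    descriptions_path: Source | None = None,
) -> None:
    rows = [
        (module, gene)
        for module in genesets
        for gene in sorted(genesets[module])
    ]
    pd.DataFrame(rows, columns=list(GENESET_HEADER)).to_csv(
        path, sep="\t", index=False
    )
    if descriptions_path is not None:
        drows = [
            (m, genesets.source(m), genesets.description(m))
            for m in genesets
            if m in genesets.info
        ]
        pd.DataFrame(drows, columns=list(DESCRIPTION_HEADER)).to_csv(
            descriptions_path, sep="\t", index=False
        )


def write_network(network: WeightedNetwork, path: Source) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------


def _fmt_markers(pairs: Sequence[tuple[str, float]]) -> str:
    return ",".join(f"{m}:{v:.4g}" for m, v in pairs)


def write_msea_tables(
    results: Sequence, out_dir: Source, fdr_cutoff: float = 0.25
) -> list[Path]:
    """Write the four MSEA output tables, rows sorted by ascending p.

    ``results`` are enrichment results carrying p_value, fdr, statistic,
    counts, density ratio, top genes/markers and a per-gene detail frame.
    The top-modules detail file is restricted to modules with
    ``fdr < fdr_cutoff`` (default 25 %).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(results, key=lambda r: (r.p_value, r.module_id))

    pval = pd.DataFrame(
        [(r.module_id, r.p_value, r.fdr) for r in ordered],
        columns=["MODULE", "P", "FDR"],
    )
    full = pd.DataFrame(
        [
            (
                r.module_id,
                r.p_value,
                r.empirical_p,
                r.fdr,
                r.statistic,
                r.n_genes,
                r.n_markers,
                r.density_ratio,
                ",".join(r.top_genes),
                _fmt_markers(r.top_markers),
                r.description,
            )
            for r in ordered
        ],
        columns=[
            "MODULE", "P", "EMPIRICAL_P", "FDR", "STATISTIC", "NGENES",
            "NMARKERS", "DENSITY_RATIO", "TOP_GENES", "TOP_MARKERS", "DESCR",
        ],
    )
    top_rows = []
    gene_rows = []
    for r in ordered:
        if r.gene_details is None:
            continue
        for gene, nmark, top_marker, top_value in r.gene_details.itertuples(
            index=False
        ):
            if r.fdr < fdr_cutoff:
                top_rows.append((r.module_id, gene, nmark, top_marker, top_value))
            gene_rows.append((gene, top_value, nmark, top_marker))
    top = pd.DataFrame(
        top_rows, columns=["MODULE", "GENE", "NMARKERS", "TOP_MARKER", "TOP_VALUE"]
    )
    genes = (
        pd.DataFrame(
            gene_rows, columns=["GENE", "SCORE", "NMARKERS", "TOP_MARKER"]
        )
        .drop_duplicates(subset=["GENE"])
        .sort_values(["SCORE", "GENE"], ascending=[False, True], kind="mergesort")
    )
    paths = []
    for name, frame in zip(MSEA_FILES, (pval, full, top, genes)):
        p = out_dir / name
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths.append(p)
    return paths


def write_wkda_tables(results: Sequence, out_dir: Source) -> list[Path]:
    """Write the four wKDA output tables (all KDs, full stats, top hits,
    hub/co-hub structure), rows sorted by ascending p."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(results, key=lambda r: (r.p_value, r.module_id, r.kd_gene))

    pval = pd.DataFrame(
        [(r.module_id, r.kd_gene, r.p_value, r.fdr) for r in ordered],
        columns=["MODULE", "NODE", "P", "FDR"],
    )
    full = pd.DataFrame(
        [
            (
                r.module_id,
                r.kd_gene,
                r.neighborhood_size,
                r.overlap_count,
                r.observed_score,
                r.fold_enrichment,
                r.p_value,
                r.empirical_p,
                r.fdr,
                r.cohub_group or "",
            )
            for r in ordered
        ],
        columns=[
            "MODULE", "NODE", "NEIGHBORS", "OVERLAP", "SCORE", "FOLD",
            "P", "EMPIRICAL_P", "FDR", "COHUB_GROUP",
        ],
    )
    tophits = pd.DataFrame(
        [
            (r.module_id, r.kd_gene, r.p_value, r.fdr)
            for r in ordered
            if r.is_top
        ],
        columns=["MODULE", "NODE", "P", "FDR"],
    )
    groups: dict[tuple[str, str], list[str]] = {}
    for r in ordered:
        if r.cohub_group:
            groups.setdefault((r.module_id, r.cohub_group), []).append(r.kd_gene)
    hub = pd.DataFrame(
        [
            (module, rep, ",".join(sorted(members)))
            for (module, rep), members in sorted(groups.items())
        ],
        columns=["MODULE", "HUB", "COHUBS"],
    )
    paths = []
    for name, frame in zip(WKDA_FILES, (pval, full, tophits, hub)):
        p = out_dir / name
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths.append(p)
    return paths


def write_cytoscape_files(
    results: Sequence,
    network: WeightedNetwork,
    out_dir: Source,
    genesets: GeneSetCollection | None = None,
) -> tuple[Path, Path]:
    """Export the selected KD subnetworks as Cytoscape-importable tables.

    The edge table is the union of edges lying inside any selected KD's
    subnetwork ({hub} plus neighborhood); the node table flags KDs and
    lists gene-set membership so nodes can be shaped/colored on import.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    selected = [r for r in results if getattr(r, "is_top", False)]
    kd_nodes = {r.kd_gene for r in selected}
    edge_keys: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    for r in selected:
        sub = set(r.neighborhood) | {r.kd_gene}
        nodes |= sub
        inside = network.edges["TAIL"].isin(sub) & network.edges["HEAD"].isin(sub)
        for tail, head, _ in network.edges.loc[inside].itertuples(index=False):
            edge_keys.add((tail, head))
    edges = network.edges[
        [
            (t, h) in edge_keys
            for t, h in zip(network.edges["TAIL"], network.edges["HEAD"])
        ]
    ].reset_index(drop=True)

    def membership(node: str) -> str:
        if genesets is None:
            return ""
        return ",".join(m for m in genesets if node in genesets[m])

    node_table = pd.DataFrame(
        [
            (node, int(node in kd_nodes), membership(node))
            for node in sorted(nodes)
        ],
        columns=["NODE", "IS_KD", "MODULES"],
    )
    edge_path = out_dir / "cytoscape_edges.txt"
    node_path = out_dir / "cytoscape_nodes.txt"
    edges.to_csv(edge_path, sep="\t", index=False)
    node_table.to_csv(node_path, sep="\t", index=False)
    return edge_path, node_path
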