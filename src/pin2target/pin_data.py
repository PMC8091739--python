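"""Canonical data model: directed gene-interaction graph, adjacency matrix,
drug->target maps, and the plain-text readers/writers shared by every stage.

Conventions fixed here and relied on everywhere else:

* An edge ``(u, v)`` means gene ``v`` is a *downstream* interacting partner
  of gene ``u``; the adjacency matrix puts a 1 at ``(i, j)`` iff ``i -> j``.
* Node order is sorted lexicographically at load so matrix layouts are
  deterministic across runs.
* Gene identifiers are matched as exact strings (no case folding, no alias
  resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A delimited input file violates its format contract."""


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping emitted when an edge list is ingested."""

    n_nodes: int
    n_edges: int
    n_duplicates_dropped: int
    n_self_loops_dropped: int


@dataclass
class PINGraph:
    """Directed protein-interaction network.

    ``nodes`` is an ordered list of unique gene identifiers; ``edges`` is a
    set of ``(source, target)`` pairs. Self-loops and duplicate edges are
    disallowed by construction (see :func:`read_edge_list`).
    """

    nodes: list[str]
    edges: set[tuple[str, str]]
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node identifiers must be unique")
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r}->{v!r} is not allowed")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint missing from nodes: {(u, v)!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "PINGraph":
        """Build a graph from raw (source, target) pairs.

        Duplicates are collapsed and self-loops dropped; node order is
        lexicographic. ``extra_nodes`` adds isolated genes.
        """
        raw = list(edges)
        seen: set[tuple[str, str]] = set()
        n_dup = n_loop = 0
        nodes: set[str] = set(extra_nodes)
        for u, v in raw:
            nodes.add(u)
            nodes.add(v)
            if u == v:
                n_loop += 1
                continue
            if (u, v) in seen:
                n_dup += 1
                continue
            seen.add((u, v))
        report = LoadReport(len(nodes), len(seen), n_dup, n_loop)
        return cls(sorted(nodes), seen, load_report=report)


@dataclass
class AdjacencyMatrix:
    """Binary N x N matrix aligned to a fixed gene order.

    Row ``i`` is the out-neighborhood indicator vector of gene ``i`` — the
    per-gene feature vector fed to the autoencoder.
    """

    entries: np.ndarray
    node_order: list[str]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        n = len(self.node_order)
        if self.entries.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.entries.shape} does not match {n} nodes"
            )
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.node_order)

    def to_edges(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.entries)
        return {(self.node_order[i], self.node_order[j]) for i, j in zip(rows, cols)}


@dataclass
class DrugTargetMap:
    """Mapping drug identifier -> set of target gene identifiers.

    Target genes are raw strings; PIN membership is not required at this
    stage (mapping onto a graph happens via :func:`map_genes_to_pin`).
    """

    targets: dict[str, set[str]]
    indications: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, genes in self.targets.items():
            if not genes:
                raise ValueError(f"drug {drug!r} has an empty target set")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.targets)

    def __len__(self) -> int:
        return len(self.targets)


def read_edge_list(
    path: str | Path, delimiter: str | None = "\t", has_header: bool = False
) -> PINGraph:
    """Read a 2+ column delimited edge list into a :class:`PINGraph`.

    Duplicate edges are collapsed, self-loops removed; both are counted in
    the graph's ``load_report``. Lines starting with ``#`` and blank lines
    are skipped. ``delimiter=None`` splits on any whitespace.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if has_header and lineno == 1:
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            fields = [f for f in fields if f != ""]
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected >=2 columns, got {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
    graph = PINGraph.from_edges(edges)
    r = graph.load_report
    logger.info(
        "loaded %s: %d nodes, %d edges (%d duplicates dropped, %d self-loops dropped)",
        path, r.n_nodes, r.n_edges, r.n_duplicates_dropped, r.n_self_loops_dropped,
    )
    return graph


def write_edge_list(graph: PINGraph, path: str | Path, delimiter: str = "\t") -> None:
    """Write the edge set as sorted 2-column delimited text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {graph.n_nodes} nodes, {graph.n_edges} edges\n")
        for u, v in sorted(graph.edges):
            fh.write(f"{u}{delimiter}{v}\n")


def to_adjacency(graph: PINGraph) -> AdjacencyMatrix:
    """Binary adjacency matrix in the graph's node order; (i,j)=1 iff i->j."""
    if graph.n_nodes == 0:
        raise ValueError("cannot build an adjacency matrix for an empty graph")
    idx = graph.node_index()
    entries = np.zeros((graph.n_nodes, graph.n_nodes), dtype=np.int8)
    for u, v in graph.edges:
        entries[idx[u], idx[v]] = 1
    return AdjacencyMatrix(entries, list(graph.nodes))


def read_drug_target_table(path: str | Path, delimiter: str = "\t") -> DrugTargetMap:
    """Read a drug/target[/indication] table; targets aggregate across rows."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    targets: dict[str, set[str]] = {}
    indications: dict[str, str] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if lineno == 1 and fields[0].lower() == "drug":
                continue
            if len(fields) < 2 or not fields[1].strip():
                raise ParseError(f"{path}:{lineno}: row is missing a target column")
            drug, gene = fields[0], fields[1]
            targets.setdefault(drug, set()).add(gene)
            if len(fields) >= 3 and fields[2]:
                indications[drug] = fields[2]
            n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: no data rows")
    return DrugTargetMap(targets, indications)


def write_drug_target_table(drug_map: DrugTargetMap, path: str | Path) -> None:
    """Write a DrugTargetMap as TSV with a drug/target/indication header."""
    with open(path, "w") as fh:
        fh.write("drug\ttarget\tindication\n")
        for drug in drug_map.drugs:
            ind = drug_map.indications.get(drug, "")
            for gene in sorted(drug_map.targets[drug]):
                fh.write(f"{drug}\t{gene}\t{ind}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene identifier per line; blanks and '#' comments skipped."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def map_genes_to_pin(genes: Iterable[str], graph: PINGraph) -> set[str]:
    """Intersect a gene set with the graph's node set (exact string match)."""
    genes = set(genes)
    mapped = genes & set(graph.nodes)
    if genes and not mapped:
        logger.warning("none of %d genes mapped onto the PIN", len(genes))
    else:
        logger.info("%d of %d genes mapped onto the PIN", len(mapped), len(genes))
    return mapped
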