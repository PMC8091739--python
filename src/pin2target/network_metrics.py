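"""Per-gene network topology: degrees, centralities, clustering, bow-tie
decomposition, maximum-matching controllability, and latent-vs-metric
Spearman correlations.

Directionality policy: degrees, betweenness, closeness, PageRank, bow-tie
and controllability operate on the directed graph; the clustering
coefficient and nearest-neighbor degree use the undirected simple
projection (their standard definitions are undirected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.stats import rankdata

from pin2target.pin_data import PINGraph

logger = logging.getLogger(__name__)

#: fixed TSV column order of the metric table (gene index + 11 metrics)
METRIC_COLUMNS = [
    "gene",
    "indegree",
    "outdegree",
    "betweenness",
    "closeness",
    "pagerank",
    "clustering",
    "nnd",
    "bowtie_input",
    "bowtie_core",
    "bowtie_output",
    "indispensable",
]

METRIC_NAMES = METRIC_COLUMNS[1:]


@dataclass(frozen=True)
class ControllabilityResult:
    """Maximum matching size, driver-node count ND, and per-gene flags."""

    matching_size: int
    nd: int
    indispensable: dict[str, bool]


def compute_degrees(graph: PINGraph) -> tuple[dict[str, int], dict[str, int]]:
    indeg = {g: 0 for g in graph.nodes}
    outdeg = {g: 0 for g in graph.nodes}
    for u, v in graph.edges:
        outdeg[u] += 1
        indeg[v] += 1
    return indeg, outdeg


def compute_betweenness(graph: PINGraph) -> dict[str, float]:
    """Directed shortest-path betweenness, endpoints excluded, equal split
    among equal-length shortest paths (unnormalized pair counts)."""
    g = graph.to_networkx()
    return dict(nx.betweenness_centrality(g, normalized=False))


def compute_closeness(graph: PINGraph) -> dict[str, float]:
    """Out-distance closeness with reachable-set scaling.

    For gene i reaching r other genes at total distance s:
    ``(r / s) * (r / (N - 1))``; genes reaching nothing score 0.
    """
    g = graph.to_networkx()
    n = graph.n_nodes
    out = {}
    for v in graph.nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        r = len(dist) - 1
        if r == 0 or n == 1:
            out[v] = 0.0
        else:
            s = sum(dist.values())
            out[v] = (r / s) * (r / (n - 1))
    return out


def compute_pagerank(
    graph: PINGraph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Power iteration with uniform dangling-mass redistribution."""
    n = graph.n_nodes
    idx = graph.node_index()
    outdeg = np.zeros(n)
    targets: list[list[int]] = [[] for _ in range(n)]
    for u, v in graph.edges:
        outdeg[idx[u]] += 1
        targets[idx[u]].append(idx[v])
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = np.zeros(n)
        dangling_mass = x[outdeg == 0].sum()
        for i in range(n):
            if outdeg[i]:
                share = x[i] / outdeg[i]
                for j in targets[i]:
                    new[j] += share
        new = damping * (new + dangling_mass / n) + (1 - damping) / n
        if np.abs(new - x).sum() < tol:
            x = new
            break
        x = new
    else:
        raise RuntimeError(f"PageRank did not converge in {max_iter} iterations")
    return {g: float(x[idx[g]]) for g in graph.nodes}


def _undirected_neighbors(graph: PINGraph) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {g: set() for g in graph.nodes}
    for u, v in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def compute_clustering(graph: PINGraph) -> dict[str, float]:
    """C_i = 2 e_i / (k_i (k_i - 1)) on the undirected projection; 0 for
    k_i < 2. e_i counts undirected links among i's neighbors."""
    adj = _undirected_neighbors(graph)
    out = {}
    for v in graph.nodes:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        e = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if nbrs[b] in adj[nbrs[a]]
        )
        out[v] = 2.0 * e / (k * (k - 1))
    return out


def compute_nnd(graph: PINGraph) -> dict[str, float]:
    """Mean undirected degree over a gene's undirected neighbors; 0 if
    isolated."""
    adj = _undirected_neighbors(graph)
    deg = {g: len(adj[g]) for g in graph.nodes}
    return {
        g: (float(np.mean([deg[w] for w in adj[g]])) if adj[g] else 0.0)
        for g in graph.nodes
    }


def bowtie_decompose(graph: PINGraph) -> dict[str, str]:
    """Label each gene input/core/output/other.

    Core = largest strongly connected component (ties -> component holding
    the lexicographically smallest gene). Input reaches the core; output is
    reachable from it. A size-1 core is degenerate: everything is 'other'.
    """
    g = graph.to_networkx()
    sccs = list(nx.strongly_connected_components(g))
    if not sccs:
        return {}
    max_size = max(len(c) for c in sccs)
    if max_size <= 1:
        logger.warning("degenerate bow-tie: largest SCC has size 1")
        return {v: "other" for v in graph.nodes}
    candidates = [c for c in sccs if len(c) == max_size]
    core = min(candidates, key=lambda c: min(c))
    rep = next(iter(core))
    reach_from_core = nx.descendants(g, rep) | core
    reach_to_core = nx.ancestors(g, rep) | core
    labels = {}
    for v in graph.nodes:
        if v in core:
            labels[v] = "core"
        elif v in reach_to_core:
            labels[v] = "input"
        elif v in reach_from_core:
            labels[v] = "output"
        else:
            labels[v] = "other"
    return labels


def maximum_matching(graph: PINGraph) -> int:
    """Maximum matching size in the bipartite out-copy/in-copy graph (one
    bipartite edge per directed edge)."""
    if not graph.edges:
        return 0
    idx = graph.node_index()
    rows = [idx[u] for u, v in graph.edges]
    cols = [idx[v] for u, v in graph.edges]
    n = graph.n_nodes
    m = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    match = maximum_bipartite_matching(m, perm_type="column")
    return int((match >= 0).sum())


def driver_count(graph: PINGraph) -> int:
    """Minimum driver-node count: ND = max(N - matching_size, 1)."""
    return max(graph.n_nodes - maximum_matching(graph), 1)


def _delete_node(graph: PINGraph, v: str) -> PINGraph:
    nodes = [g for g in graph.nodes if g != v]
    edges = {(a, b) for a, b in graph.edges if a != v and b != v}
    return PINGraph(nodes, edges)


def classify_indispensable(graph: PINGraph) -> ControllabilityResult:
    """A gene is indispensable iff removing it (with incident edges)
    strictly increases the driver-node count ND."""
    matching = maximum_matching(graph)
    nd = max(graph.n_nodes - matching, 1)
    flags = {}
    for v in graph.nodes:
        sub = _delete_node(graph, v)
        nd_v = max(sub.n_nodes - maximum_matching(sub), 1) if sub.n_nodes else 0
        flags[v] = nd_v > nd
    return ControllabilityResult(matching, nd, flags)


def assemble_metric_table(graph: PINGraph) -> pd.DataFrame:
    """All metrics as one DataFrame in graph node order (columns
    :data:`METRIC_COLUMNS`)."""
    indeg, outdeg = compute_degrees(graph)
    btw = compute_betweenness(graph)
    cls = compute_closeness(graph)
    pr = compute_pagerank(graph)
    clu = compute_clustering(graph)
    nnd = compute_nnd(graph)
    bowtie = bowtie_decompose(graph)
    ctrl = classify_indispensable(graph)
    rows = []
    for g in graph.nodes:
        label = bowtie[g]
        rows.append(
            {
                "gene": g,
                "indegree": indeg[g],
                "outdegree": outdeg[g],
                "betweenness": btw[g],
                "closeness": cls[g],
                "pagerank": pr[g],
                "clustering": clu[g],
                "nnd": nnd[g],
                "bowtie_input": int(label == "input"),
                "bowtie_core": int(label == "core"),
                "bowtie_output": int(label == "output"),
                "indispensable": int(ctrl.indispensable[g]),
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def write_metric_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class CorrelationMatrix:
    """Spearman rho between latent dimensions (rows) and metrics (columns);
    zero-variance latent dimensions are flagged n.a. and left NaN."""

    rho: pd.DataFrame
    na_dimensions: list[int]

    def write_tsv(self, path) -> None:
        self.rho.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def correlate_latent_metrics(
    latent: np.ndarray, metrics: pd.DataFrame, genes: list[str] | None = None
) -> CorrelationMatrix:
    """Spearman correlation of every latent dimension against every metric
    column, with average-rank tie handling."""
    latent = np.asarray(latent, dtype=float)
    if latent.shape[0] != len(metrics):
        raise ValueError(
            f"latent has {latent.shape[0]} rows but metric table has {len(metrics)}"
        )
    if genes is not None and list(metrics["gene"]) != list(genes):
        raise ValueError("latent rows and metric table are not aligned by gene")
    metric_cols = [c for c in metrics.columns if c != "gene"]
    mvals = metrics[metric_cols].to_numpy(dtype=float)
    d = latent.shape[1]
    rho = np.full((d, len(metric_cols)), np.nan)
    na_dims = []
    mranks = [rankdata(mvals[:, j]) for j in range(len(metric_cols))]
    mvar = [np.var(r) > 0 for r in mranks]
    for i in range(d):
        col = latent[:, i]
        if np.var(col) == 0:
            na_dims.append(i)
            continue
        lr = rankdata(col)
        for j in range(len(metric_cols)):
            if not mvar[j]:
                continue
            rho[i, j] = np.corrcoef(lr, mranks[j])[0, 1]
    frame = pd.DataFrame(
        rho,
        index=[f"dim_{i + 1}" for i in range(d)],
        columns=metric_cols,
    )
    return CorrelationMatrix(frame, na_dims)
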