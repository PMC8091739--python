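"""Seeded synthetic inputs for end-to-end testing without external data.

Produces a sparse directed scale-free PIN grown by preferential attachment,
a planted "positive" gene class whose adjacency rows are made topologically
cohesive (the learnable signal for the prioritizer), a drug->target map
enriched for the planted class, and GMT gene-set collections containing one
seeded "true pathway".

All generators are pure functions of (config, seed). The global seed fans
out to per-stage child seeds (seed, seed+1, ...) so stages can be
regenerated independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from pin2target.pin_data import DrugTargetMap, PINGraph

logger = logging.getLogger(__name__)

# child-seed offsets per stage
_PIN_SEED = 0
_POSITIVE_SEED = 1
_DRUG_SEED = 2
_GENESET_SEED = 3


@dataclass
class SyntheticConfig:
    n_nodes: int = 500
    edges_per_new_node: int = 3
    n_positives: int = 30
    positive_cohesion: float = 0.9
    n_drugs: int = 50
    targets_per_drug: tuple[int, int] = (1, 8)
    positive_target_enrichment: float = 0.5
    n_gene_sets: int = 50
    gene_set_size: tuple[int, int] = (10, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_nodes <= 0 or self.edges_per_new_node <= 0:
            problems.append("n_nodes and edges_per_new_node must be positive")
        if self.n_positives < 0 or self.n_positives >= self.n_nodes:
            problems.append("n_positives must be in [0, n_nodes)")
        if not (0.0 <= self.positive_cohesion <= 1.0):
            problems.append("positive_cohesion must be in [0, 1]")
        if not (0.0 <= self.positive_target_enrichment <= 1.0):
            problems.append("positive_target_enrichment must be in [0, 1]")
        if self.n_nodes < self.edges_per_new_node + 1:
            problems.append("n_nodes must be >= edges_per_new_node + 1")
        if problems:
            raise ValueError("; ".join(problems))


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_pin(config: SyntheticConfig) -> PINGraph:
    """Grow a directed scale-free graph by preferential attachment.

    Starts from a directed (m+1)-cycle so the undirected projection is
    connected. Each new node sends ``edges_per_new_node`` edges to distinct
    existing nodes chosen proportional to indegree+1, and receives one edge
    from a uniformly chosen existing node.
    """
    rng = np.random.default_rng(config.seed + _PIN_SEED)
    n, m = config.n_nodes, config.edges_per_new_node
    width = len(str(n - 1))
    names = [_gene_name(i, width) for i in range(n)]

    indeg = np.zeros(n, dtype=np.int64)
    edges: set[tuple[int, int]] = set()
    n0 = m + 1
    for i in range(n0):  # seed cycle keeps the start connected
        j = (i + 1) % n0
        edges.add((i, j))
        indeg[j] += 1

    for new in range(n0, n):
        existing = new
        weights = indeg[:existing] + 1.0
        weights /= weights.sum()
        targets = rng.choice(existing, size=m, replace=False, p=weights)
        for t in targets:
            edges.add((new, int(t)))
            indeg[t] += 1
        src = int(rng.integers(existing))
        if (src, new) not in edges:
            edges.add((src, new))
            indeg[new] += 1

    graph = PINGraph.from_edges((names[u], names[v]) for u, v in edges)
    logger.info("synthetic PIN: %d nodes, %d edges", graph.n_nodes, graph.n_edges)
    return graph


def _undirected_adj(graph: PINGraph) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {g: set() for g in graph.nodes}
    for u, v in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _k_step_neighborhood(adj: dict[str, set[str]], anchor: str, k: int) -> set[str]:
    frontier = {anchor}
    seen = {anchor}
    for _ in range(k):
        frontier = {w for v in frontier for w in adj[v]} - seen
        seen |= frontier
    return seen


def plant_positives(graph: PINGraph, config: SyntheticConfig) -> set[str]:
    """Pick a cohesive positive class and rewire its out-edges.

    An anchor of above-median undirected degree is chosen; positives are
    sampled from its 2-step undirected neighborhood with probability
    ``positive_cohesion`` (uniformly from the rest otherwise). Each positive
    is then rewired so at least a ``positive_cohesion`` fraction of its
    out-edges lands inside the anchor neighborhood, which makes positives'
    adjacency rows mutually similar. The graph is modified in place.
    """
    if config.n_positives == 0:
        return set()
    rng = np.random.default_rng(config.seed + _POSITIVE_SEED)
    adj = _undirected_adj(graph)
    degrees = {g: len(adj[g]) for g in graph.nodes}
    median = float(np.median(list(degrees.values())))
    eligible = sorted(g for g, d in degrees.items() if d > median) or sorted(
        graph.nodes
    )
    anchor = eligible[int(rng.integers(len(eligible)))]

    hood = _k_step_neighborhood(adj, anchor, 2)
    if len(hood) < config.n_positives:
        hood = _k_step_neighborhood(adj, anchor, 3)
        if len(hood) < config.n_positives:
            raise ValueError(
                f"anchor neighborhood ({len(hood)}) smaller than "
                f"n_positives ({config.n_positives})"
            )
    hood_list = sorted(hood)
    outside = sorted(set(graph.nodes) - hood)

    positives: set[str] = set()
    hood_pool = list(hood_list)
    outside_pool = list(outside)
    while len(positives) < config.n_positives:
        use_hood = rng.random() < config.positive_cohesion
        pool = hood_pool if (use_hood and hood_pool) else outside_pool
        if not pool:
            pool = hood_pool or outside_pool
        g = pool.pop(int(rng.integers(len(pool))))
        positives.add(g)

    # Rewire into a compact "signature" subset of the neighborhood: a
    # 2-step neighborhood of a well-connected anchor can cover much of a
    # scale-free graph, which would dilute the cohesion signal.
    pool_size = min(len(hood_list), max(25, 3 * config.edges_per_new_node))
    picked = rng.choice(len(hood_list), size=pool_size, replace=False)
    signature = {hood_list[i] for i in picked}
    _rewire_into_neighborhood(graph, positives, signature, config.positive_cohesion, rng)
    return positives


def _rewire_into_neighborhood(
    graph: PINGraph,
    positives: set[str],
    hood: set[str],
    fraction: float,
    rng: np.random.Generator,
) -> None:
    """Retarget out-edges of each positive so >= fraction land in `hood`."""
    out: dict[str, list[str]] = {g: [] for g in graph.nodes}
    for u, v in graph.edges:
        out[u].append(v)
    hood_sorted = sorted(hood)
    for g in sorted(positives):
        targets = sorted(out[g])
        if not targets:
            continue
        need = int(np.ceil(fraction * len(targets)))
        inside = [t for t in targets if t in hood]
        outside = [t for t in targets if t not in hood]
        rng.shuffle(outside)
        while len(inside) < need and outside:
            old = outside.pop()
            candidates = [
                c for c in hood_sorted
                if c != g and c not in inside and (g, c) not in graph.edges
            ]
            if not candidates:
                break
            new = candidates[int(rng.integers(len(candidates)))]
            graph.edges.discard((g, old))
            graph.edges.add((g, new))
            inside.append(new)


def generate_drug_target_map(
    graph: PINGraph, positives: set[str], config: SyntheticConfig
) -> DrugTargetMap:
    """Random drugs whose targets are enriched for the planted class."""
    lo, hi = config.targets_per_drug
    if hi > graph.n_nodes:
        raise ValueError("targets_per_drug upper bound exceeds node count")
    rng = np.random.default_rng(config.seed + _DRUG_SEED)
    nodes = list(graph.nodes)
    enriched_pool = sorted(positives) if positives else []
    width = len(str(config.n_drugs - 1)) if config.n_drugs > 1 else 1
    targets: dict[str, set[str]] = {}
    for d in range(config.n_drugs):
        name = f"drug{d:0{width}d}"
        k = int(rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        while len(chosen) < k:
            if enriched_pool and rng.random() < config.positive_target_enrichment:
                chosen.add(enriched_pool[int(rng.integers(len(enriched_pool)))])
            else:
                chosen.add(nodes[int(rng.integers(len(nodes)))])
        targets[name] = chosen
    return DrugTargetMap(targets)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the name of the seeded true pathway (if any)."""

    sets: dict[str, set[str]]
    true_pathway: str | None = None

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.sets:
                genes = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\tsynthetic\t{genes}\n")


def generate_gene_sets(
    graph: PINGraph, planted: set[str], config: SyntheticConfig
) -> GeneSetCollection:
    """Random gene sets; exactly one contains >=70% of the planted genes."""
    lo, hi = config.gene_set_size
    if hi > graph.n_nodes:
        raise ValueError("gene_set_size upper bound exceeds node count")
    rng = np.random.default_rng(config.seed + _GENESET_SEED)
    nodes = list(graph.nodes)
    width = len(str(max(config.n_gene_sets - 1, 1)))
    sets: dict[str, set[str]] = {}
    for s in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(len(nodes), size=size, replace=False))
        sets[f"SET{s:0{width}d}"] = {nodes[i] for i in members}

    true_name = None
    if planted:
        true_name = "TRUE_PATHWAY"
        n_in = int(np.ceil(0.7 * len(planted)))
        planted_sorted = sorted(planted)
        picked = rng.choice(len(planted_sorted), size=n_in, replace=False)
        members = {planted_sorted[i] for i in picked}
        size = max(hi, n_in)
        others = sorted(set(nodes) - members)
        while len(members) < size and others:
            members.add(others.pop(int(rng.integers(len(others)))))
        sets[true_name] = members
    return GeneSetCollection(sets, true_pathway=true_name)


def adjacency_row_jaccard(graph: PINGraph, genes: set[str]) -> float:
    """Mean pairwise Jaccard similarity of the genes' out-neighbor sets."""
    out: dict[str, set[str]] = {g: set() for g in graph.nodes}
    for u, v in graph.edges:
        out[u].add(v)
    gl = sorted(genes)
    sims = []
    for i in range(len(gl)):
        for j in range(i + 1, len(gl)):
            a, b = out[gl[i]], out[gl[j]]
            union = a | b
            sims.append(len(a & b) / len(union) if union else 0.0)
    return float(np.mean(sims)) if sims else 0.0
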