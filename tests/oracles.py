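"""Independent brute-force oracles for graph algorithms.

Deliberately naive (exhaustive enumeration) so they stay independent of the
library-backed implementations they check. Only usable on tiny graphs.
"""

from collections import deque

from pin2target.pin_data import PINGraph


def brute_matching_size(graph: PINGraph) -> int:
    """Maximum matching in the out-copy/in-copy bipartite graph by
    exhaustive search over edge subsets."""
    edges = sorted(graph.edges)
    best = 0

    def rec(i, used_u, used_v, size):
        nonlocal best
        best = max(best, size)
        if i == len(edges) or size + (len(edges) - i) <= best:
            return
        for j in range(i, len(edges)):
            u, v = edges[j]
            if u not in used_u and v not in used_v:
                rec(j + 1, used_u | {u}, used_v | {v}, size + 1)

    rec(0, frozenset(), frozenset(), 0)
    return best


def brute_nd(graph: PINGraph) -> int:
    return max(graph.n_nodes - brute_matching_size(graph), 1)


def _reachable(graph: PINGraph, start: str) -> set[str]:
    out = {g: set() for g in graph.nodes}
    for u, v in graph.edges:
        out[u].add(v)
    seen = {start}
    queue = deque([start])
    while queue:
        v = queue.popleft()
        for w in out[v]:
            if w not in seen:
                seen.add(w)
                queue.append(w)
    return seen


def brute_bowtie(graph: PINGraph) -> dict[str, str]:
    """Bow-tie labels from pairwise reachability."""
    reach = {v: _reachable(graph, v) for v in graph.nodes}
    sccs = []
    assigned = set()
    for v in graph.nodes:
        if v in assigned:
            continue
        comp = {w for w in graph.nodes if w in reach[v] and v in reach[w]}
        sccs.append(comp)
        assigned |= comp
    max_size = max(len(c) for c in sccs)
    if max_size <= 1:
        return {v: "other" for v in graph.nodes}
    core = min((c for c in sccs if len(c) == max_size), key=min)
    rep = min(core)
    labels = {}
    for v in graph.nodes:
        if v in core:
            labels[v] = "core"
        elif rep in reach[v]:
            labels[v] = "input"
        elif v in reach[rep]:
            labels[v] = "output"
        else:
            labels[v] = "other"
    return labels


def brute_indispensable(graph: PINGraph) -> dict[str, bool]:
    """Definitional oracle: ND recomputed on every node-deleted subgraph."""
    nd = brute_nd(graph)
    flags = {}
    for v in graph.nodes:
        nodes = [g for g in graph.nodes if g != v]
        edges = {(a, b) for a, b in graph.edges if v not in (a, b)}
        sub = PINGraph(nodes, edges)
        nd_v = max(sub.n_nodes - brute_matching_size(sub), 1) if nodes else 0
        flags[v] = nd_v > nd
    return flags


def brute_betweenness(graph: PINGraph) -> dict[str, float]:
    """Endpoint-excluded betweenness by explicit shortest-path enumeration."""
    out = {g: set() for g in graph.nodes}
    for u, v in graph.edges:
        out[u].add(v)

    def all_shortest_paths(s, t):
        # BFS layer by layer, collecting predecessors
        dist = {s: 0}
        preds = {s: []}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in out[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    preds[w] = [v]
                    queue.append(w)
                elif dist[w] == dist[v] + 1:
                    preds[w].append(v)
        if t not in dist:
            return []
        paths = []

        def back(v, acc):
            if v == s:
                paths.append([s] + acc[::-1])
                return
            for p in preds[v]:
                back(p, acc + [v])

        back(t, [])
        return paths

    bt = {v: 0.0 for v in graph.nodes}
    for s in graph.nodes:
        for t in graph.nodes:
            if s == t:
                continue
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bt[v] += 1.0 / len(paths)
    return bt
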