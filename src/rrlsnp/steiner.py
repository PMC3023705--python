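"""Brute-force minimal Steiner networks on the sequence hypercube.

Independent reference for validating median-joining networks on small binary
instances: the length of the shortest network (Steiner tree) connecting a set
of binary haplotypes, allowing unsampled intermediate vertices, computed by
the Dreyfus-Wagner dynamic program over the full {0,1}^n hypercube.  This is
exponential in the number of terminals and sites and is meant for oracles
only (n_sites <= ~10, terminals <= ~8).
"""

from __future__ import annotations

from typing import Sequence

__all__ = ["steiner_minimal_length", "hypercube_mst_length", "graph_steiner_length"]


def _hamming(a: int, b: int) -> int:
    return (a ^ b).bit_count()


def steiner_minimal_length(terminals: Sequence[tuple], n_sites: int) -> int:
    """Length of a minimal Steiner tree connecting binary haplotypes.

    ``terminals`` are tuples over {'0','1'} (or ints 0/1) of length
    ``n_sites``; edge lengths are unit Hamming steps.  Dreyfus-Wagner:
    dp[S][v] = cost of the cheapest tree spanning terminal subset S plus
    vertex v.
    """
    terms = sorted({_to_int(t) for t in terminals})
    k = len(terms)
    if k <= 1:
        return 0
    V = 1 << n_sites
    INF = 1 << 30
    t0, rest = terms[0], terms[1:]
    m = len(rest)
    # dp over subsets of `rest`
    dp = [[INF] * V for _ in range(1 << m)]
    for i, t in enumerate(rest):
        for v in range(V):
            dp[1 << i][v] = _hamming(t, v)
    for S in range(1, 1 << m):
        if S.bit_count() >= 2:
            # merge sub-splits at every vertex
            sub = (S - 1) & S
            while sub:
                comp = S ^ sub
                if sub < comp:  # each split once
                    for v in range(V):
                        c = dp[sub][v] + dp[comp][v]
                        if c < dp[S][v]:
                            dp[S][v] = c
                sub = (sub - 1) & S
        # relax through the hypercube (distances are Hamming)
        row = dp[S]
        best = [min(row[u] + _hamming(u, v) for u in range(V)) for v in range(V)]
        dp[S] = best
    full = (1 << m) - 1
    return min(dp[full][v] + _hamming(v, t0) for v in range(V))


def hypercube_mst_length(terminals: Sequence[tuple]) -> int:
    """MST length over the terminals alone (no Steiner points); Prim's."""
    terms = sorted({_to_int(t) for t in terminals})
    if len(terms) <= 1:
        return 0
    in_tree = {terms[0]}
    out = set(terms[1:])
    total = 0
    while out:
        d, v = min(
            (min(_hamming(u, x) for u in in_tree), x) for x in out
        )
        total += d
        in_tree.add(v)
        out.remove(v)
    return total


def graph_steiner_length(graph, terminals: Sequence, weight: str = "length") -> float:
    """Exact minimal Steiner tree length within an arbitrary weighted graph.

    Dreyfus-Wagner over the graph metric (all-pairs shortest paths); intended
    for small instances (terminals <= ~10).  ``terminals`` must be nodes of
    ``graph``.
    """
    import networkx as nx

    terms = list(dict.fromkeys(terminals))
    if len(terms) <= 1:
        return 0.0
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    nV = len(nodes)
    INF = float("inf")
    dist = [[INF] * nV for _ in range(nV)]
    for src, lengths in nx.all_pairs_dijkstra_path_length(graph, weight=weight):
        i = index[src]
        for dst, d in lengths.items():
            dist[i][index[dst]] = d
    t0, rest = index[terms[0]], [index[t] for t in terms[1:]]
    m = len(rest)
    dp = [[INF] * nV for _ in range(1 << m)]
    for i, t in enumerate(rest):
        for v in range(nV):
            dp[1 << i][v] = dist[t][v]
    for S in range(1, 1 << m):
        if S.bit_count() >= 2:
            sub = (S - 1) & S
            while sub:
                comp = S ^ sub
                if sub < comp:
                    for v in range(nV):
                        c = dp[sub][v] + dp[comp][v]
                        if c < dp[S][v]:
                            dp[S][v] = c
                sub = (sub - 1) & S
        row = dp[S]
        dp[S] = [min(row[u] + dist[u][v] for u in range(nV)) for v in range(nV)]
    full = (1 << m) - 1
    return min(dp[full][v] + dist[v][t0] for v in range(nV))


def _to_int(t) -> int:
    bits = 0
    for i, s in enumerate(t):
        b = int(s)
        if b not in (0, 1):
            raise ValueError("binary states required")
        bits |= b << i
    return bits
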