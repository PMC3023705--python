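"""Median-joining haplotype networks.

A median-joining (MJ) network depicts intraspecific sequence evolution by
combining all minimum spanning trees of the observed haplotypes (the minimum
spanning network, MSN) with inferred intermediate haplotypes: for triplets of
nearby sequences, the coordinate-wise (quasi-)median is added as an unsampled
"median vector" whenever it shortens the network.  The tolerance ``epsilon``
relaxes the feasible-link criterion (0 = strict MSN); per-site weights let
transversions or coding positions count more.  Median vectors that end up
with fewer than three neighbours are pruned.

Haplotype tables come in as rectangular DataFrames (rows = haplotypes,
columns = sites, plus optional ``frequency`` and ``population`` columns);
networks are networkx graphs exportable as DOT, GraphML or a TSV edge list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Haplotype",
    "HaploNetwork",
    "condense_sites",
    "mj_network",
    "export_network",
    "import_network_tsv",
]

_MAX_ITER = 100
_MAX_QUASI_EXPANSION = 243  # cap on vectors from one quasi-median expansion


@dataclass
class Haplotype:
    id: str
    states: tuple
    frequency: int = 1
    population: str = ""


@dataclass
class HaploNetwork:
    graph: nx.Graph  # nodes = state tuples; attrs: ids, frequency, population, is_median
    site_labels: list
    epsilon: float
    weights: np.ndarray

    def nodes(self):
        return list(self.graph.nodes)

    def observed_nodes(self):
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    def median_nodes(self):
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def edge_length(self, u, v) -> float:
        return self.graph.edges[u, v]["length"]

    def total_edge_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))

    def parsimony_length(self) -> float:
        """Length of the shortest subnetwork connecting the observed haplotypes.

        Exact Steiner tree within the network graph, with median vectors as
        optional junctions; equals the most-parsimonious tree length the
        network encodes.  Exponential in the number of observed haplotypes,
        so meant for small networks.
        """
        from .steiner import graph_steiner_length

        return graph_steiner_length(self.graph, self.observed_nodes())


def condense_sites(table: pd.DataFrame) -> tuple:
    """Collapse a haplotype table to its variable sites and unique rows.

    Site columns are every column except ``frequency``/``population``.
    Identical haplotypes merge with summed frequencies (first id and
    population kept; merged ids recorded).  Missing states (NaN/empty) raise:
    imputation is out of scope.  Returns ``(haplotypes, site_map)`` where
    ``site_map`` maps condensed site index -> original column label.
    """
    if table.empty:
        raise ValueError("empty haplotype table")
    meta = [c for c in ("frequency", "population") if c in table.columns]
    sites = [c for c in table.columns if c not in meta]
    states = table[sites].astype("object")
    if states.isna().any().any() or (states == "").any().any():
        raise ValueError("missing states are unsupported")
    variable = [c for c in sites if states[c].nunique() > 1]
    site_map = dict(enumerate(variable))

    merged: dict[tuple, Haplotype] = {}
    for idx, row in table.iterrows():
        key = tuple(str(states.at[idx, c]) for c in variable)
        freq = int(row["frequency"]) if "frequency" in meta else 1
        pop = str(row["population"]) if "population" in meta else ""
        if key in merged:
            merged[key].frequency += freq
        else:
            merged[key] = Haplotype(id=str(idx), states=key, frequency=freq,
                                    population=pop)
    return list(merged.values()), site_map


def _dist(a: tuple, b: tuple, w: np.ndarray) -> float:
    return float(sum(wi for ai, bi, wi in zip(a, b, w) if ai != bi))


def _feasible_links(vecs: list, w: np.ndarray, epsilon: float) -> list:
    """Links of the epsilon-relaxed minimum spanning network.

    A pair is feasible when its distance is within ``epsilon`` of the
    threshold at which its two endpoints' clusters first connect (computed by
    a Kruskal sweep); epsilon = 0 yields exactly the union of all minimum
    spanning trees.
    """
    n = len(vecs)
    if n <= 1:
        return []
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = _dist(vecs[i], vecs[j], w)
    # connection thresholds via Kruskal over increasing distance values
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    thresh = np.zeros((n, n))
    members: dict[int, set] = {i: {i} for i in range(n)}
    for val in sorted({d[i, j] for i, j in itertools.combinations(range(n), 2)}):
        pairs = [
            (i, j)
            for i, j in itertools.combinations(range(n), 2)
            if d[i, j] == val and find(i) != find(j)
        ]
        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            for a in members[ri]:
                for b in members[rj]:
                    thresh[a, b] = thresh[b, a] = val
            members[ri] |= members[rj]
            members.pop(rj)
            parent[rj] = ri
    return [
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if d[i, j] <= thresh[i, j] + epsilon
    ]


def _quasi_medians(u: tuple, v: tuple, w: tuple) -> list:
    """Coordinate-wise medians of a triplet; multistate ties expand.

    Where two sequences agree the majority state wins; where all three differ
    the site contributes each of the three states (quasi-median expansion),
    capped to keep degenerate multistate inputs tractable.
    """
    per_site = []
    n_out = 1
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            per_site.append((a,))
        elif b == c:
            per_site.append((b,))
        else:
            per_site.append((a, b, c))
            n_out *= 3
        if n_out > _MAX_QUASI_EXPANSION:
            return []
    return [tuple(x) for x in itertools.product(*per_site)]


def mj_network(
    haplotypes: Sequence[Haplotype],
    epsilon: float = 0.0,
    weights: Sequence[float] | None = None,
    site_labels: dict | None = None,
    max_iter: int = _MAX_ITER,
) -> HaploNetwork:
    """Build a median-joining network over condensed haplotypes.

    Iterates: (1) compute feasible links under the epsilon-relaxed MSN
    criterion; (2) for every linked pair and every third sequence, form the
    (quasi-)median vectors and add the new ones with minimal connection cost
    to their generating triplet; repeat until no median is added.  Unsampled
    vectors with fewer than three neighbours in the final link set are then
    pruned (links recomputed after each removal round).
    """
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    n_sites = len(haplotypes[0].states)
    if any(len(h.states) != n_sites for h in haplotypes):
        raise ValueError("haplotypes differ in length")
    w = np.ones(n_sites) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != n_sites or (w <= 0).any():
        raise ValueError("weights must be positive, one per site")

    observed: dict[tuple, Haplotype] = {}
    for h in haplotypes:
        if h.states in observed:
            observed[h.states].frequency += h.frequency
        else:
            observed[h.states] = h
    vecs = sorted(observed)  # deterministic node order

    for iteration in range(max_iter):
        links = _feasible_links(vecs, w, epsilon)
        best_cost = None
        best: set = set()
        vec_set = set(vecs)
        for i, j in links:
            u, v = vecs[i], vecs[j]
            for t in vecs:
                if t == u or t == v:
                    continue
                for m in _quasi_medians(u, v, t):
                    if m in vec_set:
                        continue
                    cost = _dist(u, m, w) + _dist(v, m, w) + _dist(t, m, w)
                    if best_cost is None or cost < best_cost - 1e-12:
                        best_cost, best = cost, {m}
                    elif abs(cost - best_cost) <= 1e-12:
                        best.add(m)
        new = best - vec_set
        if not new:
            break
        vecs = sorted(vec_set | new)
    else:
        raise RuntimeError(f"median-joining did not converge within {max_iter} iterations")

    # prune unsampled vectors of degree < 3, recomputing links as we go
    while True:
        links = _feasible_links(vecs, w, epsilon)
        degree = {v: 0 for v in vecs}
        for i, j in links:
            degree[vecs[i]] += 1
            degree[vecs[j]] += 1
        doomed = [v for v in vecs if v not in observed and degree[v] < 3]
        if not doomed:
            break
        vecs = [v for v in vecs if v not in doomed]

    g = nx.Graph()
    median_count = 0
    for v in vecs:
        if v in observed:
            h = observed[v]
            g.add_node(v, ids=h.id, frequency=h.frequency,
                       population=h.population, is_median=False)
        else:
            median_count += 1
            g.add_node(v, ids=f"mv{median_count}", frequency=0,
                       population="", is_median=True)
    for i, j in _feasible_links(vecs, w, epsilon):
        u, v = vecs[i], vecs[j]
        diff = [k for k in range(n_sites) if u[k] != v[k]]
        g.add_edge(u, v, length=_dist(u, v, w), sites=diff)
    labels = [site_labels.get(i, i) if site_labels else i for i in range(n_sites)]
    return HaploNetwork(graph=g, site_labels=labels, epsilon=epsilon, weights=w)


# ---------------------------------------------------------------------------
# Export / import


def _node_rows(net: HaploNetwork):
    for v, d in net.graph.nodes(data=True):
        yield {
            "id": d["ids"],
            "states": "".join(map(str, v)),
            "frequency": d["frequency"],
            "population": d["population"],
            "is_median": int(d["is_median"]),
        }


def _edge_rows(net: HaploNetwork):
    for u, v, d in net.graph.edges(data=True):
        yield {
            "source": net.graph.nodes[u]["ids"],
            "target": net.graph.nodes[v]["ids"],
            "length": d["length"],
            "sites": ",".join(str(net.site_labels[k]) for k in d["sites"]),
        }


def export_network(net: HaploNetwork, path: str, fmt: str = "tsv") -> None:
    """Write the network as DOT, GraphML or a TSV node+edge table.

    Node size attributes are proportional to haplotype frequency; median
    vectors are flagged (and drawn small/red in DOT, echoing the usual
    rendering of inferred intermediates).
    """
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("#nodes\tid\tstates\tfrequency\tpopulation\tis_median\n")
            for r in _node_rows(net):
                fh.write("N\t{id}\t{states}\t{frequency}\t{population}\t{is_median}\n".format(**r))
            fh.write("#edges\tsource\ttarget\tlength\tsites\n")
            for r in _edge_rows(net):
                fh.write("E\t{source}\t{target}\t{length}\t{sites}\n".format(**r))
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph haplotypes {\n  node [shape=circle];\n")
            for r in _node_rows(net):
                size = 0.2 if r["is_median"] else 0.3 + 0.15 * np.sqrt(r["frequency"])
                color = "red" if r["is_median"] else "lightyellow"
                fh.write(
                    f'  "{r["id"]}" [label="{r["id"]}", width={size:.2f}, '
                    f'fixedsize=true, fillcolor={color}, style=filled, '
                    f'frequency={r["frequency"]}, states="{r["states"]}"];\n'
                )
            for r in _edge_rows(net):
                fh.write(
                    f'  "{r["source"]}" -- "{r["target"]}" '
                    f'[label="{r["sites"]}", len={r["length"]}];\n'
                )
            fh.write("}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for r in _node_rows(net):
            g.add_node(r["id"], **{k: v for k, v in r.items() if k != "id"})
        for r in _edge_rows(net):
            g.add_edge(r["source"], r["target"], length=r["length"], sites=r["sites"])
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network_tsv(path: str) -> HaploNetwork:
    """Read a TSV export back into a HaploNetwork (exact round-trip)."""
    g = nx.Graph()
    id_to_states: dict[str, tuple] = {}
    n_sites = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "N":
                _, nid, states, freq, pop, is_med = parts
                key = tuple(states)
                n_sites = len(key)
                id_to_states[nid] = key
                g.add_node(key, ids=nid, frequency=int(freq), population=pop,
                           is_median=bool(int(is_med)))
            elif parts[0] == "E":
                _, src, tgt, length, sites = parts
                u, v = id_to_states[src], id_to_states[tgt]
                diff = [k for k in range(n_sites) if u[k] != v[k]]
                g.add_edge(u, v, length=float(length), sites=diff)
    return HaploNetwork(graph=g, site_labels=list(range(n_sites)),
                        epsilon=0.0, weights=np.ones(n_sites))
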