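"""Median-joining haplotype network construction.

Builds the epsilon-relaxed minimum-spanning network over recoded haplotype
vectors, augments it with majority-consensus median (Steiner) vectors that
shorten the network, iterates to a fixpoint, and prunes obsolete medians.
Median nodes stand for unsampled or extinct haplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .popdata import HaplotypeSet

__all__ = ["HaplotypeNetwork", "median_joining_network"]


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # nodes carry is_median, frequency; edges carry weight (steps)
    node_vectors: dict[str, tuple[str, ...]]

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def total_length(self) -> int:
        return int(sum(w for _, _, w in self.graph.edges(data="weight")))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node1": a, "node2": b, "steps": int(w)}
            for a, b, w in sorted(self.graph.edges(data="weight"))
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "steps"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": n,
                "is_median": bool(d["is_median"]),
                "frequency": int(d["frequency"]),
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["id", "is_median", "frequency"])


def _dist(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    return sum(1 for x, y in zip(a, b) if x != y and x != "-" and y != "-")


def _msn_edges(vectors: list[tuple[str, ...]], epsilon: int) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed minimum-spanning network.

    Pairs are processed in ascending distance; at each distance level every
    pair whose endpoints were in different components at any of the last
    (epsilon+1) levels is linked.  epsilon=0 is the standard MSN containing
    every MST.
    """
    n = len(vectors)
    pairs = sorted(
        ((_dist(vectors[i], vectors[j]), i, j) for i in range(n) for j in range(i + 1, n))
    )
    by_level: dict[int, list[tuple[int, int]]] = {}
    for d, i, j in pairs:
        by_level.setdefault(d, []).append((i, j))

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # merge_level[a, b]: distance level at which a and b first share a component
    merge_level = np.zeros((n, n))
    for d in sorted(by_level):
        merging = [(i, j) for i, j in by_level[d] if find(i) != find(j)]
        for i, j in merging:
            pi, pj = find(i), find(j)
            if pi != pj:
                members_i = [x for x in range(n) if find(x) == pi]
                members_j = [x for x in range(n) if find(x) == pj]
                for a in members_i:
                    for b in members_j:
                        merge_level[a, b] = merge_level[b, a] = d
                parent[pi] = pj
    return [(i, j, d) for d, i, j in pairs if d <= merge_level[i, j] + epsilon]


def _median(a, b, c) -> tuple[str, ...]:
    """Per-column majority consensus of three vectors; ties take the
    lexicographically smallest state (deterministic)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(min(x, y, z))
    return tuple(out)


def median_joining_network(
    h: HaplotypeSet, epsilon: int = 0, max_medians: int = 1000
) -> HaplotypeNetwork:
    """Median-joining network of a haplotype set.

    Iteratively adds majority-consensus medians of connected triplets when
    they strictly reduce total network length, then prunes medians that lie on
    no shortest connection between observed haplotypes or have degree < 3.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if h.n_haplotypes < 2:
        raise ValueError("need >=2 haplotypes")

    vectors: list[tuple[str, ...]] = [tuple(v) for v in h.vectors]
    names: list[str] = list(h.labels)
    n_observed = len(names)
    freqs = h.counts.sum(axis=0)

    def build(vecs):
        edges = _msn_edges(vecs, epsilon)
        G = nx.Graph()
        G.add_nodes_from(range(len(vecs)))
        for i, j, w in edges:
            G.add_edge(i, j, weight=w)
        return G

    G = build(vectors)
    current_len = sum(w for _, _, w in G.edges(data="weight"))
    existing = set(vectors)

    improved = True
    while improved and len(vectors) - n_observed < max_medians:
        improved = False
        candidates: dict[tuple[str, ...], None] = {}
        for u in G.nodes:
            neigh = sorted(G.neighbors(u))
            for v, w in itertools.combinations(neigh, 2):
                m = _median(vectors[u], vectors[v], vectors[w])
                if m not in existing:
                    candidates[m] = None
        for m in candidates:
            trial = vectors + [m]
            Gt = build(trial)
            new_len = sum(w for _, _, w in Gt.edges(data="weight"))
            if new_len < current_len:
                vectors = trial
                existing.add(m)
                G, current_len = Gt, new_len
                improved = True
                break  # rebuild candidate set around the new topology

    # prune medians off every shortest observed-observed connection, then
    # medians of degree < 3 (iterate: removals can expose new prunable nodes)
    while True:
        sp = dict(nx.all_pairs_dijkstra_path_length(G, weight="weight"))
        drop = []
        for m in range(n_observed, len(vectors)):
            if m not in G:
                continue
            on_path = False
            for a in range(n_observed):
                for b in range(a + 1, n_observed):
                    if m in sp[a] and m in sp[b] and a in sp and b in sp[a]:
                        if sp[a][m] + sp[m][b] == sp[a][b]:
                            on_path = True
                            break
                if on_path:
                    break
            if not on_path or G.degree(m) < 3:
                drop.append(m)
        if not drop:
            break
        G.remove_nodes_from(drop)
        # restore connectivity among survivors with a fresh MSN over them
        keep = sorted(G.nodes)
        sub_vectors = [vectors[i] for i in keep]
        G2 = build(sub_vectors)
        G = nx.relabel_nodes(G2, dict(enumerate(keep)))
        if not any(i >= n_observed for i in keep):
            break

    out = nx.Graph()
    node_vectors: dict[str, tuple[str, ...]] = {}
    med_counter = 0
    name_of: dict[int, str] = {}
    for i in sorted(G.nodes):
        if i < n_observed:
            name = names[i]
            out.add_node(name, is_median=False, frequency=int(freqs[name]))
        else:
            med_counter += 1
            name = f"mv{med_counter}"
            out.add_node(name, is_median=True, frequency=0)
        name_of[i] = name
        node_vectors[name] = vectors[i]
    for a, b, w in G.edges(data="weight"):
        out.add_edge(name_of[a], name_of[b], weight=int(w))
    return HaplotypeNetwork(out, node_vectors)
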