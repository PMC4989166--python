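"""Hierarchical AMOVA and spatial analysis of molecular variance (SAMOVA).

AMOVA partitions molecular variance among groups, among populations within
groups and within populations using squared mutational distances between
haplotypes (the Phi-statistics convention).  SAMOVA searches, by simulated
annealing over geographically contiguous assignments, for the K-group
partition of populations maximising the among-group fraction F_CT.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .popdata import DistanceMatrix, HaplotypeSet, PopulationTable

__all__ = [
    "Grouping",
    "AmovaResult",
    "SamovaResult",
    "amova",
    "build_contiguity",
    "samova",
    "samova_scan",
]


@dataclass(frozen=True)
class Grouping:
    assignment: dict[str, int]  # population -> group index

    def __post_init__(self) -> None:
        groups = set(self.assignment.values())
        if not groups:
            raise ValueError("empty grouping")

    @property
    def K(self) -> int:
        return len(set(self.assignment.values()))


@dataclass(frozen=True)
class AmovaResult:
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    F_CT: float
    F_SC: float
    F_ST: float
    negative_component: bool = False
    defined: bool = True

    @property
    def total(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c


@dataclass(frozen=True)
class SamovaResult:
    grouping: Grouping
    amova: AmovaResult
    F_CT: float
    n_starts: int
    seed: int | None
    accepted_moves: int
    best_trajectory: tuple[float, ...] = ()


def _pair_sums(h: HaplotypeSet, d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """W[p,q] = sum over ordered individual pairs (one in p, one in q) of d^2."""
    counts = h.counts.to_numpy(dtype=float)
    d2 = d.values.astype(float) ** 2
    W = counts @ d2 @ counts.T
    n = counts.sum(axis=1)
    return W, n


def _amova_from_sums(
    W: np.ndarray, n: np.ndarray, groups: np.ndarray, K: int
) -> AmovaResult:
    """Variance components from precomputed between-population pair sums.

    SS conventions: SS_total = sum_jk d2/(2N); within-population and
    within-group analogues divide by twice the unit size.  Coefficients for
    unequal sample sizes follow the standard three-level AMOVA design.
    """
    N = n.sum()
    P = len(n)
    ss_total = W.sum() / (2 * N)
    ss_wp = sum(W[p, p] / (2 * n[p]) for p in range(P))
    n_g = np.array([n[groups == g].sum() for g in range(K)], dtype=float)
    ss_wg = 0.0
    for g in range(K):
        idx = np.where(groups == g)[0]
        ss_wg += W[np.ix_(idx, idx)].sum() / (2 * n_g[g])
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    df_ag = K - 1
    df_ap = P - K
    df_wp = N - P
    if df_wp <= 0:
        return AmovaResult(0, 0, 0, np.nan, np.nan, np.nan, defined=False)
    sigma_c = ss_wp / df_wp
    sum_npg = sum(
        (n[groups == g] ** 2).sum() / n_g[g] for g in range(K)
    )
    if df_ap > 0:
        n_prime = (N - sum_npg) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n_prime if n_prime > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n_dprime = (sum_npg - (n**2).sum() / N) / df_ag
        n_tprime = (N - (n_g**2).sum() / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    else:
        sigma_a = 0.0

    total = sigma_a + sigma_b + sigma_c
    negative = sigma_a < 0 or sigma_b < 0
    if total <= 0:
        return AmovaResult(
            sigma_a, sigma_b, sigma_c, np.nan, np.nan, np.nan,
            negative_component=negative, defined=False,
        )
    F_CT = sigma_a / total if df_ag > 0 else np.nan
    F_ST = (sigma_a + sigma_b) / total
    denom = sigma_b + sigma_c
    F_SC = sigma_b / denom if denom > 0 else np.nan
    return AmovaResult(sigma_a, sigma_b, sigma_c, F_CT, F_SC, F_ST, negative)


def amova(h: HaplotypeSet, d: DistanceMatrix, g: Grouping) -> AmovaResult:
    """Three-level AMOVA for a given grouping of populations.

    With K=1 only F_ST is defined.  Negative variance-component estimates are
    reported as-is with ``negative_component`` set.
    """
    pops = list(h.counts.index)
    missing = [p for p in pops if p not in g.assignment]
    if missing:
        raise ValueError(f"populations missing from grouping: {missing}")
    group_ids = sorted(set(g.assignment.values()))
    remap = {gid: i for i, gid in enumerate(group_ids)}
    groups = np.array([remap[g.assignment[p]] for p in pops])
    W, n = _pair_sums(h, d)
    return _amova_from_sums(W, n, groups, len(group_ids))


def build_contiguity(pops: PopulationTable, jitter_seed: int = 0) -> nx.Graph:
    """Delaunay-neighbour graph of populations on (lon, lat).

    Collinear layouts fall back to a chain in sorted axis order.  Duplicate
    coordinates are deterministically jittered with a warning.
    """
    coords = pops.coordinates
    names = list(coords.index)
    pts = coords[["longitude", "latitude"]].to_numpy(dtype=float)
    if len(names) < 2:
        raise ValueError("need >=2 populations")
    if pd.DataFrame(pts).duplicated().any():
        warnings.warn("duplicate population coordinates jittered")
        rng = np.random.default_rng(jitter_seed)
        dup = pd.DataFrame(pts).duplicated().to_numpy()
        pts = pts.copy()
        pts[dup] += rng.normal(0, 1e-4, size=(dup.sum(), 2))
    G = nx.Graph()
    G.add_nodes_from(names)
    try:
        if len(names) < 3:
            raise QhullError("too few points")
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for i, j in itertools.combinations(simplex, 2):
                G.add_edge(names[i], names[j])
    except QhullError:
        # collinear: chain along the dominant axis
        axis = 0 if np.ptp(pts[:, 0]) >= np.ptp(pts[:, 1]) else 1
        order = np.argsort(pts[:, axis], kind="stable")
        for a, b in zip(order, order[1:]):
            G.add_edge(names[a], names[b])
    return G


def _connected(group_pops: list[int], adj: list[set[int]]) -> bool:
    if not group_pops:
        return False
    members = set(group_pops)
    stack = [group_pops[0]]
    seen = {group_pops[0]}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in members and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen == members


def _fct(W, n, groups, K) -> float:
    res = _amova_from_sums(W, n, groups, K)
    return res.F_CT if res.defined and np.isfinite(res.F_CT) else -np.inf


def _initial_partition(P: int, K: int, adj: list[set[int]], rng) -> np.ndarray:
    """Grow K contiguous regions from random seeds."""
    seeds = rng.choice(P, size=K, replace=False)
    groups = np.full(P, -1)
    frontier = list(seeds)
    for g, s in enumerate(seeds):
        groups[s] = g
    unassigned = set(range(P)) - set(seeds)
    while unassigned:
        progress = False
        for u in rng.permutation(sorted(unassigned)):
            neigh_groups = {groups[v] for v in adj[u] if groups[v] >= 0}
            if neigh_groups:
                groups[u] = rng.choice(sorted(neigh_groups))
                unassigned.discard(u)
                progress = True
        if not progress:  # disconnected contiguity graph: attach arbitrarily
            u = unassigned.pop()
            groups[u] = rng.integers(K)
    return groups


def samova(
    h: HaplotypeSet,
    d: DistanceMatrix,
    pops: PopulationTable,
    K: int,
    n_starts: int = 100,
    seed: int | None = None,
    t0: float = 1.0,
    cooling: float = 0.95,
    iters_per_temp: int = 100,
    t_min: float = 1e-3,
    contiguity: nx.Graph | None = None,
) -> SamovaResult:
    """Annealed search for the best K-group contiguous partition.

    Objective is F_CT; moves reassign one boundary population to an adjacent
    group when both source and target groups stay connected.  Best of
    ``n_starts`` independent runs is returned; identical seeds give identical
    results.
    """
    pop_names = list(h.counts.index)
    P = len(pop_names)
    if not (2 <= K < P):
        raise ValueError(f"K must satisfy 2 <= K < {P}")
    G = contiguity if contiguity is not None else build_contiguity(pops)
    index = {p: i for i, p in enumerate(pop_names)}
    adj: list[set[int]] = [set() for _ in range(P)]
    for a, b in G.edges:
        if a in index and b in index:
            adj[index[a]].add(index[b])
            adj[index[b]].add(index[a])
    W, n = _pair_sums(h, d)

    master = np.random.default_rng(seed)
    best_groups = None
    best_f = -np.inf
    total_accepted = 0
    trajectory: list[float] = []

    for _ in range(n_starts):
        rng = np.random.default_rng(master.integers(2**31))
        groups = _initial_partition(P, K, adj, rng)
        f = _fct(W, n, groups, K)
        run_best, run_best_groups = f, groups.copy()
        T = t0
        while T > t_min:
            for _ in range(iters_per_temp):
                u = int(rng.integers(P))
                g_old = groups[u]
                neigh = sorted({groups[v] for v in adj[u]} - {g_old})
                if not neigh:
                    continue
                g_new = int(neigh[int(rng.integers(len(neigh)))])
                groups[u] = g_new
                src = [i for i in range(P) if groups[i] == g_old]
                dst = [i for i in range(P) if groups[i] == g_new]
                if not src or not _connected(src, adj) or not _connected(dst, adj):
                    groups[u] = g_old
                    continue
                f_new = _fct(W, n, groups, K)
                if f_new >= f or rng.random() < math.exp((f_new - f) / T):
                    f = f_new
                    total_accepted += 1
                    if f > run_best:
                        run_best, run_best_groups = f, groups.copy()
                else:
                    groups[u] = g_old
            T *= cooling
        trajectory.append(run_best)
        if run_best > best_f:
            best_f, best_groups = run_best, run_best_groups

    assignment = {p: int(best_groups[i]) for i, p in enumerate(pop_names)}
    grouping = Grouping(assignment)
    res = amova(h, d, grouping)
    return SamovaResult(
        grouping, res, res.F_CT, n_starts, seed, total_accepted,
        tuple(np.maximum.accumulate(trajectory)),
    )


def enumerate_contiguous_partitions(adj: list[set[int]], P: int, K: int):
    """All partitions of {0..P-1} into K non-empty connected groups.

    Exhaustive (used as an oracle for small P); assignments are canonical:
    group indices appear in order of first population.
    """
    def rec(i, groups, next_g):
        if i == P:
            if next_g == K and all(
                _connected([j for j in range(P) if groups[j] == g], adj)
                for g in range(K)
            ):
                yield groups.copy()
            return
        for g in range(min(next_g + 1, K)):
            groups[i] = g
            yield from rec(i + 1, groups, max(next_g, g + 1))
        groups[i] = -1

    yield from rec(0, np.full(P, -1), 0)


def samova_exhaustive(
    h: HaplotypeSet, d: DistanceMatrix, pops: PopulationTable, K: int,
    contiguity: nx.Graph | None = None,
) -> SamovaResult:
    """Exact best contiguous K-partition by enumeration (small P only)."""
    pop_names = list(h.counts.index)
    P = len(pop_names)
    if P > 12:
        raise ValueError("exhaustive search limited to <=12 populations")
    G = contiguity if contiguity is not None else build_contiguity(pops)
    index = {p: i for i, p in enumerate(pop_names)}
    adj: list[set[int]] = [set() for _ in range(P)]
    for a, b in G.edges:
        adj[index[a]].add(index[b])
        adj[index[b]].add(index[a])
    W, n = _pair_sums(h, d)
    best_f, best = -np.inf, None
    for groups in enumerate_contiguous_partitions(adj, P, K):
        f = _fct(W, n, groups, K)
        if f > best_f:
            best_f, best = f, groups.copy()
    grouping = Grouping({p: int(best[i]) for i, p in enumerate(pop_names)})
    res = amova(h, d, grouping)
    return SamovaResult(grouping, res, res.F_CT, 0, None, 0)


def samova_scan(
    h: HaplotypeSet,
    d: DistanceMatrix,
    pops: PopulationTable,
    K_range: range | list[int],
    plateau_threshold: float = 0.01,
    reliable_floor: float = 0.5,
    **samova_kwargs,
) -> dict:
    """F_CT(K) profile over a range of K with a plateau-based suggestion.

    Suggested K is the smallest K at which the forward increase in F_CT drops
    below ``plateau_threshold``; if no K reaches ``reliable_floor`` the scan
    flags "no reliable grouping" (the criterion is configurable because it is
    a judgement call, not a statistic).
    """
    rows = []
    results = {}
    for K in K_range:
        res = samova(h, d, pops, K, **samova_kwargs)
        results[K] = res
        rows.append(
            {"K": K, "F_CT": res.F_CT, "F_SC": res.amova.F_SC, "F_ST": res.amova.F_ST}
        )
    profile = pd.DataFrame(rows)
    fct = profile["F_CT"].to_numpy()
    ks = profile["K"].to_numpy()
    suggested = int(ks[-1])
    for i in range(len(ks) - 1):
        if fct[i + 1] - fct[i] < plateau_threshold:
            suggested = int(ks[i])
            break
    reliable = bool(np.nanmax(fct) >= reliable_floor)
    return {
        "profile": profile,
        "results": results,
        "suggested_K": suggested,
        "reliable": reliable,
    }
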