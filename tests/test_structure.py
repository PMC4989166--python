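"""AMOVA oracle checks, contiguity graph, SAMOVA annealing vs exhaustive."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from haplogeo.popdata import DistanceMatrix
from haplogeo.structure import (
    Grouping,
    amova,
    build_contiguity,
    enumerate_contiguous_partitions,
    samova,
    samova_exhaustive,
    samova_scan,
)

from conftest import make_haplotype_set, make_population_table


def _dist(values):
    arr = np.asarray(values, dtype=float)
    return DistanceMatrix(tuple(f"H{i+1}" for i in range(len(arr))), arr)


def _random_dataset(rng, n_pops=6, n_haps=5):
    counts = rng.integers(0, 6, size=(n_pops, n_haps)).astype(float)
    counts[:, 0] += 2  # every population has >=2 individuals
    d = rng.integers(1, 8, size=(n_haps, n_haps)).astype(float)
    d = np.triu(d, 1)
    d = d + d.T
    h = make_haplotype_set(
        pd.DataFrame(counts, index=[f"P{i}" for i in range(n_pops)],
                     columns=[f"H{i+1}" for i in range(n_haps)])
    )
    return h, _dist(d), counts, d


def _amova_oracle(counts, d, groups):
    """AMOVA recomputed from explicit per-individual squared distances."""
    n_pops, n_haps = counts.shape
    # expand to individuals
    pop_of, hap_of = [], []
    for p in range(n_pops):
        for k in range(n_haps):
            pop_of += [p] * int(counts[p, k])
            hap_of += [k] * int(counts[p, k])
    pop_of, hap_of = np.array(pop_of), np.array(hap_of)
    N = len(pop_of)
    d2 = d[np.ix_(hap_of, hap_of)] ** 2
    groups_of = groups[pop_of]

    ss_total = d2.sum() / (2 * N)
    ss_wp = 0.0
    for p in range(n_pops):
        idx = np.where(pop_of == p)[0]
        ss_wp += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    K = len(set(groups))
    ss_wg = 0.0
    for g in range(K):
        idx = np.where(groups_of == g)[0]
        ss_wg += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_ag, ss_ap = ss_total - ss_wg, ss_wg - ss_wp

    n = counts.sum(axis=1)
    n_g = np.array([n[groups == g].sum() for g in range(K)], dtype=float)
    df_ag, df_ap, df_wp = K - 1, n_pops - K, N - n_pops
    sigma_c = ss_wp / df_wp
    sum_npg = sum((n[groups == g] ** 2).sum() / n_g[g] for g in range(K))
    n_prime = (N - sum_npg) / df_ap
    sigma_b = (ss_ap / df_ap - sigma_c) / n_prime
    n_dprime = (sum_npg - (n**2).sum() / N) / df_ag
    n_tprime = (N - (n_g**2).sum() / N) / df_ag
    sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    return sigma_a, sigma_b, sigma_c


class TestAmova:
    def test_matches_individual_level_oracle(self):
        """Pair-sum computation equals explicit per-individual SS at 1e-10."""
        rng = np.random.default_rng(11)
        for trial in range(5):
            h, dm, counts, d = _random_dataset(rng)
            groups = np.array([0, 0, 1, 1, 2, 2])
            res = amova(h, dm, Grouping({f"P{i}": int(groups[i]) for i in range(6)}))
            sa, sb, sc = _amova_oracle(counts, d, groups)
            assert res.sigma_a == pytest.approx(sa, abs=1e-10)
            assert res.sigma_b == pytest.approx(sb, abs=1e-10)
            assert res.sigma_c == pytest.approx(sc, abs=1e-10)

    def test_perfect_group_structure(self):
        """Two groups, each fixed for its own haplotype -> F_CT near 1."""
        counts = pd.DataFrame(
            {"H1": [6, 6, 0, 0], "H2": [0, 0, 6, 6]},
            index=["P1", "P2", "P3", "P4"],
        )
        h = make_haplotype_set(counts)
        res = amova(h, _dist([[0, 5], [5, 0]]),
                    Grouping({"P1": 0, "P2": 0, "P3": 1, "P4": 1}))
        assert res.F_CT == pytest.approx(1.0)
        assert res.sigma_b == pytest.approx(0.0, abs=1e-12)
        assert res.sigma_c == pytest.approx(0.0, abs=1e-12)

    def test_group_labels_arbitrary(self):
        rng = np.random.default_rng(5)
        h, dm, counts, d = _random_dataset(rng)
        g1 = Grouping({f"P{i}": v for i, v in enumerate([0, 0, 1, 1, 2, 2])})
        g2 = Grouping({f"P{i}": v for i, v in enumerate([7, 7, 3, 3, 9, 9])})
        r1, r2 = amova(h, dm, g1), amova(h, dm, g2)
        assert r1.F_CT == pytest.approx(r2.F_CT, abs=1e-12)

    def test_missing_population_raises(self):
        rng = np.random.default_rng(6)
        h, dm, *_ = _random_dataset(rng)
        with pytest.raises(ValueError, match="missing"):
            amova(h, dm, Grouping({"P0": 0, "P1": 1}))

    def test_single_group_fst_only(self):
        rng = np.random.default_rng(8)
        h, dm, *_ = _random_dataset(rng)
        res = amova(h, dm, Grouping({f"P{i}": 0 for i in range(6)}))
        assert np.isnan(res.F_CT)
        assert np.isfinite(res.F_ST)


class TestContiguity:
    def test_delaunay_connected(self):
        rng = np.random.default_rng(2)
        coords = {f"P{i}": (22 + rng.random() * 8, 105 + rng.random() * 12)
                  for i in range(10)}
        G = build_contiguity(make_population_table(coords))
        assert nx.is_connected(G)
        assert set(G.nodes) == set(coords)

    def test_collinear_chain(self):
        coords = {f"P{i}": (25.0, 105.0 + i) for i in range(5)}
        G = build_contiguity(make_population_table(coords))
        assert nx.is_connected(G)
        # chain: endpoints degree 1, interior degree 2
        degs = sorted(dict(G.degree).values())
        assert degs == [1, 1, 2, 2, 2]

    def test_duplicate_coordinates_warn(self):
        coords = {"P1": (25.0, 105.0), "P2": (25.0, 105.0), "P3": (26.0, 106.0)}
        with pytest.warns(UserWarning, match="duplicate"):
            G = build_contiguity(make_population_table(coords))
        assert len(G.nodes) == 3

    def test_two_populations(self):
        G = build_contiguity(make_population_table({"A": (25, 105), "B": (26, 106)}))
        assert list(G.edges) == [("A", "B")]


class TestEnumeration:
    def test_counts_on_a_path(self):
        # contiguous 2-partitions of a path of 5 = 4 (cut points)
        adj = [set() for _ in range(5)]
        for i in range(4):
            adj[i].add(i + 1)
            adj[i + 1].add(i)
        parts = list(enumerate_contiguous_partitions(adj, 5, 2))
        assert len(parts) == 4

    def test_respects_contiguity(self):
        adj = [{1}, {0, 2}, {1, 3}, {2}]
        for groups in enumerate_contiguous_partitions(adj, 4, 2):
            for g in range(2):
                members = [i for i in range(4) if groups[i] == g]
                assert members == list(range(members[0], members[-1] + 1))


class TestSamova:
    def _structured(self, rng, P=6):
        """Two geographic blocks fixed for divergent haplotype pools."""
        counts = np.zeros((P, 4))
        half = P // 2
        counts[:half, 0] = 5
        counts[:half, 1] = 3
        counts[half:, 2] = 5
        counts[half:, 3] = 3
        d = np.array([
            [0, 1, 8, 9],
            [1, 0, 9, 8],
            [8, 9, 0, 1],
            [9, 8, 1, 0],
        ], dtype=float)
        h = make_haplotype_set(
            pd.DataFrame(counts, index=[f"P{i}" for i in range(P)],
                         columns=["H1", "H2", "H3", "H4"])
        )
        coords = {f"P{i}": (25 + 0.3 * rng.random(), 105 + i + 0.2 * rng.random())
                  for i in range(P)}
        return h, _dist(d), make_population_table(coords)

    def test_recovers_true_split(self):
        rng = np.random.default_rng(1)
        h, dm, pops = self._structured(rng)
        res = samova(h, dm, pops, 2, n_starts=5, seed=0)
        g = res.grouping.assignment
        left = {g[f"P{i}"] for i in range(3)}
        right = {g[f"P{i}"] for i in range(3, 6)}
        assert len(left) == 1 and len(right) == 1 and left != right
        assert res.F_CT > 0.8

    def test_matches_exhaustive_oracle(self):
        """Annealing finds the same optimum as full enumeration (P<=8)."""
        rng = np.random.default_rng(9)
        for trial in range(3):
            P = 7
            counts = rng.integers(0, 5, size=(P, 4)).astype(float)
            counts[:, 0] += 2
            d = rng.integers(1, 7, size=(4, 4)).astype(float)
            d = np.triu(d, 1)
            d = d + d.T
            h = make_haplotype_set(
                pd.DataFrame(counts, index=[f"P{i}" for i in range(P)],
                             columns=[f"H{j+1}" for j in range(4)])
            )
            coords = {f"P{i}": (22 + 6 * rng.random(), 105 + 8 * rng.random())
                      for i in range(P)}
            pops = make_population_table(coords)
            dm = _dist(d)
            for K in (2, 3):
                exact = samova_exhaustive(h, dm, pops, K)
                anneal = samova(h, dm, pops, K, n_starts=10, seed=trial)
                assert anneal.F_CT == pytest.approx(exact.F_CT, abs=1e-9)

    def test_grouping_is_contiguous(self):
        rng = np.random.default_rng(4)
        h, dm, pops = self._structured(rng, P=8)
        res = samova(h, dm, pops, 3, n_starts=5, seed=3)
        G = build_contiguity(pops)
        for g in set(res.grouping.assignment.values()):
            members = [p for p, v in res.grouping.assignment.items() if v == g]
            assert nx.is_connected(G.subgraph(members))

    def test_seed_reproducible(self):
        rng = np.random.default_rng(10)
        h, dm, pops = self._structured(rng)
        r1 = samova(h, dm, pops, 2, n_starts=3, seed=42)
        r2 = samova(h, dm, pops, 2, n_starts=3, seed=42)
        assert r1.grouping.assignment == r2.grouping.assignment
        assert r1.F_CT == r2.F_CT

    def test_invalid_k(self):
        rng = np.random.default_rng(12)
        h, dm, pops = self._structured(rng)
        with pytest.raises(ValueError):
            samova(h, dm, pops, 1)
        with pytest.raises(ValueError):
            samova(h, dm, pops, 6)

    def test_scan_suggests_true_k(self):
        rng = np.random.default_rng(13)
        h, dm, pops = self._structured(rng)
        scan = samova_scan(h, dm, pops, range(2, 5), n_starts=5, seed=0)
        assert scan["suggested_K"] == 2
        assert scan["reliable"]
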