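"""Fast-greedy community detection, modularity, partition comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pcnkit import build_pcn, compare_partitions, fast_greedy, modularity
from pcnkit.community import CommunityPartition

from conftest import network_from_edges, random_gnp_edges


def two_cliques(k, bridge=((0, 0),)):
    """Two K_k cliques with bridge edges (i in clique 1, j in clique 2)."""
    edges = list(itertools.combinations(range(k), 2))
    edges += [(u + k, v + k) for u, v in itertools.combinations(range(k), 2)]
    edges += [(i, j + k) for i, j in bridge]
    return network_from_edges(2 * k, edges)


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_bruteforce(net):
    best_q, best = -1.0, None
    for part in set_partitions(list(range(net.n))):
        labels = np.empty(net.n, dtype=int)
        for cid, block in enumerate(part):
            labels[block] = cid
        q = modularity(net, labels)
        if q > best_q:
            best_q, best = q, labels
    return best_q, best


class TestModularity:
    def test_single_community_is_zero(self):
        net = two_cliques(4)
        assert modularity(net, np.zeros(net.n, dtype=int)) == pytest.approx(0.0)

    def test_two_disconnected_triangles_split_is_half(self):
        net = network_from_edges(6, [(0, 1), (1, 2), (0, 2),
                                     (3, 4), (4, 5), (3, 5)])
        assert modularity(net, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        net = network_from_edges(n, random_gnp_edges(n, 0.3, rng))
        labels = rng.integers(0, 4, size=n)
        assert -0.5 <= modularity(net, labels) <= 1.0

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            modularity(two_cliques(3), np.zeros(4, dtype=int))


class TestFastGreedy:
    def test_two_cliques_found(self):
        part = fast_greedy(two_cliques(4))
        assert part.n_communities == 2
        memb = part.membership
        assert memb.loc[1:4].nunique() == 1 and memb.loc[5:8].nunique() == 1

    def test_two_cliques_equals_bruteforce_optimum(self):
        net = two_cliques(4)
        part = fast_greedy(net)
        best_q, _ = best_partition_bruteforce(net)
        assert part.q == pytest.approx(best_q, abs=1e-12)

    def test_edgeless_graph_gives_singletons(self):
        net = network_from_edges(5, [])
        part = fast_greedy(net)
        assert part.n_communities == 5 and part.q == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_never_beats_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        net = network_from_edges(n, random_gnp_edges(n, 0.45, rng))
        part = fast_greedy(net)
        best_q, _ = best_partition_bruteforce(net)
        assert part.q <= best_q + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_reported_q_matches_formula(self, seed):
        """The greedy's incremental Q bookkeeping agrees with direct
        evaluation of the modularity formula on the returned partition."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 40))
        net = network_from_edges(n, random_gnp_edges(n, 0.2, rng))
        part = fast_greedy(net)
        assert part.q == pytest.approx(modularity(net, part.membership), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_no_community_spans_components(self, seed):
        rng = np.random.default_rng(seed)
        e1 = random_gnp_edges(6, 0.5, rng)
        e2 = [(u + 6, v + 6) for u, v in random_gnp_edges(6, 0.5, rng)]
        net = network_from_edges(12, e1 + e2)
        memb = fast_greedy(net).membership
        left = set(memb.loc[1:6])
        right = set(memb.loc[7:12])
        assert not (left & right)

    def test_deterministic(self, mixed_chain):
        net = build_pcn(mixed_chain)
        p1, p2 = fast_greedy(net), fast_greedy(net)
        assert p1.membership.equals(p2.membership) and p1.q == p2.q

    def test_agrees_with_igraph_on_fixture(self, mixed_chain):
        """Independent cross-check: same maximal Q as igraph's fast-greedy
        on the contact network of the mixed fixture."""
        igraph = pytest.importorskip("igraph")
        net = build_pcn(mixed_chain)
        pos = {n: k for k, n in enumerate(net.structure.author_numbers)}
        g = igraph.Graph(n=net.n,
                         edges=[(pos[i], pos[j]) for i, j in sorted(net.contacts)])
        ref = g.community_fastgreedy().as_clustering()
        ours = fast_greedy(net)
        assert ours.q == pytest.approx(g.modularity(ref.membership), abs=1e-9)
        assert ours.n_communities == len(ref)


class TestComparePartitions:
    def make(self, labels, sid="x"):
        idx = pd.Index(range(1, len(labels) + 1), name="residue")
        return CommunityPartition(structure_id=sid,
                                  membership=pd.Series(list(labels), index=idx),
                                  q=0.0)

    def test_identical_partitions_no_reassignment(self):
        p = self.make([0] * 5 + [1] * 5)
        cmpres = compare_partitions(p, p)
        assert cmpres.reassigned == ()
        assert cmpres.splits == {} and cmpres.merges == {}

    def test_label_permutation_invariance(self):
        p = self.make([0] * 5 + [1] * 5)
        q = self.make([3] * 5 + [0] * 5)
        cmpres = compare_partitions(p, q)
        assert cmpres.reassigned == ()

    def test_bisected_community_is_a_split(self):
        p = self.make([0] * 8 + [1] * 4)
        q = self.make([0] * 4 + [2] * 4 + [1] * 4)
        cmpres = compare_partitions(p, q)
        assert 0 in cmpres.splits and len(cmpres.splits[0]) == 2

    def test_merge_detection(self):
        p = self.make([0] * 4 + [1] * 4)
        q = self.make([0] * 8)
        cmpres = compare_partitions(p, q)
        assert 0 in cmpres.merges and set(cmpres.merges[0]) == {0, 1}

    def test_min_overlap_filters_flicker(self):
        p = self.make([0] * 9 + [1])
        q = self.make([0] * 9 + [2])
        # the single residue that moved is below min_overlap=3 on one side
        cmpres = compare_partitions(p, q, min_overlap=3)
        assert cmpres.splits == {}

    def test_overlap_counts_cover_all_matched(self):
        p = self.make([0, 0, 1, 1, 2, 2])
        q = self.make([1, 1, 1, 0, 0, 2])
        cmpres = compare_partitions(p, q)
        assert cmpres.overlap.values.sum() == 6
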