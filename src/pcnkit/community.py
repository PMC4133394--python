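"""Fast-greedy modularity communities and cross-structure comparison.

Community detection follows the Clauset-Newman-Moore agglomeration: start
from singleton communities, repeatedly merge the connected pair with the
largest modularity gain, and return the partition with the highest
modularity seen along the merge sequence.  Ties in the gain are broken by
the lexicographically smallest (min id, max id) community pair, which makes
runs bit-reproducible.

Modularity Q = sum_c (e_cc - a_c^2), where e_cc is the fraction of edges
with both ends in community c and a_c the fraction of edge endpoints in c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ContactNetwork
from .structure import ResidueMapping

__all__ = ["CommunityPartition", "PartitionComparison", "fast_greedy",
           "modularity", "compare_partitions"]


@dataclass(frozen=True)
class CommunityPartition:
    """Disjoint communities covering all residues of one network.

    ``membership`` maps author residue number -> community id (0-based,
    renumbered in order of first appearance along the chain).
    """

    structure_id: str
    membership: pd.Series
    q: float

    @property
    def n_communities(self) -> int:
        return int(self.membership.nunique())

    def community(self, cid: int) -> list[int]:
        return list(self.membership.index[self.membership == cid])


@dataclass(frozen=True)
class PartitionComparison:
    """How communities of a reference partition map onto another's.

    ``overlap`` is a contingency table (ref community x other community) of
    matched-residue counts; ``matched`` maps each ref community to the other
    community of maximal overlap; ``reassigned`` lists residues whose other
    community is not the one their ref community matched to; ``splits`` and
    ``merges`` list communities whose members land in >= 2 counterpart
    communities with at least ``min_overlap`` residues each.
    """

    overlap: pd.DataFrame
    matched: dict[int, int]
    reassigned: tuple[int, ...]
    splits: dict[int, tuple[int, ...]]
    merges: dict[int, tuple[int, ...]]


def modularity(network: ContactNetwork, membership: pd.Series | dict | np.ndarray) -> float:
    """Evaluate Q = sum_c (e_cc - a_c^2) for a given node partition.

    ``membership`` may be positional (array of length n) or indexed by
    author residue number.  A network with no edges has Q = 0.
    """
    nums = network.structure.author_numbers
    if isinstance(membership, pd.Series):
        labels = np.array([membership[n] for n in nums])
    elif isinstance(membership, dict):
        labels = np.array([membership[n] for n in nums])
    else:
        labels = np.asarray(membership)
        if labels.shape != (network.n,):
            raise ValueError(f"membership length {labels.shape} != n nodes {network.n}")
    m = network.n_edges
    if m == 0:
        return 0.0
    a = network.adjacency
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_cc = a[np.ix_(mask, mask)].sum() / (2.0 * m)
        a_c = a[mask].sum() / (2.0 * m)
        q += e_cc - a_c * a_c
    return float(q)


def fast_greedy(network: ContactNetwork) -> CommunityPartition:
    """Clauset-Newman-Moore greedy modularity maximisation.

    Deterministic: equal modularity gains are resolved toward the smallest
    (min community id, max community id) pair.  Only connected community
    pairs are merged, so no community ever spans two components.  Returns
    the partition at the maximal modularity along the merge sequence.
    """
    n = network.n
    m = network.n_edges
    nums = network.structure.author_numbers
    if m == 0:
        # singleton partition; Q = 0 by convention on an edgeless graph
        memb = pd.Series(range(n), index=pd.Index(nums, name="residue"))
        return CommunityPartition(structure_id=network.structure_id,
                                  membership=memb, q=0.0)

    adj = network.adjacency
    # e[i][j]: fraction of edges between communities i and j (symmetric);
    # a[i]: fraction of edge endpoints in community i
    e: list[dict[int, float]] = [dict() for _ in range(n)]
    for i in range(n):
        for j in np.nonzero(adj[i])[0]:
            e[i][int(j)] = 1.0 / (2.0 * m)
    a = [sum(row.values()) for row in e]
    alive = set(range(n))
    labels = list(range(n))  # node -> community id
    q = sum(e[i].get(i, 0.0) for i in range(n)) - sum(x * x for x in a)

    best_q = q
    best_labels = list(labels)
    while len(alive) > 1:
        best = None  # (dq, i, j)
        for i in sorted(alive):
            for j in sorted(e[i]):
                if j <= i or j not in alive:
                    continue
                dq = 2.0 * (e[i][j] - a[i] * a[j])
                if best is None or dq > best[0] + 1e-15:
                    best = (dq, i, j)
        if best is None:
            break  # remaining communities are in different components
        dq, i, j = best
        # merge j into i
        for k, v in e[j].items():
            if k == j:
                e[i][i] = e[i].get(i, 0.0) + v
            elif k == i:
                e[i][i] = e[i].get(i, 0.0) + 2.0 * v
            else:
                e[i][k] = e[i].get(k, 0.0) + v
                e[k][i] = e[k].get(i, 0.0) + v
            if k != j:
                e[k].pop(j, None)
        e[i].pop(j, None)
        e[j] = {}
        a[i] += a[j]
        a[j] = 0.0
        alive.discard(j)
        labels = [i if l == j else l for l in labels]
        q += dq
        if q > best_q + 1e-12:
            best_q = q
            best_labels = list(labels)

    # renumber communities in order of first appearance
    remap: dict[int, int] = {}
    out = []
    for l in best_labels:
        if l not in remap:
            remap[l] = len(remap)
        out.append(remap[l])
    memb = pd.Series(out, index=pd.Index(nums, name="residue"))
    return CommunityPartition(structure_id=network.structure_id,
                              membership=memb, q=float(best_q))


def compare_partitions(ref: CommunityPartition, other: CommunityPartition,
                       mapping: ResidueMapping | None = None,
                       min_overlap: int = 3) -> PartitionComparison:
    """Match communities between two partitions by maximal residue overlap.

    Residues are paired by author number (restricted to ``mapping`` when
    given).  Matching is greedy on descending overlap; split/merge events
    require at least ``min_overlap`` residues in each involved counterpart,
    filtering single-residue flicker.  The comparison is invariant to
    community relabelling on either side.
    """
    ref_m = ref.membership
    oth_m = other.membership
    if mapping is not None:
        common = [n for n in mapping.matched_numbers
                  if n in ref_m.index and n in oth_m.index]
    else:
        common = [n for n in ref_m.index if n in oth_m.index]
    if not common:
        raise ValueError("no shared residues between the two partitions")

    overlap = pd.crosstab(ref_m.loc[common], oth_m.loc[common])
    overlap.index.name = "ref_community"
    overlap.columns.name = "other_community"

    # greedy maximum-overlap matching
    cells = [(int(overlap.loc[r, c]), r, c)
             for r in overlap.index for c in overlap.columns
             if overlap.loc[r, c] > 0]
    cells.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched: dict[int, int] = {}
    used_other: set[int] = set()
    for cnt, r, c in cells:
        if r not in matched and c not in used_other:
            matched[r] = c
            used_other.add(c)

    reassigned = tuple(
        n for n in common
        if ref_m[n] in matched and oth_m[n] != matched[ref_m[n]]
    )
    splits = {}
    for r in overlap.index:
        targets = tuple(int(c) for c in overlap.columns
                        if overlap.loc[r, c] >= min_overlap)
        if len(targets) >= 2:
            splits[int(r)] = targets
    merges = {}
    for c in overlap.columns:
        sources = tuple(int(r) for r in overlap.index
                        if overlap.loc[r, c] >= min_overlap)
        if len(sources) >= 2:
            merges[int(c)] = sources
    return PartitionComparison(overlap=overlap, matched=matched,
                               reassigned=reassigned, splits=splits,
                               merges=merges)
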