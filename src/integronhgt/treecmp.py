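"""Quantitative tree-incongruence testing.

Host, integrase (IntI) and *attC* trees are compared through their
non-trivial bipartitions (splits): removing an internal edge of the
unrooted tree partitions the leaves into two sides, and two trees agree
on an edge exactly when they induce the same split.  The normalised
PH85 distance

    nPH85 = |A Δ B| / (|A| + |B|)

(A, B the two trees' split sets) is 0 for identical topologies and 1
for trees sharing no split; branch lengths are ignored.  Significance is
assessed by a label-permutation randomisation test: topologies are held
fixed while one tree's leaf labels are shuffled, which preserves tree
shape under the null of no association between the two leaf orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass(frozen=True)
class BipartitionSet:
    """Canonical non-trivial splits of a leaf-labelled tree.

    Each split is stored as one side only — the lexicographically
    smaller side (fewer leaves first; ties by sorted label tuple) — so
    set operations between trees compare splits directly.
    """

    leaf_universe: frozenset[str]
    splits: frozenset[frozenset[str]]

    def __len__(self) -> int:
        return len(self.splits)


def _canonical(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def _canonicalise_splits(
    raw_sides: set[frozenset[str]], universe: frozenset[str]
) -> frozenset[frozenset[str]]:
    out = set()
    for side in raw_sides:
        if 2 <= len(side) <= len(universe) - 2:
            out.add(_canonical(side, universe))
    return frozenset(out)


def bipartitions(tree: dendropy.Tree) -> BipartitionSet:
    """Extract the canonical non-trivial splits of a tree.

    Rooting is immaterial: the split of the edge above a node is the set
    of leaves below it, and complementary sides collapse to one
    canonical form.  Binary n-leaf trees yield exactly n - 3 splits;
    star trees yield none.
    """
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    universe = frozenset(labels)
    raw: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        raw.add(below)
    return BipartitionSet(universe, _canonicalise_splits(raw, universe))


def nph85(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Normalised bipartition distance between two trees on one leaf set.

    nPH85 = |A Δ B| / (|A| + |B|); 0 when both split sets are empty.
    Trees with differing leaf sets are a hard error — prune with
    :func:`restrict_to_common_leaves` first.
    """
    b1, b2 = bipartitions(t1), bipartitions(t2)
    if b1.leaf_universe != b2.leaf_universe:
        only1 = sorted(b1.leaf_universe - b2.leaf_universe)
        only2 = sorted(b2.leaf_universe - b1.leaf_universe)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    return _nph85_sets(b1.splits, b2.splits)


def _nph85_sets(a: frozenset[frozenset[str]], b: frozenset[frozenset[str]]) -> float:
    if not a and not b:
        return 0.0
    return len(a ^ b) / (len(a) + len(b))


def restrict_to_common_leaves(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    label_map: dict[str, str] | None = None,
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Prune both trees to their shared leaf set.

    ``label_map`` renames t2's leaves into t1's name space first (host
    and *attC* trees rarely share tip names verbatim).  Degree-2 nodes
    created by pruning are suppressed with branch lengths summed.
    Fewer than 4 common leaves is a hard error.
    """
    t1 = t1.clone(depth=1)
    t2 = t2.clone(depth=1)
    if label_map:
        for leaf in t2.leaf_node_iter():
            if leaf.taxon.label in label_map:
                leaf.taxon.label = label_map[leaf.taxon.label]
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    common = l1 & l2
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} common leaves after mapping; need at least 4"
        )
    for t in (t1, t2):
        t.retain_taxa_with_labels(common)
        t.suppress_unifurcations()
    return t1, t2


def randomisation_test(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    n_rand: int = 10_000,
    seed: int | None = None,
    scheme: str = "permute_labels",
) -> tuple[float, float]:
    """Observed nPH85 plus a permutation p-value for congruence.

    The null distribution holds both topologies fixed and permutes t2's
    leaf labels uniformly at random ``n_rand`` times (``scheme
    "random_topology"`` instead redraws t2 as a uniformly random binary
    topology on the same leaves).  The one-sided, +1-smoothed p-value

        p = (1 + #{nPH85_perm <= nPH85_obs}) / (n_rand + 1)

    is small when the trees are more congruent than chance.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if scheme not in ("permute_labels", "random_topology"):
        raise ValueError(f"unknown randomisation scheme {scheme!r}")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    if b1.leaf_universe != b2.leaf_universe:
        raise ValueError("leaf sets differ; restrict_to_common_leaves first")
    observed = _nph85_sets(b1.splits, b2.splits)

    rng = np.random.default_rng(seed)
    labels = sorted(b1.leaf_universe)
    universe = b1.leaf_universe
    count_le = 0
    for _ in range(n_rand):
        if scheme == "permute_labels":
            perm = rng.permutation(len(labels))
            mapping = {labels[i]: labels[perm[i]] for i in range(len(labels))}
            permuted = _canonicalise_splits(
                {frozenset(mapping[x] for x in side) for side in b2.splits},
                universe,
            )
        else:
            permuted = _random_binary_splits(labels, rng)
        if _nph85_sets(b1.splits, permuted) <= observed:
            count_le += 1
    p = (1 + count_le) / (n_rand + 1)
    return observed, p


def _random_binary_splits(
    labels: list[str], rng: np.random.Generator
) -> frozenset[frozenset[str]]:
    """Splits of a uniformly random unrooted binary topology (sequential
    random-edge leaf addition)."""
    # grow an edge list over node ids; leaves are 0..n-1
    n = len(labels)
    edges: list[tuple[int, int]] = [(0, 1), (1, 2), (0, 2)] if n == 3 else []
    if n < 4:
        return frozenset()
    next_id = n  # internal node ids from n upward
    edges = [(0, next_id), (1, next_id), (2, next_id)]
    next_id += 1
    for leaf in range(3, n):
        ei = int(rng.integers(len(edges)))
        u, v = edges.pop(ei)
        mid = next_id
        next_id += 1
        edges.extend([(u, mid), (v, mid), (leaf, mid)])
    # adjacency; splits from internal edges by flood fill
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    universe = frozenset(labels)
    raw: set[frozenset[str]] = set()
    for u, v in edges:
        if u < n or v < n:
            continue  # pendant edge -> trivial split
        side: set[int] = set()
        stack = [u]
        seen = {v}
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x < n:
                side.add(x)
            stack.extend(adj[x])
        raw.add(frozenset(labels[i] for i in side))
    return _canonicalise_splits(raw, universe)
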