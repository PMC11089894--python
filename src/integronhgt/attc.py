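"""Structure-based comparison of *attC* recombination sites.

Integron integrases recognise *attC* sites by their folded single-stranded
secondary structure, not by primary sequence, so *attC* relatedness is
assessed on structures.  The chain here is deliberately simple and fully
deterministic so that every step has an exact oracle:

1. fold each site by maximum base pairing (Nussinov-style dynamic
   programming over nested structures, AU/GC and optional GU wobble,
   minimum hairpin loop of 3);
2. compare folds with a normalised mountain metric — the mean absolute
   difference between length-normalised "mountain" height profiles
   (height at position k = number of pairs enclosing k), sampled at
   evenly spaced relative positions so sites of different lengths are
   comparable;
3. pick the k most representative sites per bacterial clade by medoid
   centrality (smallest summed distance to clade-mates);
4. cluster the pooled representatives into a rooted ultrametric WPGMA
   tree (McQuitty linkage: merged-cluster distances are plain means of
   the two constituents).

Topology-level conclusions (which clades separate) are the target;
thermodynamic folding and sequence-structure alignment are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .model import CassetteRecord, SecondaryStructure

log = logging.getLogger(__name__)

_RNA_MAP = str.maketrans("Tt", "Uu")
_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


def _pairable(a: str, b: str, allow_gu: bool) -> bool:
    if (a, b) in _WC_PAIRS:
        return True
    return allow_gu and (a, b) in _GU_PAIRS


def fold_attc(sequence: str, min_loop: int = 3, allow_gu: bool = True) -> SecondaryStructure:
    """Fold a DNA/RNA sequence by maximum base pairing.

    The dynamic programme maximises the number of nested AU/GC (and,
    by default, GU) pairs with hairpin loops of at least ``min_loop``
    unpaired bases.  Among co-optimal structures the traceback pairs the
    smallest available 5' index first and, for that index, chooses the
    partner of largest span — a fixed rule so folds are reproducible
    across platforms.
    """
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    rna = sequence.upper().translate(_RNA_MAP)
    bad = set(rna) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide character(s) {sorted(bad)} in sequence")
    n = len(rna)
    # M[i][j] = max pairs on rna[i..j] inclusive
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _pairable(rna[i], rna[k], allow_gu):
                    inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = M[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
                    # N never pairs (not in the pairing sets)
            M[i][j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = M[i][j]
        if target == 0:
            continue
        # prefer pairing the 5'-most index; among its co-optimal partners
        # take the largest span (largest k)
        chosen = None
        for k in range(j, i + min_loop, -1):
            if _pairable(rna[i], rna[k], allow_gu):
                inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                right = M[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == target:
                    chosen = k
                    break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.add((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
    return SecondaryStructure(sequence=rna, pairs=frozenset(pairs))


def mountain_heights(s: SecondaryStructure) -> np.ndarray:
    """Length-normalised mountain profile: h[k] = (#pairs enclosing k)/L,
    where a pair (i, j) encloses positions i <= k < j."""
    n = len(s)
    h = np.zeros(n)
    for i, j in s.pairs:
        h[i:j] += 1.0
    return h / n


def structure_distance(
    s1: SecondaryStructure, s2: SecondaryStructure, n_samples: int = 100
) -> float:
    """Normalised mountain distance between two folds.

    Both height profiles are sampled at ``n_samples`` evenly spaced
    relative positions x_t = (t + 0.5)/n_samples (index floor(x * L)),
    and the distance is the mean absolute difference.  This is a
    pseudo-metric: zero on identical profiles, symmetric, and it
    satisfies the triangle inequality on the sampled vectors.
    """
    h1, h2 = mountain_heights(s1), mountain_heights(s2)
    x = (np.arange(n_samples) + 0.5) / n_samples
    v1 = h1[np.floor(x * len(s1)).astype(int)]
    v2 = h2[np.floor(x * len(s2)).astype(int)]
    return float(np.mean(np.abs(v1 - v2)))


def sampled_heights(s: SecondaryStructure, n_samples: int = 100) -> np.ndarray:
    """The sampled height vector underlying :func:`structure_distance`."""
    h = mountain_heights(s)
    x = (np.arange(n_samples) + 0.5) / n_samples
    return h[np.floor(x * len(s)).astype(int)]


def pairwise_distances(
    structures: Mapping[str, SecondaryStructure], n_samples: int = 100
) -> DistanceMatrix:
    labels = tuple(sorted(structures))
    vecs = np.stack([sampled_heights(structures[l], n_samples) for l in labels])
    # mean |v_i - v_j| over the shared sample grid
    d = np.abs(vecs[:, None, :] - vecs[None, :, :]).mean(axis=2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(labels=labels, values=d)


def select_representatives(
    attcs: Mapping[str, Sequence[tuple[str, SecondaryStructure]]],
    k: int = 10,
    n_samples: int = 100,
) -> dict[str, list[str]]:
    """Per clade, the ``k`` most representative *attC* ids by medoid
    centrality.

    Structures are first deduplicated within each clade by exact
    sequence + dot-bracket equality (non-redundant sets); each remaining
    member is scored by its summed distance to all members, and the k
    smallest sums win (ties by id).  Clades with <= k members return all.
    """
    result: dict[str, list[str]] = {}
    for clade, members in attcs.items():
        seen: set[tuple[str, str]] = set()
        unique: list[tuple[str, SecondaryStructure]] = []
        for attc_id, s in sorted(members, key=lambda t: t[0]):
            key = (s.sequence, s.dot_bracket)
            if key in seen:
                continue
            seen.add(key)
            unique.append((attc_id, s))
        if len(unique) <= k:
            result[clade] = [i for i, _ in unique]
            continue
        dm = pairwise_distances({i: s for i, s in unique}, n_samples)
        row_sums = dm.values.sum(axis=1)
        order = sorted(zip(row_sums, dm.labels))
        result[clade] = sorted(i for _, i in order[:k])
    return result


def wpgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Agglomerate a distance matrix into a rooted ultrametric WPGMA tree.

    At each step the two clusters at minimum distance merge at height
    d/2; the merged cluster's distance to any other is the arithmetic
    mean of the two constituents' distances (McQuitty linkage).  Ties are
    broken by the lexicographically smallest pair of cluster keys, where
    a cluster's key is its smallest leaf label (logged).
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("WPGMA needs at least 2 labels")

    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)

    # cluster state: key -> (height, node)
    nodes: dict[str, dendropy.Node] = {}
    heights: dict[str, float] = {}
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes[label] = node
        heights[label] = 0.0
    dist: dict[frozenset[str], float] = {}
    for ia, a in enumerate(dm.labels):
        for b in dm.labels[ia + 1:]:
            dist[frozenset((a, b))] = dm.get(a, b)

    active = sorted(dm.labels)
    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        n_at_min = 0
        for ia, a in enumerate(active):
            for b in active[ia + 1:]:
                d = dist[frozenset((a, b))]
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
                    n_at_min = 1
                elif abs(d - best[0]) <= 1e-15:
                    n_at_min += 1
                    if (a, b) < (best[1], best[2]):
                        best = (best[0], a, b)
        assert best is not None
        d, a, b = best
        if n_at_min > 1:
            log.info("WPGMA tie at distance %g; merging (%s, %s)", d, a, b)
        h = d / 2
        parent = dendropy.Node()
        for child_key in (a, b):
            child = nodes[child_key]
            child.edge.length = h - heights[child_key]
            parent.add_child(child)
        key = min(a, b)
        nodes.pop(a), nodes.pop(b)
        heights.pop(a), heights.pop(b)
        nodes[key] = parent
        heights[key] = h
        active.remove(a)
        active.remove(b)
        for other in active:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((key, other))] = (da + db) / 2
        dist.pop(frozenset((a, b)))
        active.append(key)
        active.sort()

    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    return tree


def build_attc_tree(
    records: Sequence[CassetteRecord], k: int = 10, n_samples: int = 100
) -> dendropy.Tree:
    """Fold, select per-clade representatives, and cluster into the
    structure-based *attC* tree.  Leaves are labelled ``clade|attc_id``.

    Clades without any usable *attC* sequence are dropped with a warning;
    at least two clades must remain.
    """
    by_clade: dict[str, list[tuple[str, SecondaryStructure]]] = {}
    for rec in records:
        if not rec.attc_sequence:
            continue
        clade = rec.clade_label or "unassigned"
        by_clade.setdefault(clade, []).append(
            (rec.cassette_id, fold_attc(rec.attc_sequence))
        )
    empty = {rec.clade_label for rec in records
             if rec.clade_label and rec.clade_label not in by_clade}
    for clade in sorted(empty):
        log.warning("clade %r has no usable attC sequence; dropped", clade)
    if len(by_clade) < 2:
        raise ValueError("need attC sequences from at least 2 clades")

    reps = select_representatives(by_clade, k=k, n_samples=n_samples)
    pooled: dict[str, SecondaryStructure] = {}
    for clade, ids in reps.items():
        id_map = dict(by_clade[clade])
        for attc_id in ids:
            pooled[f"{clade}|{attc_id}"] = id_map[attc_id]
    dm = pairwise_distances(pooled, n_samples)
    return wpgma_tree(dm)
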