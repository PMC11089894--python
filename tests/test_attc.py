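"""attC folding, structural distances, representative selection, WPGMA."""

import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy
from hypothesis import given, settings
from hypothesis import strategies as st

from integronhgt.attc import (
    DistanceMatrix,
    build_attc_tree,
    fold_attc,
    mountain_heights,
    pairwise_distances,
    sampled_heights,
    select_representatives,
    structure_distance,
    wpgma_tree,
)
from integronhgt.io import tree_to_newick
from integronhgt.model import CassetteRecord, SecondaryStructure
from integronhgt.simulate import AttcTemplate, generate_attc

from oracles import max_pairs_exhaustive


class TestFold:
    def test_no_complementary_bases(self):
        s = fold_attc("AAAA")
        assert s.pairs == frozenset()
        assert s.dot_bracket == "...."

    def test_perfect_hairpin(self):
        s = fold_attc("GGGAAAACCC", min_loop=3)
        assert s.pairs == frozenset({(0, 9), (1, 8), (2, 7)})
        assert s.dot_bracket == "(((....)))"

    def test_min_loop_respected(self):
        s = fold_attc("GC", min_loop=3)
        assert s.pairs == frozenset()
        for i, j in fold_attc("GCGCGCGCGCGC", min_loop=3).pairs:
            assert j - i - 1 >= 3

    def test_gu_wobble_toggle(self):
        with_gu = fold_attc("GGGAAAAUUU", allow_gu=True)
        without = fold_attc("GGGAAAAUUU", allow_gu=False)
        assert len(with_gu.pairs) >= len(without.pairs)

    def test_dna_input_mapped_to_rna(self):
        s = fold_attc("GGGAAAACCC")
        assert "T" not in s.sequence

    def test_invalid_character_is_error(self):
        with pytest.raises(ValueError):
            fold_attc("ACGX")

    def test_deterministic(self):
        seq = "GCAUGCAUGCAUGCAUGC"
        assert fold_attc(seq).pairs == fold_attc(seq).pairs

    @given(st.text(alphabet="ACGU", min_size=1, max_size=18))
    @settings(max_examples=250, deadline=None, derandomize=True)
    def test_optimal_pair_count_up_to_18nt(self, seq):
        """The DP fold attains the exhaustive-enumeration maximum."""
        folded = fold_attc(seq)
        assert len(folded.pairs) == max_pairs_exhaustive(seq)


def _structs(n=12, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        length = int(rng.integers(10, 40))
        seq = "".join(rng.choice(list("ACGU"), length))
        out.append(fold_attc(seq))
    return out


class TestStructureDistance:
    def test_identity(self):
        for s in _structs(5):
            assert structure_distance(s, s) == 0.0

    def test_symmetry(self):
        structs = _structs(6, seed=1)
        for a, b in itertools.combinations(structs, 2):
            assert structure_distance(a, b) == pytest.approx(
                structure_distance(b, a), abs=1e-15
            )

    def test_triangle_inequality(self):
        structs = _structs(8, seed=2)
        for a, b, c in itertools.combinations(structs, 3):
            dab = structure_distance(a, b)
            dbc = structure_distance(b, c)
            dac = structure_distance(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_hand_computed_value(self):
        # 3 stacked pairs on 10 nt vs fully unpaired: heights of the paired
        # structure are (1,2,3,3,3,3,3,2,1,0)/10; mean |h| over the sample
        # grid equals the mean of the sampled heights.
        paired = SecondaryStructure("GGGAAAACCC", frozenset({(0, 9), (1, 8), (2, 7)}))
        unpaired = SecondaryStructure("AAAAAAAAAA", frozenset())
        h = mountain_heights(paired)
        x = (np.arange(100) + 0.5) / 100
        expected = np.mean(h[np.floor(x * 10).astype(int)])
        assert structure_distance(paired, unpaired) == pytest.approx(expected)

    def test_distance_uses_sampled_height_vectors(self):
        a, b = _structs(2, seed=3)
        va, vb = sampled_heights(a), sampled_heights(b)
        assert structure_distance(a, b) == pytest.approx(np.abs(va - vb).mean())


class TestRepresentatives:
    def test_small_clade_returns_all(self):
        seqs = ["GGGAAAACCC", "GGAAAAGCCC", "GCGAAAACGC", "AGGAAAACCU"]
        structs = [(f"a{i}", fold_attc(s)) for i, s in enumerate(seqs)]
        reps = select_representatives({"cladeA": structs}, k=10)
        assert reps["cladeA"] == [f"a{i}" for i in range(4)]

    def test_outlier_excluded(self):
        hairpin = fold_attc("GGGGGAAAACCCCC")
        flat = fold_attc("AAAAAAAAAAAAAA")
        members = [("m1", hairpin),
                   ("m2", fold_attc("GGGGGAAAACCCCC")),
                   ("m3", flat)]
        # m1/m2 identical structures dedupe to one; force distinct sequences
        members = [("m1", hairpin),
                   ("m2", fold_attc("CCCCCAAAAGGGGG")),
                   ("m3", flat)]
        reps = select_representatives({"c": members}, k=2)
        assert "m3" not in reps["c"]

    def test_k1_is_medoid(self):
        structs = {f"s{i}": s for i, s in enumerate(_structs(5, seed=7))}
        dm = pairwise_distances(structs)
        medoid = dm.labels[int(np.argmin(dm.values.sum(axis=1)))]
        reps = select_representatives(
            {"c": list(structs.items())}, k=1
        )
        assert reps["c"] == [medoid]

    def test_redundant_structures_deduplicated(self):
        s = fold_attc("GGGAAAACCC")
        members = [(f"m{i}", s) for i in range(20)]
        reps = select_representatives({"c": members}, k=10)
        assert reps["c"] == ["m0"]


def _dm(labels, entries):
    n = len(labels)
    m = np.zeros((n, n))
    for (a, b), v in entries.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(tuple(labels), m)


class TestWpgma:
    def test_two_taxa_cherry(self):
        t = wpgma_tree(_dm(["A", "B"], {("A", "B"): 4.0}))
        (a, b) = t.seed_node.child_nodes()
        assert a.edge.length == b.edge.length == 2.0

    def test_hand_executed_merge_sequence(self):
        dm = _dm(
            ["A", "B", "C", "D"],
            {("A", "B"): 2, ("A", "C"): 4, ("A", "D"): 6,
             ("B", "C"): 4, ("B", "D"): 6, ("C", "D"): 6},
        )
        t = wpgma_tree(dm)
        assert tree_to_newick(t) == "(((A:1.0,B:1.0):1.0,C:2.0):1.0,D:3.0);"

    def test_ultrametric_input_reproduced_exactly(self):
        # cophenetic matrix of ((A,B):h1,(C,D):h2) at heights 1, 2, root 5
        labels = ["A", "B", "C", "D"]
        dm = _dm(labels, {("A", "B"): 2, ("C", "D"): 4,
                          ("A", "C"): 10, ("A", "D"): 10,
                          ("B", "C"): 10, ("B", "D"): 10})
        t = wpgma_tree(dm)
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for a, b in itertools.combinations(labels, 2):
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                dm.get(a, b), abs=1e-12
            )

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(12)
        labels = [f"t{i}" for i in range(7)]
        m = rng.random((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        t = wpgma_tree(DistanceMatrix(tuple(labels), m))
        depths = {lf.taxon.label: lf.distance_from_root() for lf in t.leaf_node_iter()}
        vals = list(depths.values())
        assert max(vals) - min(vals) < 1e-9

    def test_matches_scipy_weighted_linkage_heights(self):
        rng = np.random.default_rng(3)
        n = 6
        m = rng.random((n, n)) + 0.1
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = tuple(f"x{i}" for i in range(n))
        t = wpgma_tree(DistanceMatrix(labels, m))
        root_height = next(iter(t.leaf_node_iter())).distance_from_root()
        condensed = m[np.triu_indices(n, 1)]
        link = scipy.cluster.hierarchy.linkage(condensed, method="weighted")
        assert root_height == pytest.approx(link[-1, 2] / 2, rel=1e-9)

    def test_asymmetric_matrix_is_error(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))


def _clade_records(templates, n_per_clade=6, seed=0):
    records = []
    for t_i, tmpl in enumerate(templates):
        for s_i, seq in enumerate(generate_attc(tmpl, n_per_clade, seed=seed + t_i)):
            records.append(
                CassetteRecord(
                    cassette_id=f"a{t_i}_{s_i:02d}",
                    genome_id="g",
                    species_label=f"sp{t_i}",
                    clade_label=tmpl.clade_label,
                    plant_site="not_announced",
                    sequence=seq,
                    attc_sequence=seq,
                )
            )
    return records


# The package's default clade templates have distinct paired fractions
# (stem length over total length): the normalised mountain profile is
# scale-free, so hairpins with the same ratio look alike at any size.
from integronhgt.simulate import DEFAULT_ATTC_TEMPLATES

TEMPLATES = list(DEFAULT_ATTC_TEMPLATES)


class TestBuildAttcTree:
    def test_deepest_split_separates_templates(self):
        records = _clade_records(TEMPLATES, seed=21)
        tree = build_attc_tree(records, k=10)
        sides = [
            {lf.taxon.label.split("|")[0] for lf in ch.leaf_iter()}
            for ch in tree.seed_node.child_nodes()
        ]
        assert {frozenset(s) for s in sides} == {
            frozenset({t.clade_label}) for t in TEMPLATES
        }

    def test_within_clade_distance_below_between(self):
        records = _clade_records(TEMPLATES, seed=5)
        structs = {r.cassette_id: fold_attc(r.attc_sequence) for r in records}
        clades = {r.cassette_id: r.clade_label for r in records}
        dm = pairwise_distances(structs)
        within, between = [], []
        for (i, a), (j, b) in itertools.combinations(enumerate(dm.labels), 2):
            (within if clades[a] == clades[b] else between).append(dm.values[i, j])
        assert np.mean(within) < np.mean(between)

    def test_single_clade_is_error(self):
        records = _clade_records(TEMPLATES[:1], seed=2)
        with pytest.raises(ValueError):
            build_attc_tree(records)

    def test_reproducible_newick(self):
        records = _clade_records(TEMPLATES, seed=8)
        t1 = build_attc_tree(records, k=5)
        t2 = build_attc_tree(records, k=5)
        assert tree_to_newick(t1) == tree_to_newick(t2)
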