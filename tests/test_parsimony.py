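"""Fitch/Hartigan scoring against brute-force minimization, and MP search."""

import itertools
import random

import numpy as np
import pytest

from supertree.encoding import CharacterMatrix, encode_baum_ragan
from supertree.parsimony import (
    MPSearchConfig,
    _BitData,
    fitch_column_score,
    mp_score,
    mp_search,
    mp_search_constrained,
)
from supertree.trees import SourceProfile, bipartitions, parse_newick

from conftest import random_binary_tree, random_topology


def brute_force_changes(tree, column):
    """Minimum 0/1 changes over all internal assignments and '?' choices."""
    nodes = list(tree.preorder())
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    leaf_choices = [
        [column[l.label]] if column.get(l.label, "?") != "?" else [0, 1]
        for l in leaves
    ]
    best = None
    for internal_states in itertools.product([0, 1], repeat=len(internals)):
        smap = dict(zip((id(n) for n in internals), internal_states))
        for leaf_states in itertools.product(*leaf_choices):
            smap.update(zip((id(n) for n in leaves), leaf_states))
            changes = sum(
                1
                for n in nodes
                if n.parent is not None and smap[id(n)] != smap[id(n.parent)]
            )
            best = changes if best is None else min(best, changes)
    return best


def random_column(labels, rng, q_prob=0.3):
    return {lb: rng.choice([0, 1, "?"] if rng.random() < q_prob else [0, 1])
            for lb in labels}


class TestFitchColumnScore:
    def test_compatible_quartet_costs_one(self):
        tree = parse_newick("((a,b),(c,d));")
        assert fitch_column_score(tree, {"a": 0, "b": 0, "c": 1, "d": 1}) == 1

    def test_conflicting_quartet_costs_two(self):
        tree = parse_newick("((a,b),(c,d));")
        assert fitch_column_score(tree, {"a": 0, "b": 1, "c": 0, "d": 1}) == 2

    def test_single_observed_state_costs_zero(self):
        tree = parse_newick("((a,b),(c,d),e);")
        assert fitch_column_score(tree, {"a": 1}) == 0
        assert fitch_column_score(tree, {}) == 0

    def test_matches_brute_force_on_random_cases(self):
        # oracle equivalence with '?' and polytomies, trees up to 7 leaves
        rng = random.Random(11)
        for _ in range(150):
            n = rng.randint(4, 7)
            labels = [f"t{i}" for i in range(n)]
            tree = random_topology(labels, rng, polytomy_prob=0.4)
            column = random_column(labels, rng)
            assert fitch_column_score(tree, column) == brute_force_changes(tree, column)

    def test_invariant_to_anchor(self):
        t1 = parse_newick("(((a,b),c),(d,e));")
        t2 = parse_newick("((d,e),(c,(a,b)));")
        col = {"a": 0, "b": 1, "c": 1, "d": 0, "e": 1}
        assert fitch_column_score(t1, col) == fitch_column_score(t2, col)


class TestBitParallelPath:
    def test_agrees_with_hartigan_on_binary_trees(self, rng):
        for _ in range(25):
            n = rng.randint(4, 12)
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng)
            ncol = rng.randint(1, 8)
            data = np.array(
                [[rng.choice([0, 1, 2]) for _ in range(ncol)] for _ in labels],
                dtype=np.uint8,
            )
            matrix = CharacterMatrix(taxa=labels, data=data)
            assert _BitData(matrix).score(tree) == mp_score(tree, matrix)


class TestMPScore:
    def test_own_encoding_has_no_homoplasy(self, rng):
        # a compatible binary column costs exactly 1, so a tree scored
        # against its own encoding scores ncol
        tree = random_binary_tree([f"t{i}" for i in range(10)], rng)
        matrix = encode_baum_ragan(SourceProfile([tree]))
        assert mp_score(tree, matrix) == matrix.ncol

    def test_star_tree_scores_brute_force(self):
        # each informative column on a star costs min(#0, #1)
        star = parse_newick("(a,b,c,d,e);")
        data = np.array(
            [[0, 0], [0, 0], [1, 1], [1, 1], [1, 0]], dtype=np.uint8
        )
        matrix = CharacterMatrix(taxa=list("abcde"), data=data)
        expected = sum(
            brute_force_changes(star, {t: int(data[i, j]) for i, t in enumerate("abcde")})
            for j in range(2)
        )
        assert mp_score(star, matrix) == expected

    def test_invariant_to_rerooting(self, rng):
        t1 = parse_newick("(((a,b),c),((d,e),f));")
        t2 = parse_newick("((d,e),(f,(c,(a,b))));")
        matrix = encode_baum_ragan(
            SourceProfile([random_binary_tree(list("abcdef"), rng)])
        )
        assert mp_score(t1, matrix) == mp_score(t2, matrix)

    def test_matrix_taxon_absent_from_tree_rejected(self):
        matrix = CharacterMatrix(
            taxa=list("abcde"),
            data=np.array([[0], [0], [1], [1], [0]], dtype=np.uint8),
        )
        with pytest.raises(ValueError):
            mp_score(parse_newick("((a,b),(c,d));"), matrix)

    def test_at_least_ncol_when_columns_informative(self, rng):
        trees = [random_binary_tree([f"t{i}" for i in range(8)], rng) for _ in range(3)]
        matrix = encode_baum_ragan(SourceProfile(trees))
        other = random_binary_tree([f"t{i}" for i in range(8)], rng)
        assert mp_score(other, matrix) >= matrix.ncol


class TestMPSearch:
    def test_recovers_compatible_profile(self, rng):
        model = random_binary_tree([f"t{i}" for i in range(8)], rng)
        matrix = encode_baum_ragan(SourceProfile([model]))
        trees, report = mp_search(matrix, MPSearchConfig(n_starts=2, seed=5))
        assert report.mp_score == matrix.ncol
        keys = {t.topology_key() for t in trees}
        assert model.topology_key() in keys

    def test_four_taxa_matches_exhaustive(self, rng):
        quartets = [
            parse_newick(s)
            for s in ("((a,b),(c,d));", "((a,c),(b,d));", "((a,d),(b,c));")
        ]
        for trial in range(10):
            data = np.array(
                [[rng.choice([0, 1]) for _ in range(6)] for _ in range(4)],
                dtype=np.uint8,
            )
            matrix = CharacterMatrix(taxa=list("abcd"), data=data)
            best = min(mp_score(q, matrix) for q in quartets)
            _trees, report = mp_search(matrix, MPSearchConfig(n_starts=2, seed=trial))
            assert report.mp_score == best

    def test_same_seed_same_result(self, rng):
        trees = [random_binary_tree([f"t{i}" for i in range(9)], rng) for _ in range(3)]
        matrix = encode_baum_ragan(SourceProfile(trees))
        out1, _ = mp_search(matrix, MPSearchConfig(seed=3))
        out2, _ = mp_search(matrix, MPSearchConfig(seed=3))
        assert [t.newick() for t in out1] == [t.newick() for t in out2]

    def test_all_missing_rows_dropped_with_warning(self):
        data = np.array(
            [[0, 0], [0, 0], [1, 1], [1, 1], [0, 1], [2, 2]], dtype=np.uint8
        )
        matrix = CharacterMatrix(taxa=list("abcdeg"), data=data)
        with pytest.warns(UserWarning):
            trees, _ = mp_search(matrix, MPSearchConfig(n_starts=1, seed=0))
        assert "g" not in trees[0].leaf_labels


class TestConstrainedSearch:
    def test_binary_constraint_returned(self, rng):
        model = random_binary_tree([f"t{i}" for i in range(7)], rng)
        matrix = encode_baum_ragan(SourceProfile([model]))
        trees, _ = mp_search_constrained(matrix, model, MPSearchConfig(seed=1))
        assert [t.topology_key() for t in trees] == [model.topology_key()]

    def test_star_constraint_like_unconstrained(self, rng):
        model = random_binary_tree([f"t{i}" for i in range(7)], rng)
        matrix = encode_baum_ragan(SourceProfile([model]))
        star = parse_newick("(" + ",".join(sorted(model.leaf_labels)) + ");")
        trees, report = mp_search_constrained(matrix, star, MPSearchConfig(seed=1))
        assert report.mp_score == matrix.ncol

    def test_six_taxa_against_filtered_exhaustive(self, rng):
        # constraint: one fixed cherry; compare with brute force over all
        # binary trees honoring it
        labels = list("abcdef")
        model = random_binary_tree(labels, rng)
        matrix = encode_baum_ragan(SourceProfile([model, random_binary_tree(labels, rng)]))
        constraint = parse_newick("((a,b),c,d,e,f);")
        trees, report = mp_search_constrained(
            matrix, constraint, MPSearchConfig(n_starts=4, seed=2)
        )
        required = constraint.topology_key()
        best = None
        for t in _all_binary_trees(labels):
            if required <= t.topology_key():
                s = mp_score(t, matrix)
                best = s if best is None else min(best, s)
        assert report.mp_score == best
        for t in trees:
            assert required <= t.topology_key()


def _all_binary_trees(labels):
    """Enumerate all unrooted binary topologies by sequential insertion."""
    from supertree.trees import Node, Tree

    def grow(tree, remaining):
        if not remaining:
            yield tree
            return
        label = remaining[0]
        edges = [n for n in tree.preorder() if n.parent is not None]
        for i in range(len(edges)):
            work = tree.copy()
            target = [n for n in work.preorder() if n.parent is not None][i]
            parent = target.parent
            mid = Node()
            idx = parent.children.index(target)
            parent.children[idx] = mid
            mid.parent = parent
            target.parent = mid
            mid.children.append(target)
            mid.add(Node(label))
            yield from grow(work, remaining[1:])

    root = Node()
    for lb in labels[:3]:
        root.add(Node(lb))
    yield from grow(Tree(root), labels[3:])
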