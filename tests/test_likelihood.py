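"""CFN + discrete-gamma likelihood against closed forms and enumeration."""

import itertools
import math
import random

import numpy as np
import pytest

from supertree.encoding import CharacterMatrix, encode_baum_ragan
from supertree.likelihood import (
    GammaRates,
    MLSearchConfig,
    ml_search,
    mrl_score,
    optimize_alpha,
    optimize_branch_lengths,
    site_log_likelihood,
    transition_probabilities,
    tree_log_likelihood,
    with_branch_lengths,
)
from supertree.parsimony import mp_score
from supertree.synthetic import simulate_characters
from supertree.trees import SourceProfile, parse_newick

from conftest import random_binary_tree, random_topology


def brute_force_site_likelihood(tree, column, rate):
    """Exhaustive sum over internal states (and '?' leaf states)."""
    nodes = list(tree.preorder())
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    leaf_choices = [
        [column[l.label]] if column.get(l.label, "?") != "?" else [0, 1]
        for l in leaves
    ]
    total = 0.0
    for istates in itertools.product([0, 1], repeat=len(internals)):
        smap = dict(zip((id(n) for n in internals), istates))
        for lstates in itertools.product(*leaf_choices):
            smap.update(zip((id(n) for n in leaves), lstates))
            p = 0.5
            for n in nodes:
                if n.parent is None:
                    continue
                same, change = transition_probabilities(n.length, rate)
                p *= change if smap[id(n)] != smap[id(n.parent)] else same
            total += p
    return total


def random_lengths(tree, rng):
    for n in tree.preorder():
        if n.parent is not None:
            n.length = rng.uniform(0.01, 1.2)
    return tree


class TestSiteLikelihood:
    def test_two_leaf_same_state_closed_form(self):
        for t in (0.05, 0.3, 1.0, 4.0):
            tree = parse_newick(f"(a:{t / 2},b:{t / 2});")
            ll = site_log_likelihood(tree, {"a": 0, "b": 0})
            assert math.exp(ll) == pytest.approx((1 + math.exp(-2 * t)) / 4, abs=1e-12)

    def test_two_leaf_limits(self):
        near_zero = parse_newick("(a:1e-9,b:1e-9);")
        assert math.exp(site_log_likelihood(near_zero, {"a": 0, "b": 0})) == pytest.approx(0.5, abs=1e-6)
        assert math.exp(site_log_likelihood(near_zero, {"a": 0, "b": 1})) == pytest.approx(0.0, abs=1e-6)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            site_log_likelihood(parse_newick("(a:-0.1,b:0.2);"), {"a": 0, "b": 0})

    def test_matches_enumeration_random_cases(self):
        rng = random.Random(23)
        for _ in range(100):
            n = rng.randint(4, 6)
            labels = [f"t{i}" for i in range(n)]
            tree = random_lengths(random_topology(labels, rng, polytomy_prob=0.35), rng)
            column = {
                lb: rng.choice([0, 1, "?"]) for lb in labels
            }
            rate = rng.uniform(0.2, 2.5)
            ll = site_log_likelihood(tree, column, rate=rate)
            brute = brute_force_site_likelihood(tree, column, rate)
            assert math.exp(ll) == pytest.approx(brute, abs=1e-10)

    def test_invariant_to_anchor_and_leaf_order(self):
        t1 = parse_newick("(((a:0.1,b:0.2):0.3,c:0.4):0.2,(d:0.1,e:0.5):0.3);")
        t2 = parse_newick("((e:0.5,d:0.1):0.3,(c:0.4,(b:0.2,a:0.1):0.3):0.2);")
        col = {"a": 0, "b": 1, "c": "?", "d": 1, "e": 0}
        assert site_log_likelihood(t1, col, rate=0.7) == pytest.approx(
            site_log_likelihood(t2, col, rate=0.7), abs=1e-12
        )


class TestGammaRates:
    def test_mean_one_and_sorted(self):
        for alpha in (0.05, 0.5, 1.0, 7.0):
            g = GammaRates(alpha, 4)
            assert g.rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(g.rates) >= 0).all()

    def test_k1_is_equal_rates(self):
        g = GammaRates(0.37, 1)
        assert g.rates.tolist() == [1.0]

    def test_large_alpha_degenerates_to_equal_rates(self, rng):
        tree = random_lengths(random_binary_tree(list("abcdef"), rng), rng)
        matrix = encode_baum_ragan(SourceProfile([random_binary_tree(list("abcdef"), rng)]))
        ll_gamma = tree_log_likelihood(tree, matrix, GammaRates(1e6, 4))
        ll_equal = tree_log_likelihood(tree, matrix, GammaRates.equal())
        assert ll_gamma == pytest.approx(ll_equal, abs=1e-6)


class TestTreeLogLikelihood:
    def test_all_missing_column_contributes_zero(self):
        tree = with_branch_lengths(parse_newick("((a,b),(c,d));"))
        m = CharacterMatrix(
            taxa=list("abcd"),
            data=np.array([[0, 2], [0, 2], [1, 2], [1, 2]], dtype=np.uint8),
        )
        m_first = CharacterMatrix(
            taxa=list("abcd"), data=np.array([[0], [0], [1], [1]], dtype=np.uint8)
        )
        g = GammaRates(0.8, 4)
        assert tree_log_likelihood(tree, m, g) == pytest.approx(
            tree_log_likelihood(tree, m_first, g), abs=1e-12
        )

    def test_mixture_is_mean_of_category_likelihoods(self):
        rng = random.Random(5)
        tree = random_lengths(random_binary_tree(list("abcde"), rng), rng)
        col = {"a": 0, "b": 1, "c": 1, "d": 0, "e": "?"}
        g = GammaRates(0.6, 4)
        per_cat = [math.exp(site_log_likelihood(tree, col, rate=r)) for r in g.rates]
        m = CharacterMatrix(
            taxa=sorted("abcde"),
            data=np.array([[0], [1], [1], [0], [2]], dtype=np.uint8),
        )
        assert tree_log_likelihood(tree, m, g) == pytest.approx(
            math.log(sum(per_cat) / 4), abs=1e-10
        )


class TestOptimizeBranchLengths:
    def test_two_taxon_cfn_distance(self):
        # m sites, d differences: t_hat solves (1 - e^(-2t))/2 = d/m
        m_sites, d = 20, 3
        data = np.zeros((2, m_sites), dtype=np.uint8)
        data[1, :d] = 1
        matrix = CharacterMatrix(taxa=["a", "b"], data=data)
        tree, _ll = optimize_branch_lengths(
            parse_newick("(a:0.1,b:0.1);"), matrix, GammaRates.equal()
        )
        total = sum(n.length for n in tree.preorder() if n.parent is not None)
        expected = -0.5 * math.log(1 - 2 * d / m_sites)
        assert total == pytest.approx(expected, rel=1e-4)

    def test_identical_sequences_hit_lower_bound(self):
        data = np.zeros((2, 10), dtype=np.uint8)
        matrix = CharacterMatrix(taxa=["a", "b"], data=data)
        tree, _ = optimize_branch_lengths(
            parse_newick("(a:0.5,b:0.5);"), matrix, GammaRates.equal()
        )
        total = sum(n.length for n in tree.preorder() if n.parent is not None)
        assert total <= 1e-6

    def test_likelihood_never_decreases(self, rng):
        model = random_lengths(random_binary_tree(list("abcdefgh"), rng), rng)
        matrix = simulate_characters(model, 60, 99)
        start = with_branch_lengths(model, default=0.1)
        ll0 = tree_log_likelihood(start, matrix, GammaRates(0.9, 4))
        _tree, ll1 = optimize_branch_lengths(start, matrix, GammaRates(0.9, 4))
        assert ll1 >= ll0 - 1e-9


class TestOptimizeAlpha:
    def test_improves_on_alpha_one(self, rng):
        model = random_lengths(random_binary_tree([f"t{i}" for i in range(10)], rng), rng)
        rates = np.random.default_rng(3).gamma(0.4, 1 / 0.4, size=300)
        matrix = simulate_characters(model, 300, 17, site_rates=rates)
        gamma, ll, _ = optimize_alpha(model, matrix, k=4)
        assert ll >= tree_log_likelihood(model, matrix, GammaRates(1.0, 4)) - 1e-9

    def test_recovers_simulated_shape_within_factor_two(self, rng):
        model = random_lengths(random_binary_tree([f"t{i}" for i in range(16)], rng), rng)
        true_alpha = 0.5
        rates = np.random.default_rng(41).gamma(true_alpha, 1 / true_alpha, size=2000)
        matrix = simulate_characters(model, 2000, 42, site_rates=rates)
        work, _ll = optimize_branch_lengths(model, matrix, GammaRates(true_alpha, 4))
        gamma, _, at_bound = optimize_alpha(work, matrix, k=4)
        assert not at_bound
        assert true_alpha / 2 <= gamma.alpha <= true_alpha * 2

    def test_flat_data_flags_bound(self):
        tree = with_branch_lengths(parse_newick("((a,b),(c,d));"))
        matrix = CharacterMatrix(
            taxa=list("abcd"), data=np.zeros((4, 5), dtype=np.uint8)
        )
        _gamma, _ll, at_bound = optimize_alpha(tree, matrix, k=4)
        assert at_bound


class TestMLSearch:
    def test_four_taxon_matches_exhaustive(self, rng):
        quartets = [
            parse_newick(s)
            for s in ("((a,b),(c,d));", "((a,c),(b,d));", "((a,d),(b,c));")
        ]
        data = np.array(
            [[0, 0, 1, 0], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 1]], dtype=np.uint8
        )
        matrix = CharacterMatrix(taxa=list("abcd"), data=data)
        tree, report = ml_search(matrix, MLSearchConfig(seed=0))
        best = max(mrl_score(q, matrix) for q in quartets)
        assert report.log_likelihood == pytest.approx(best, abs=0.05)

    def test_recovers_compatible_profile(self, rng):
        model = random_binary_tree([f"t{i}" for i in range(8)], rng)
        matrix = encode_baum_ragan(SourceProfile([model]))
        tree, _report = ml_search(matrix, MLSearchConfig(seed=1))
        assert tree.topology_key() == model.topology_key()

    def test_same_seed_same_output(self, rng):
        model = random_binary_tree([f"t{i}" for i in range(7)], rng)
        matrix = encode_baum_ragan(
            SourceProfile([model, random_binary_tree([f"t{i}" for i in range(7)], rng)])
        )
        t1, r1 = ml_search(matrix, MLSearchConfig(seed=9))
        t2, r2 = ml_search(matrix, MLSearchConfig(seed=9))
        assert t1.newick() == t2.newick()
        assert r1.log_likelihood == r2.log_likelihood


class TestMRLScore:
    def test_local_optimality_against_nni_neighbors(self, rng):
        from supertree.parsimony import _nni_neighbors

        model = random_binary_tree([f"t{i}" for i in range(7)], rng)
        matrix = encode_baum_ragan(SourceProfile([model]))
        tree, report = ml_search(matrix, MLSearchConfig(seed=2))
        best = report.log_likelihood
        for neighbor in _nni_neighbors(tree):
            assert mrl_score(neighbor, matrix) <= best + 0.05

    def test_degrades_as_conflicting_columns_added(self, rng):
        model = random_binary_tree(list("abcdefg"), rng)
        matrix = encode_baum_ragan(SourceProfile([model]))
        base = mrl_score(model, matrix)
        # append columns conflicting with the model topology
        conflict = np.array(
            [[0], [1], [0], [1], [0], [1], [0]], dtype=np.uint8
        )
        worse = matrix
        prev = base
        for _ in range(2):
            worse = CharacterMatrix(
                taxa=worse.taxa, data=np.hstack([worse.data, conflict])
            )
            cur = mrl_score(model, worse)
            assert cur < prev
            prev = cur

    def test_polytomies_scored_and_flagged(self, rng):
        model = random_binary_tree(list("abcdef"), rng)
        matrix = encode_baum_ragan(SourceProfile([model]))
        star = parse_newick("(a,b,c,d,e,f);")
        ll, report = mrl_score(star, matrix, return_report=True)
        assert ll < mrl_score(model, matrix)
        assert "scored with polytomies" in report.notes


def test_ml_and_mp_agree_on_no_homoplasy_profiles(rng):
    # with compatible sources both criteria identify the generating tree
    for seed in range(3):
        model = random_binary_tree([f"t{i}" for i in range(7)], random.Random(seed))
        matrix = encode_baum_ragan(SourceProfile([model]))
        from supertree.parsimony import MPSearchConfig, mp_search

        mp_trees, mp_rep = mp_search(matrix, MPSearchConfig(seed=seed))
        ml_tree, _ = ml_search(matrix, MLSearchConfig(seed=seed))
        assert mp_rep.mp_score == matrix.ncol
        assert ml_tree.topology_key() == model.topology_key()
        assert model.topology_key() in {t.topology_key() for t in mp_trees}
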