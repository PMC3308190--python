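"""Topological error rates, Sum-FN, p-ECR neighborhoods, score correlations.

FN (missing branch) rate: percent of the reference tree's internal edges
absent from the estimate. FP rate: percent of the estimate's internal edges
absent from the reference. When both trees are binary the two are equal;
when the reference is binary FP <= FN, since the estimate can only resolve
as many edges as a binary tree has. Sum-FN totals, over the source trees,
the internal edges missing from the supertree's restriction to each source
tree's taxa; with binary trees everywhere it is proportional to the summed
Robinson-Foulds distance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .trees import Tree, bipartitions, random_refinement, restrict

__all__ = [
    "ErrorReport",
    "fn_rate",
    "fp_rate",
    "rf_distance",
    "error_report",
    "sum_fn",
    "p_ecr",
    "spearman",
    "correlation_experiment",
]


@dataclass
class ErrorReport:
    """FN/FP percentages plus the raw counts behind them."""

    fn: float
    fp: float
    rf: int
    n_internal_true: int
    n_internal_estimated: int

    def to_dict(self):
        return {
            "fn": self.fn,
            "fp": self.fp,
            "rf": self.rf,
            "n_internal_true": self.n_internal_true,
            "n_internal_estimated": self.n_internal_estimated,
        }


def _paired_splits(true_tree: Tree, estimated: Tree):
    taxa = true_tree.leaf_labels
    if estimated.leaf_labels != taxa:
        raise ValueError("trees must share an identical leaf set")
    return (
        {b.side for b in bipartitions(true_tree, taxa)},
        {b.side for b in bipartitions(estimated, taxa)},
    )


def fn_rate(true_tree: Tree, estimated: Tree) -> float:
    """Percent of the reference's internal edges missing from the estimate."""
    bt, be = _paired_splits(true_tree, estimated)
    if not bt:
        return 0.0
    return 100.0 * len(bt - be) / len(bt)


def fp_rate(true_tree: Tree, estimated: Tree) -> float:
    """Percent of the estimate's internal edges absent from the reference."""
    bt, be = _paired_splits(true_tree, estimated)
    if not be:
        return 0.0
    return 100.0 * len(be - bt) / len(be)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: size of the bipartition symmetric difference."""
    b1, b2 = _paired_splits(t1, t2)
    return len(b1 ^ b2)


def error_report(true_tree: Tree, estimated: Tree) -> ErrorReport:
    bt, be = _paired_splits(true_tree, estimated)
    return ErrorReport(
        fn=100.0 * len(bt - be) / len(bt) if bt else 0.0,
        fp=100.0 * len(be - bt) / len(be) if be else 0.0,
        rf=len(bt ^ be),
        n_internal_true=len(bt),
        n_internal_estimated=len(be),
    )


def sum_fn(profile, supertree: Tree) -> float:
    """Percent of source-tree internal edges missing from the supertree.

    Each source tree is compared against the supertree restricted to that
    tree's taxa; the percentages pool the edge counts across sources.
    """
    super_taxa = supertree.leaf_labels
    missing = total = 0
    for i, tree in enumerate(profile):
        taxa = tree.leaf_labels
        if not taxa <= super_taxa:
            absent = sorted(taxa - super_taxa)
            raise ValueError(f"source tree {i} taxa missing from supertree: {absent}")
        bt = {b.side for b in bipartitions(tree, taxa)}
        if not bt:
            continue
        bs = {b.side for b in bipartitions(restrict(supertree, taxa), taxa)}
        missing += len(bt - bs)
        total += len(bt)
    return 100.0 * missing / total if total else 0.0


def p_ecr(tree: Tree, p: int, seed) -> Tree:
    """A p-edge-contract-and-refine move: contract p internal edges chosen
    uniformly without replacement, then randomly refine the result."""
    rng = random.Random(seed) if not isinstance(seed, random.Random) else seed
    if p < 0:
        raise ValueError("p must be non-negative")
    taxa = tree.leaf_labels
    sides = sorted(
        ({b.side for b in bipartitions(tree, taxa)}), key=lambda s: tuple(sorted(s))
    )
    if p > len(sides):
        raise ValueError(f"cannot contract {p} of {len(sides)} internal edges")
    if p == 0 and tree.is_binary():
        return tree.copy()
    keep = set(sides) - set(rng.sample(sides, p))
    from .trees import tree_from_clusters

    contracted = tree_from_clusters(taxa, keep)
    return random_refinement(contracted, rng)


def spearman(xs, ys) -> float:
    """Spearman's rank correlation (average ranks for ties)."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if len(xs) != len(ys) or len(xs) < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    rho = _stats.spearmanr(xs, ys).statistic
    return float(rho)


def correlation_experiment(profile, true_tree: Tree, supertrees, n_per_tree: int = 100,
                           p_max_fraction: float = 0.25, seed: int = 0,
                           categories: int = 4, keep_polytomies: bool = False):
    """Score p-ECR neighborhoods of estimated supertrees against tree error.

    For each input supertree, ``n_per_tree`` p-ECR neighbors are generated
    with p uniform on [0, ceil(p_max_fraction * internal edges)]; the
    originals and all neighbors are scored with the MP score, the MRL score,
    and Sum-FN, and each score's Spearman correlation with the FN rate is
    returned as ``(table, rho_by_score)``.

    Non-binary input supertrees are randomly refined first (seeded) so that
    error rates and scores are comparable across trees; pass
    ``keep_polytomies=True`` to score them as they are.
    """
    from .encoding import encode_baum_ragan
    from .likelihood import mrl_score
    from .parsimony import mp_score

    matrix = encode_baum_ragan(profile)
    taxa = true_tree.leaf_labels
    rng = random.Random(seed)
    pool = []
    for si, tree in enumerate(supertrees):
        if tree.leaf_labels != taxa:
            raise ValueError("supertrees must live on the reference taxon set")
        base = tree if keep_polytomies or tree.is_binary() else random_refinement(tree, rng)
        pool.append((si, -1, base))
        n_internal = len(bipartitions(base, taxa))
        p_max = int(np.ceil(p_max_fraction * n_internal))
        for j in range(n_per_tree):
            p = rng.randint(0, p_max)
            pool.append((si, j, p_ecr(base, p, rng)))
    rows = []
    for si, j, tree in pool:
        rows.append(
            {
                "supertree": si,
                "neighbor": j,
                "fn": fn_rate(true_tree, tree),
                "mp_score": mp_score(tree, matrix),
                "mrl_score": mrl_score(tree, matrix, categories=categories),
                "sum_fn": sum_fn(profile, tree),
            }
        )
    table = pd.DataFrame(rows)
    rho = {
        # parsimony score and Sum-FN grow with error; MRL degrades (more
        # negative), so correlate its negation to keep signs comparable
        "mp_score": spearman(table["mp_score"], table["fn"]),
        "mrl_score": spearman(-table["mrl_score"], table["fn"]),
        "sum_fn": spearman(table["sum_fn"], table["fn"]),
    }
    return table, rho
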