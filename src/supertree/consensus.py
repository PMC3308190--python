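"""Greedy (extended majority-rule) consensus of equally good trees."""

from __future__ import annotations

from collections import Counter

from .trees import ClusterTreeBuilder, Tree, bipartitions

__all__ = ["greedy_consensus", "majority_consensus"]


def _ranked_clusters(trees, taxa):
    counts = Counter()
    for tree in trees:
        for b in bipartitions(tree, taxa):
            counts[b.side] += 1
    # frequency-descending; ties broken by the canonical side, lexicographically
    return sorted(counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))


def greedy_consensus(trees) -> Tree:
    """Admit bipartitions in decreasing frequency while they stay compatible.

    The result refines the majority-rule consensus: every bipartition in more
    than half of the inputs is present (majority bipartitions are mutually
    compatible), plus any lower-frequency ones that do not conflict with what
    was already admitted. Frequency ties are broken by the lexicographic
    order of the canonical side, making the output deterministic.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("consensus of an empty collection")
    taxa = trees[0].leaf_labels
    for tree in trees[1:]:
        if tree.leaf_labels != taxa:
            raise ValueError("consensus requires identical leaf sets")
    builder = ClusterTreeBuilder(taxa)
    for side, _count in _ranked_clusters(trees, taxa):
        builder.try_insert(side)
    return builder.tree()


def majority_consensus(trees) -> Tree:
    """Strict >50% majority-rule consensus (reference implementation)."""
    trees = list(trees)
    taxa = trees[0].leaf_labels
    builder = ClusterTreeBuilder(taxa)
    for side, count in _ranked_clusters(trees, taxa):
        if count * 2 > len(trees):
            builder.try_insert(side)
    return builder.tree()
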