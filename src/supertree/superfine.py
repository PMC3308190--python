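"""SuperFine: refine each polytomy of the SCM tree with a base supertree method.

Removing a polytomy node v of degree d splits the taxa into d components;
every taxon is labeled by its component, each source tree is rewritten onto
those labels (collapsing same-label sibling leaves until every label occurs
at most once), and the base method (MRP or MRL) run on the rewritten trees
yields a resolution of v, which is grafted back. Each polytomy's refinement
depends only on the taxon partition it defines and on the source trees, so
polytomies are independent and the processing order cannot change the
output; per-polytomy RNG streams are derived from the global seed and a
digest of the partition to keep this true even with stochastic searches.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

from .consensus import greedy_consensus
from .encoding import encode_baum_ragan
from .likelihood import MLSearchConfig, ml_search
from .parsimony import MPSearchConfig, _reanchor, mp_score, mp_search
from .report import ScoreReport
from .scm import resolution, scm_tree
from .trees import SourceProfile, Tree

__all__ = [
    "PolytomyContext",
    "polytomies",
    "label_taxa",
    "reduce_source_tree",
    "refine_polytomy",
    "superfine",
]


@dataclass
class PolytomyContext:
    """Everything one polytomy's refinement depends on.

    ``assignment`` maps every taxon to its component index (1..degree);
    ``reduced`` holds the label-rewritten source trees (None entries for
    sources that carried no information about this polytomy).
    """

    degree: int
    assignment: dict
    reduced: list

    @classmethod
    def build(cls, tree, v, profile) -> "PolytomyContext":
        assignment = label_taxa(tree, v)
        return cls(
            degree=len(set(assignment.values())),
            assignment=assignment,
            reduced=[reduce_source_tree(t, assignment) for t in profile],
        )


def polytomies(tree: Tree) -> list:
    """Internal nodes of unrooted degree >= 4, in deterministic preorder."""
    out = []
    for node in tree.preorder():
        if node.is_leaf:
            continue
        degree = len(node.children) + (node.parent is not None)
        if degree >= 4:
            out.append(node)
    return out


def label_taxa(tree: Tree, v) -> dict:
    """Map every taxon to the index (1..d) of its component of ``tree`` - v."""
    degree = len(v.children) + (v.parent is not None)
    if v.is_leaf or degree < 4:
        raise ValueError("labeling requires an unresolved (degree >= 4) internal node")
    below = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    components = [below[id(child)] for child in v.children]
    if v.parent is not None:
        components.append(below[id(tree.root)] - below[id(v)])
    # canonical numbering (by smallest member) so labels do not depend on
    # the traversal anchor; order invariance of the refinement relies on it
    components.sort(key=min)
    assignment = {}
    for i, comp in enumerate(components, start=1):
        for taxon in comp:
            assignment[taxon] = i
    return assignment


def _blocks(assignment: dict) -> dict:
    blocks: dict = {}
    for taxon, lab in assignment.items():
        blocks.setdefault(lab, set()).add(taxon)
    return {lab: frozenset(taxa) for lab, taxa in blocks.items()}


def _label_name(lab: int) -> str:
    return f"B{lab:04d}"


def reduce_source_tree(tree: Tree, assignment: dict):
    """Rewrite a source tree onto component labels; None when uninformative.

    Leaves are relabeled by their component; same-label sibling leaves are
    collapsed (suppressing the degree-2 nodes this creates) until each label
    occurs at most once. Trees retaining fewer than 4 distinct labels carry
    no topology for the refinement and are dropped.
    """
    missing = tree.leaf_labels - set(assignment)
    if missing:
        raise ValueError(f"taxa without a component label: {sorted(missing)}")
    if len({assignment[l] for l in tree.leaf_labels}) < 2:
        return None
    work = tree.copy()
    for leaf in work.leaves():
        leaf.label = _label_name(assignment[leaf.label])
        leaf.length = None
    changed = True
    while changed:
        changed = False
        for node in list(work.preorder()):
            if node.is_leaf:
                continue
            seen: dict = {}
            for child in list(node.children):
                if child.is_leaf:
                    if child.label in seen:
                        child.detach()
                        changed = True
                    else:
                        seen[child.label] = child
        if changed:
            work.normalize()
    # guaranteed at most one leaf per label for SCM-derived partitions; be
    # defensive against pathological hand-built inputs
    labels = [l.label for l in work.leaves()]
    if len(labels) != len(set(labels)):
        warnings.warn("duplicate labels survived reduction; pruning extras")
        seen = set()
        for leaf in list(work.leaves()):
            if leaf.label in seen:
                leaf.detach()
            else:
                seen.add(leaf.label)
        work.normalize()
    if work.n_leaves < 4:
        return None
    return work


def _polytomy_seed(global_seed: int, blocks: dict) -> int:
    digest = hashlib.sha256()
    digest.update(str(int(global_seed)).encode())
    for block in sorted(map(sorted, blocks.values())):
        digest.update(("|".join(block) + ";").encode())
    return int.from_bytes(digest.digest()[:4], "big") % (2**31)


def refine_polytomy(reduced_profile, base: str = "mrp", config=None, seed: int = 0):
    """Supertree on the component labels from the rewritten source trees.

    Returns a tree on (a subset of) the labels, or None when the reduced
    profile is empty. With MRP, equally-best trees are combined by greedy
    consensus (which may leave the refinement partially unresolved).
    """
    trees = [t for t in reduced_profile if t is not None]
    if not trees:
        return None
    profile = SourceProfile(trees)
    matrix = encode_baum_ragan(profile)
    if matrix.ntax < 4 or matrix.ncol == 0:
        return None
    if base in ("mp", "mrp"):
        cfg = config or MPSearchConfig(n_starts=2)
        cfg = replace(cfg, seed=seed)
        best, _report = mp_search(matrix, cfg)
        return greedy_consensus(best)
    if base in ("ml", "mrl"):
        cfg = config or MLSearchConfig()
        cfg = replace(cfg, seed=seed)
        tree, _report = ml_search(matrix, cfg)
        return tree
    raise ValueError(f"unknown base method: {base}")


def _graft(work: Tree, v, labels: dict, res: Tree | None) -> None:
    """Replace polytomy v by the resolution tree ``res`` on its labels."""
    if res is None:
        return
    _reanchor(work, v)

    def _leaf_of(node):
        while node.children:
            node = node.children[0]
        return node.label

    components = {_label_name(labels[_leaf_of(c)]): c for c in v.children}
    placed = res.leaf_labels
    v.children = []

    def transform(rnode):
        if rnode.is_leaf:
            comp = components[rnode.label]
            comp.parent = None
            return comp
        from .trees import Node

        fresh = Node()
        for child in rnode.children:
            fresh.add(transform(child))
        return fresh

    for rchild in res.root.children:
        v.add(transform(rchild))
    # components whose label no source tree retained stay on the polytomy
    for name, comp in components.items():
        if name not in placed:
            comp.parent = None
            v.add(comp)


def superfine(profile, base: str = "mrp", config=None, seed: int = 0,
              polytomy_order=None):
    """SCM followed by independent refinement of every polytomy.

    ``polytomy_order`` (a permutation of polytomy indices) exists to exercise
    the order-invariance property; the output does not depend on it.
    Returns (tree, ScoreReport).
    """
    scm, _steps = scm_tree(profile)
    work = scm.copy()
    nodes = polytomies(work)
    order = list(range(len(nodes))) if polytomy_order is None else list(polytomy_order)
    for idx in order:
        v = nodes[idx]
        degree = len(v.children) + (v.parent is not None)
        if degree < 4:
            continue
        ctx = PolytomyContext.build(work, v, profile)
        res = refine_polytomy(
            ctx.reduced, base=base, config=config,
            seed=_polytomy_seed(seed, _blocks(ctx.assignment)),
        )
        _graft(work, v, ctx.assignment, res)
    work.normalize()
    matrix = encode_baum_ragan(profile)
    report = ScoreReport(
        mp_score=mp_score(work, matrix),
        ncol=matrix.ncol,
        ntax=work.n_leaves,
        resolution=resolution(work),
    )
    return work, report
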