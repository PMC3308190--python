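"""Strict Consensus Merger: pairwise merging of source trees into one tree.

A pairwise merge restricts both trees to their shared taxa X, takes the
strict consensus of the two restrictions as a backbone, and re-attaches each
maximal subtree of tree-exclusive taxa at the backbone position of its
attachment point. Edges on which the two restrictions disagree are
contracted by the strict consensus; a backbone edge that receives exclusive
subtrees from *both* trees is a "collision" and is contracted as well, all
colliding subtrees joining the resulting polytomy (on a pendant edge, which
cannot be contracted, they join a single new attachment node instead).
Attachments that map to the same backbone *node* are not collisions.

Trees are merged two at a time, always picking the pair of current trees
with the largest shared-taxon count; the final tree contains all the taxa
but is in general only partially resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trees import Node, SourceProfile, Tree, bipartitions, restrict, strict_consensus

__all__ = ["MergeStep", "pairwise_scm", "merge_order", "scm_tree", "resolution"]


@dataclass
class MergeStep:
    """Bookkeeping for one pairwise merge."""

    left: int
    right: int
    n_shared: int
    collisions: int
    disagreement_contractions: int


def resolution(tree: Tree) -> float:
    """Fraction of the n-3 possible internal edges present in the tree."""
    n = tree.n_leaves
    if n < 4:
        return 1.0
    return len(bipartitions(tree)) / (n - 3)


# ---------------------------------------------------------------------- #
# attachment extraction
# ---------------------------------------------------------------------- #
def _root_at_leaf(tree: Tree, label: str) -> Node:
    """A copy of the tree re-rooted so the leaf ``label`` is the root."""
    work = tree.copy()
    leaf = next(n for n in work.preorder() if n.is_leaf and n.label == label)
    path = []
    cur = leaf
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    for child, parent in zip(reversed(path[:-1]), reversed(path[1:])):
        parent.children.remove(child)
        child.add(parent)
    leaf.parent = None
    return leaf


def _strip_lengths(node: Node) -> Node:
    stack = [node]
    while stack:
        cur = stack.pop()
        cur.length = None
        stack.extend(cur.children)
    return node


class _Attachments:
    """Where one tree's exclusive subtrees sit relative to its restriction.

    ``node_targets``: list of (surviving-node key, [subtree roots]) —
    attachment at a node of restrict(t, X) of unrooted degree >= 3.
    ``edge_targets``: dict edge-side -> ordered chain [[subtrees at first
    position], ...] top (toward the reference leaf) to bottom, for
    attachment points suppressed into a restricted-tree edge.

    Surviving-node keys are ("side", below-set) for the node's parent edge,
    letting the merger climb contracted edges to the backbone image.
    """

    def __init__(self, tree: Tree, shared: frozenset, ref: str):
        self.shared = shared
        self.ref = ref
        self.node_targets: list = []
        self.edge_targets: dict = {}
        root = _root_at_leaf(tree, ref)
        # shared-leaf counts
        count: dict = {}
        order = []
        stack = [root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(n.children)
        for n in reversed(order):
            if n.is_leaf:
                count[id(n)] = 1 if n.label in shared else 0
            else:
                count[id(n)] = sum(count[id(c)] for c in n.children)
        self._count = count
        top = root.children[0]
        self._walk(top, parent_surviving_side=None, chain=None)

    def _walk(self, node, parent_surviving_side, chain):
        """Traverse kept nodes; ``chain`` is the open suppressed-chain list
        (or None when the node hangs directly under a surviving node)."""
        count = self._count
        if node.is_leaf:
            # bottom of any open chain is this pendant edge
            if chain:
                self._close_chain(frozenset([node.label]), chain)
            return frozenset([node.label])
        kept = [c for c in node.children if count[id(c)] > 0]
        excl = [c for c in node.children if count[id(c)] == 0]
        subtrees = [_strip_lengths(c.detach()) for c in list(excl)]
        degree = len(kept) + 1  # + parent edge (the tree hangs below ref)
        if degree >= 3:
            below = frozenset()
            for c in kept:
                below |= self._walk(c, None, None)
            if chain:
                chain.append(("*surviving*", []))  # close below at this node
                self._close_chain(below, chain)
            if subtrees:
                self.node_targets.append((("side", below), subtrees))
            return below
        # degree 2: suppressed into a chain
        link = chain if chain is not None else []
        if subtrees:
            link.append((id(node), subtrees))
        below = self._walk(kept[0], None, link)
        return below

    def _close_chain(self, below, chain):
        groups = [grp for key, grp in chain if grp]
        if groups:
            existing = self.edge_targets.setdefault(frozenset(below), [])
            existing.extend(groups)
        chain.clear()


# ---------------------------------------------------------------------- #
# pairwise merge
# ---------------------------------------------------------------------- #
def pairwise_scm(t1: Tree, t2: Tree, indices=(0, 1)):
    """Merge two trees; returns (merged tree, MergeStep)."""
    x1, x2 = t1.leaf_labels, t2.leaf_labels
    shared = x1 & x2
    if len(shared) < 2:
        raise ValueError(
            f"trees share only {len(shared)} taxa; at least 2 are required to merge"
        )
    ref = min(shared)
    r1, r2 = restrict(t1, shared), restrict(t2, shared)
    b1 = {b.side for b in bipartitions(r1, shared)}
    b2 = {b.side for b in bipartitions(r2, shared)}
    backbone = strict_consensus([r1, r2])
    backbone_sides = b1 & b2
    att1 = _Attachments(t1.copy(), shared, ref)
    att2 = _Attachments(t2.copy(), shared, ref)

    # working copy of the backbone, rooted at the reference leaf
    root = _root_at_leaf(backbone, ref)
    _strip_lengths(root)
    below: dict = {}
    order = []
    stack = [root]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(n.children)
    node_by_side = {}
    leaf_by_label = {}
    for n in reversed(order):
        if n.is_leaf:
            below[id(n)] = frozenset([n.label])
            leaf_by_label[n.label] = n
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
        node_by_side[below[id(n)]] = n

    n_shared = len(shared)

    def pendant_of(side):
        if len(side) == 1:
            return next(iter(side))
        if len(shared - side) == 1:
            return next(iter(shared - side))
        return None

    def image_node(side):
        """Backbone node a restricted-tree node with parent-edge ``side``
        maps to, climbing edges contracted by the strict consensus."""
        node = None
        cur = side
        while True:
            leaf = pendant_of(cur)
            if leaf is not None:
                node = leaf_by_label[leaf] if len(cur) == 1 else root.children[0]
                break
            if cur in backbone_sides:
                node = node_by_side[cur]
                break
            # contracted: climb toward ref by locating the enclosing node in
            # whichever restricted tree the side came from; the enclosing
            # backbone region is found by walking up the backbone itself:
            # take the smallest backbone cluster strictly containing cur
            candidates = [s for s in node_by_side if s > cur]
            cur = min(candidates, key=len)
        if node.label is not None and node.parent is not None:
            node = node.parent  # a pendant image attaches at the leaf's junction
        return resolve(node)

    # sort edge targets: those from both trees on a shared internal edge are
    # collisions and contract that edge
    merged_targets: dict = {}
    for ti, att in ((0, att1), (1, att2)):
        for side, chain in att.edge_targets.items():
            merged_targets.setdefault(side, {})[ti] = chain

    collisions = 0
    redirect: dict = {}

    def resolve(node):
        while id(node) in redirect:
            node = redirect[id(node)]
        return node

    # 1) contractions for internal-edge collisions
    for side, per_tree in sorted(merged_targets.items(), key=lambda kv: tuple(sorted(kv[0]))):
        if len(per_tree) < 2 or pendant_of(side) is not None:
            continue
        if side not in backbone_sides:
            continue  # already a node target via climbing
        node = resolve(node_by_side[side])
        parent = resolve(node.parent)
        collisions += 1
        node.detach()
        for child in list(node.children):
            child.detach()
            parent.add(child)
        redirect[id(node)] = parent
        for chain in per_tree.values():
            for group in chain:
                for sub in group:
                    parent.add(sub)

    # 2) remaining edge targets: subdivide (single tree) or pool at one new
    #    node (pendant-edge conflicts and contracted-edge targets)
    for side, per_tree in sorted(merged_targets.items(), key=lambda kv: tuple(sorted(kv[0]))):
        pend = pendant_of(side)
        if pend is not None:
            bottom = leaf_by_label[pend] if len(side) == 1 else root.children[0]
        elif side in backbone_sides:
            bottom = node_by_side[side]
        else:
            # the edge itself was contracted by the strict consensus: all its
            # attachments join the image node
            target = resolve(image_node(side))
            if len(per_tree) >= 2:
                collisions += 1
            for chain in per_tree.values():
                for group in chain:
                    for sub in group:
                        target.add(sub)
            continue
        if len(per_tree) >= 2 and pendant_of(side) is None:
            continue  # handled as a collision above
        bottom = resolve(bottom)
        parent = bottom.parent
        idx = parent.children.index(bottom)
        if len(per_tree) >= 2:
            # both trees on a pendant edge: order is unknowable, so every
            # subtree joins a single new attachment node (polytomy)
            collisions += 1
            mid = Node()
            parent.children[idx] = mid
            mid.parent = parent
            bottom.parent = mid
            mid.children.append(bottom)
            for chain in per_tree.values():
                for group in chain:
                    for sub in group:
                        mid.add(sub)
        else:
            # one tree: rebuild its suppressed path, preserving the original
            # top-to-bottom attachment order along the edge
            (chain,) = per_tree.values()
            prev = parent
            for gi, group in enumerate(chain):
                mid = Node()
                if prev is parent:
                    parent.children[idx] = mid
                    mid.parent = parent
                else:
                    prev.add(mid)
                for sub in group:
                    mid.add(sub)
                prev = mid
            bottom.parent = prev
            prev.children.append(bottom)

    # 3) node targets
    for att in (att1, att2):
        for (kind, side), subtrees in att.node_targets:
            target = resolve(image_node(side))
            for sub in subtrees:
                target.add(sub)

    # unroot: the working tree is rooted at the reference leaf
    top = root.children[0]
    root.children = []
    top.parent = None
    top.add(Node(ref))
    merged = Tree(top).normalize()
    step = MergeStep(
        left=indices[0],
        right=indices[1],
        n_shared=n_shared,
        collisions=collisions,
        disagreement_contractions=len(b1 ^ b2),
    )
    return merged, step


# ---------------------------------------------------------------------- #
# merge ordering and the full SCM tree
# ---------------------------------------------------------------------- #
def merge_order(profile) -> list:
    """Greedy pairing plan: repeatedly merge the pair of current trees with
    the largest shared-taxon count (ties: larger resulting union, then lowest
    original indices). Raises if some tree can never reach a 2-taxon overlap.
    """
    leafsets = {i: t.leaf_labels for i, t in enumerate(profile)}
    if len(leafsets) == 0:
        raise ValueError("empty profile")
    plan = []
    while len(leafsets) > 1:
        best = None
        for i in sorted(leafsets):
            for j in sorted(leafsets):
                if j <= i:
                    continue
                overlap = len(leafsets[i] & leafsets[j])
                union = len(leafsets[i] | leafsets[j])
                key = (-overlap, -union, i, j)
                if best is None or key < best[0]:
                    best = (key, i, j, overlap)
        _, i, j, overlap = best
        if overlap < 2:
            isolated = sorted(leafsets)
            raise ValueError(
                f"profile is disconnected under 2-taxon overlaps; "
                f"remaining components rooted at trees {isolated}"
            )
        plan.append((i, j, overlap))
        leafsets[min(i, j)] = leafsets[i] | leafsets[j]
        del leafsets[max(i, j)]
    return plan


def scm_tree(profile):
    """Merge a whole profile; returns (SCM tree, [MergeStep...]).

    The output's leaf set is the union S of all source-tree taxa; its
    resolution (fraction of n-3 possible internal edges realized) is
    available via :func:`resolution`.
    """
    if len(profile) == 1:
        return profile[0].copy(), []
    plan = merge_order(profile)
    current = {i: t for i, t in enumerate(profile)}
    steps = []
    for i, j, _overlap in plan:
        merged, step = pairwise_scm(current[i], current[j], indices=(i, j))
        steps.append(step)
        current[min(i, j)] = merged
        del current[max(i, j)]
    (tree,) = current.values()
    return tree, steps
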