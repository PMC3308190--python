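"""Unrooted leaf-labeled trees: newick I/O, bipartitions, restriction, consensus.

Trees are stored with an arbitrary internal "anchor" node used only for
traversal; every semantic operation (bipartitions, consensus, error rates) is
defined on the unrooted topology, so the anchor never leaks into results.
Internal degree-2 nodes are always suppressed, so each internal node has
unrooted degree >= 3 (except for trees with fewer than 3 leaves).
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "Node",
    "Tree",
    "Bipartition",
    "SourceProfile",
    "NewickError",
    "parse_newick",
    "bipartitions",
    "restrict",
    "strict_consensus",
    "random_refinement",
    "tree_from_clusters",
    "ClusterTreeBuilder",
]


class NewickError(ValueError):
    """Raised for malformed newick input or invalid leaf labelings."""


class Node:
    """A tree node; leaves carry a label, edges carry an optional length.

    ``length`` is the length of the edge to the parent (``None`` when absent).
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} deg={len(self.children) + (self.parent is not None)}>"


class Tree:
    """An unrooted, possibly multifurcating tree anchored at an internal node."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ #
    # traversal
    # ------------------------------------------------------------------ #
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def internal_nodes(self):
        return [n for n in self.preorder() if not n.is_leaf]

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #
    def copy(self) -> "Tree":
        mapping = {}
        new_root = Node(self.root.label, self.root.length)
        mapping[id(self.root)] = new_root
        for node in self.preorder():
            if node is self.root:
                continue
            clone = Node(node.label, node.length)
            mapping[id(node.parent)].add(clone)
            mapping[id(node)] = clone
        return Tree(new_root)

    def is_binary(self) -> bool:
        """True iff the unrooted topology is fully resolved."""
        if self.n_leaves < 4:
            return True
        for node in self.preorder():
            degree = len(node.children) + (node.parent is not None)
            if node.is_leaf:
                continue
            if degree != 3:
                return False
        return True

    def normalize(self) -> "Tree":
        """Suppress degree-2 nodes (merging edge lengths) and re-anchor.

        After normalization the anchor is an internal node of unrooted degree
        >= 3 whenever the tree has >= 3 leaves.
        """
        # remove childless internal nodes can't occur; suppress unifurcations
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if node.is_leaf or node is self.root:
                    continue
                if len(node.children) == 1:
                    child = node.children[0]
                    if node.length is not None or child.length is not None:
                        child.length = (node.length or 0.0) + (child.length or 0.0)
                    parent = node.parent
                    idx = parent.children.index(node)
                    node.children = []
                    child.parent = parent
                    parent.children[idx] = child
                    node.parent = None
                    changed = True
        # de-root: anchor must not have a single child, nor two children when
        # an internal child can absorb the anchor
        while len(self.root.children) == 1 and not self.root.children[0].is_leaf:
            new_root = self.root.children[0]
            new_root.parent = None
            new_root.length = None
            self.root = new_root
        if len(self.root.children) == 1 and self.root.children[0].is_leaf:
            # two-node tree written as root above a leaf: keep as is
            pass
        if len(self.root.children) == 2:
            a, b = self.root.children
            merge = a if not a.is_leaf else (b if not b.is_leaf else None)
            if merge is not None:
                other = b if merge is a else a
                if merge.length is not None or other.length is not None:
                    other.length = (merge.length or 0.0) + (other.length or 0.0)
                self.root.children.remove(merge)
                for child in list(merge.children):
                    self.root.add(child)
                merge.children = []
                merge.parent = None
        return self

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def newick(self, lengths: bool = True) -> str:
        def fmt(node):
            if node.is_leaf:
                body = _quote_label(node.label)
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.length is not None and node.parent is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"

    def topology_key(self) -> frozenset:
        """Canonical hashable key of the unrooted topology (ignores lengths)."""
        universe = self.leaf_labels
        return frozenset(b.side for b in bipartitions(self, universe))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Tree n_leaves={self.n_leaves}>"


def _quote_label(label: str) -> str:
    specials = set("()[]{}:;,'=\t\n ")
    if any(ch in specials for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------- #
# parsing (delegated to dendropy, converted to this module's structure)
# ---------------------------------------------------------------------- #
def parse_newick(text: str) -> Tree:
    """Parse a single newick string into a normalized unrooted :class:`Tree`.

    Polytomies and missing branch lengths are allowed; quoted labels are
    supported; internal node labels are parsed but ignored.
    """
    if not text.strip():
        raise NewickError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickError(f"malformed newick: {exc}") from None
    root = _convert_dendropy(dtree.seed_node)
    tree = Tree(root).normalize()
    labels = [leaf.label for leaf in tree.leaves()]
    if any(lb is None or lb == "" for lb in labels):
        raise NewickError("unlabeled leaf in newick input")
    if len(labels) != len(set(labels)):
        dup = sorted({lb for lb in labels if labels.count(lb) > 1})
        raise NewickError(f"duplicate leaf label(s): {', '.join(dup)}")
    return tree


def _convert_dendropy(dnode) -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else None
    node = Node(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add(_convert_dendropy(child))
    return node


def read_newick_file(path) -> list[Tree]:
    """Read newick trees from a file (one tree per ';'-terminated statement)."""
    try:
        dtrees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"malformed newick in {path}: {exc}") from None
    trees = []
    for dtree in dtrees:
        tree = Tree(_convert_dendropy(dtree.seed_node)).normalize()
        labels = [leaf.label for leaf in tree.leaves()]
        if len(labels) != len(set(labels)):
            raise NewickError(f"duplicate leaf label in {path}")
        trees.append(tree)
    return trees


def write_newick_file(trees, path, lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.newick(lengths=lengths) + "\n")


# ---------------------------------------------------------------------- #
# bipartitions
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class Bipartition:
    """A split of a taxon universe induced by an internal edge.

    Stored canonically as the side *not* containing the lexicographically
    smallest taxon of the universe, which makes the representation independent
    of edge polarity.
    """

    side: frozenset
    universe: frozenset

    def __post_init__(self):
        side, universe = self.side, self.universe
        if not side <= universe:
            raise ValueError("bipartition side not contained in universe")
        ref = min(universe)
        if ref in side:
            object.__setattr__(self, "side", universe - side)
        if not (2 <= len(self.side) <= len(universe) - 2):
            raise ValueError("trivial bipartition")

    @property
    def other_side(self) -> frozenset:
        return self.universe - self.side

    def restricted(self, subset: frozenset):
        """The induced bipartition on ``subset``, or None if trivial there."""
        a = self.side & subset
        b = subset - a
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition(a, frozenset(subset))

    def __repr__(self):
        return "|".join(
            ",".join(sorted(s)) for s in (self.side, self.other_side)
        )


def bipartitions(tree: Tree, universe=None) -> set:
    """The set of non-trivial bipartitions induced by the tree's internal edges.

    ``universe`` defaults to the tree's own leaf set; it may be a superset,
    in which case splits are still taken on the tree's leaves but expressed
    canonically with respect to ``universe``.
    """
    leaves = tree.leaf_labels
    if universe is None:
        universe = leaves
    else:
        universe = frozenset(universe)
        if not leaves <= universe:
            missing = sorted(leaves - universe)
            raise ValueError(f"leaf labels not in universe: {missing}")
    result = set()
    below = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is not None:
            side = below[id(node)]
            if 2 <= len(side) <= len(leaves) - 2:
                result.add(Bipartition(side, universe))
    return result


# ---------------------------------------------------------------------- #
# restriction
# ---------------------------------------------------------------------- #
def restrict(tree: Tree, subset) -> Tree:
    """The induced subtree on ``subset`` with degree-2 nodes suppressed.

    Branch lengths along suppressed paths are summed when present.
    """
    keep = frozenset(subset) & tree.leaf_labels
    if not keep:
        raise ValueError("restriction to an empty leaf set")

    def build(node):
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kept = [b for b in (build(c) for c in node.children) if b is not None]
        if not kept:
            return None
        clone = Node(node.label, node.length)
        for k in kept:
            clone.add(k)
        return clone

    root = build(tree.root)
    return Tree(root).normalize()


# ---------------------------------------------------------------------- #
# building trees from compatible clusters
# ---------------------------------------------------------------------- #
class ClusterTreeBuilder:
    """Incrementally build a tree on ``taxa`` from compatible bipartitions.

    Bipartitions are handled as "clusters": the side not containing the
    reference taxon (the lexicographically smallest). ``try_insert`` refuses
    incompatible clusters, which is exactly the test greedy consensus needs.
    """

    def __init__(self, taxa):
        self.taxa = frozenset(taxa)
        if len(self.taxa) < 1:
            raise ValueError("empty taxon set")
        self.ref = min(self.taxa)
        self.root = Node()
        self._leafset = {id(self.root): self.taxa}
        for label in sorted(self.taxa):
            leaf = self.root.add(Node(label))
            self._leafset[id(leaf)] = frozenset([label])

    def try_insert(self, cluster: frozenset) -> bool:
        """Insert a cluster (side excluding the reference taxon); False if
        incompatible with the clusters already present."""
        cluster = frozenset(cluster)
        if self.ref in cluster or not 2 <= len(cluster) <= len(self.taxa) - 2:
            raise ValueError("cluster must be a non-trivial side excluding the reference taxon")
        node = self.root
        while True:
            inside = [c for c in node.children if self._leafset[id(c)] & cluster]
            if len(inside) == 1 and self._leafset[id(inside[0])] >= cluster:
                child = inside[0]
                if self._leafset[id(child)] == cluster:
                    return True  # already present
                if child.is_leaf:
                    return False
                node = child
                continue
            break
        union = frozenset().union(*(self._leafset[id(c)] for c in inside))
        if union != cluster:
            return False
        if any(not self._leafset[id(c)] <= cluster for c in inside):
            return False
        fresh = Node()
        for child in inside:
            child.detach()
            fresh.add(child)
        node.add(fresh)
        self._leafset[id(fresh)] = union
        return True

    def tree(self) -> Tree:
        return Tree(self.root).copy().normalize()


def tree_from_clusters(taxa, clusters) -> Tree:
    """Build the tree displaying exactly the given compatible bipartition sides."""
    builder = ClusterTreeBuilder(taxa)
    for cluster in sorted(clusters, key=lambda c: (-len(c), tuple(sorted(c)))):
        if not builder.try_insert(cluster):
            raise ValueError(f"incompatible cluster: {sorted(cluster)}")
    return builder.tree()


# ---------------------------------------------------------------------- #
# consensus primitive and random refinement
# ---------------------------------------------------------------------- #
def strict_consensus(trees) -> Tree:
    """The tree whose bipartitions are exactly those shared by all inputs."""
    trees = list(trees)
    if not trees:
        raise ValueError("strict consensus of an empty collection")
    taxa = trees[0].leaf_labels
    for tree in trees[1:]:
        if tree.leaf_labels != taxa:
            raise ValueError("strict consensus requires identical leaf sets")
    common = set.intersection(*({b.side for b in bipartitions(t, taxa)} for t in trees))
    return tree_from_clusters(taxa, common)


def random_refinement(tree: Tree, seed) -> Tree:
    """Refine every polytomy into a binary resolution chosen at random.

    Each polytomy is resolved by repeatedly joining two randomly chosen
    members of its neighbor set under a fresh node (random coalescence);
    this is deterministic given ``seed`` and covers all resolutions, though
    not uniformly.
    """
    rng = random.Random(seed) if not isinstance(seed, random.Random) else seed
    out = tree.copy()
    for node in list(out.preorder()):
        limit = 3 if node.parent is None else 2
        while len(node.children) > limit:
            i, j = sorted(rng.sample(range(len(node.children)), 2))
            a, b = node.children[i], node.children[j]
            joint = Node()
            a.detach()
            b.detach()
            joint.add(a)
            joint.add(b)
            node.add(joint)
    # a 3-leaf anchored star is already unrooted-binary; normalize re-anchors
    return out.normalize()


# ---------------------------------------------------------------------- #
# profiles
# ---------------------------------------------------------------------- #
@dataclass
class SourceProfile:
    """An ordered collection of source trees and their union taxon set S."""

    trees: list = field(default_factory=list)
    min_leaves: int = 4

    def __post_init__(self):
        for i, tree in enumerate(self.trees):
            if tree.n_leaves < self.min_leaves:
                raise ValueError(
                    f"source tree {i} has {tree.n_leaves} leaves; "
                    f"trees with < {self.min_leaves} leaves carry no unrooted topology"
                )

    @property
    def taxa(self) -> frozenset:
        if not self.trees:
            return frozenset()
        return frozenset().union(*(t.leaf_labels for t in self.trees))

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @classmethod
    def load(cls, path) -> "SourceProfile":
        """Load from a multi-newick file, or a directory of newick files."""
        trees = []
        if os.path.isdir(path):
            for name in sorted(os.listdir(path)):
                full = os.path.join(path, name)
                if os.path.isfile(full):
                    trees.extend(read_newick_file(full))
        else:
            trees = read_newick_file(path)
        return cls(trees)

    def save(self, path) -> None:
        write_newick_file(self.trees, path)
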