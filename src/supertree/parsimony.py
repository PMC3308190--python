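"""Reversible Fitch parsimony and a heuristic maximum-parsimony search.

This is the MRP criterion engine: columns over {0,1,?} are scored by the
minimum number of 0<->1 changes over all internal-state assignments ('?'
leaves free), and trees are searched by random-addition greedy construction
followed by NNI/SPR hill climbing with an optional column-reweighting
ratchet. The search is this package's own MP heuristic, playing the role
that dedicated parsimony programs play in large-scale MRP analyses.

Two scoring paths are kept: a bit-parallel Fitch pass over Python integers
(exact for binary trees, used by the search) and a vectorized Hartigan pass
(exact for any multifurcating tree, used for general scoring); tests pin
both to a brute-force oracle.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np

from .encoding import MISSING, ONE, ZERO, CharacterMatrix
from .report import ScoreReport
from .trees import Node, Tree, random_refinement

__all__ = [
    "MPSearchConfig",
    "fitch_column_score",
    "mp_score",
    "mp_search",
    "mp_search_constrained",
]


@dataclass
class MPSearchConfig:
    """Knobs of the MP heuristic; ``seed`` fixes the full search trajectory."""

    n_starts: int = 3
    moves: tuple = ("nni", "spr")
    ratchet_rounds: int = 0
    ratchet_fraction: float = 0.25
    max_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")
        if not 0.0 < self.ratchet_fraction < 1.0:
            raise ValueError("ratchet_fraction must lie in (0, 1)")
        bad = set(self.moves) - {"nni", "spr"}
        if bad:
            raise ValueError(f"unknown moves: {sorted(bad)}")


# ---------------------------------------------------------------------- #
# scoring
# ---------------------------------------------------------------------- #
# Hartigan state-set bitmasks: 1 = {0}, 2 = {1}, 3 = {0,1}
_CODE_TO_SET = {ZERO: 1, ONE: 2, MISSING: 3, "0": 1, "1": 2, "?": 3, None: 3, 0: 1, 1: 2}


def _hartigan_changes(tree: Tree, state_sets: dict, ncol: int, dtype=np.int32):
    """Per-column minimum change counts by Hartigan's generalized Fitch pass.

    ``state_sets`` maps leaf label -> (ncol,) uint8 bitmask array; leaves
    absent from the map count as all-missing.
    """
    changes = np.zeros(ncol, dtype=dtype)
    full = np.full(ncol, 3, dtype=np.uint8)
    sets = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = state_sets.get(node.label, full)
            continue
        kids = [sets.pop(id(c)) for c in node.children]
        cnt0 = np.zeros(ncol, dtype=dtype)
        cnt1 = np.zeros(ncol, dtype=dtype)
        for s in kids:
            cnt0 += s & 1
            cnt1 += s >> 1
        best = np.maximum(cnt0, cnt1)
        changes += len(kids) - best
        sets[id(node)] = ((cnt0 == best) * 1 | (cnt1 == best) * 2).astype(np.uint8)
    return changes


def fitch_column_score(tree: Tree, column: dict) -> int:
    """Minimum 0<->1 changes for one column (a map leaf label -> 0/1/'?').

    Missing leaves are free; multifurcations are handled exactly. A column
    with fewer than two observed states scores 0 (degenerate, not an error).
    """
    sets = {
        label: np.array([_CODE_TO_SET[value]], dtype=np.uint8)
        for label, value in column.items()
    }
    unknown = set(column) - tree.leaf_labels
    if unknown:
        raise ValueError(f"column taxa absent from tree: {sorted(unknown)}")
    return int(_hartigan_changes(tree, sets, 1)[0])


def _matrix_state_sets(matrix: CharacterMatrix) -> dict:
    lut = np.array([1, 2, 3], dtype=np.uint8)
    return {t: lut[matrix.data[i]] for i, t in enumerate(matrix.taxa)}


def mp_score(tree: Tree, matrix: CharacterMatrix, weights=None) -> int:
    """Total parsimony score of ``tree`` for every column of the MRP matrix."""
    missing = set(matrix.taxa) - set(tree.leaf_labels)
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    changes = _hartigan_changes(tree, _matrix_state_sets(matrix), matrix.ncol)
    if weights is None:
        return int(changes.sum())
    return int(np.dot(changes, weights))


# -- bit-parallel Fitch (binary trees) ---------------------------------- #
class _BitData:
    """Per-taxon bitmask pair over columns: bit j of A set iff state 0 is
    allowed at column j, bit j of B iff state 1 is allowed."""

    def __init__(self, matrix: CharacterMatrix, taxa=None):
        self.ncol = matrix.ncol
        self.mask = (1 << matrix.ncol) - 1
        self.A = {}
        self.B = {}
        rows = {t: matrix.data[i] for i, t in enumerate(matrix.taxa)}
        for t in taxa if taxa is not None else matrix.taxa:
            row = rows[t]
            a = b = 0
            for j in range(matrix.ncol):
                c = row[j]
                if c != ONE:
                    a |= 1 << j
                if c != ZERO:
                    b |= 1 << j
            self.A[t] = a
            self.B[t] = b

    def score(self, tree: Tree) -> int:
        """Exact Fitch score for a fully binary (unrooted) tree."""
        full = self.mask
        cost = 0
        acc = {}
        for node in tree.postorder():
            if node.is_leaf:
                acc[id(node)] = (self.A.get(node.label, full), self.B.get(node.label, full))
                continue
            it = iter(node.children)
            a, b = acc.pop(id(next(it)))
            for child in it:
                ca, cb = acc.pop(id(child))
                ia, ib = a & ca, b & cb
                empty = full & ~(ia | ib)
                cost += empty.bit_count()
                a = ia | (empty & (a | ca))
                b = ib | (empty & (b | cb))
            acc[id(node)] = (a, b)
        return cost


# ---------------------------------------------------------------------- #
# tree surgery for the search
# ---------------------------------------------------------------------- #
def _reanchor(tree: Tree, node: Node) -> Tree:
    """Re-anchor the traversal at ``node`` (an internal node), in place."""
    if node is tree.root:
        return tree
    path = []
    cur = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    for child, parent in zip(reversed(path[:-1]), reversed(path[1:])):
        parent.children.remove(child)
        child.add(parent)
        parent.length = child.length
    node.length = None
    node.parent = None
    tree.root = node
    return tree


def _insert_leaf_on_edge(tree: Tree, below: Node, label, rng_pos=None) -> Node:
    """Subdivide the edge above ``below`` and attach a new leaf there."""
    parent = below.parent
    mid = Node()
    idx = parent.children.index(below)
    parent.children[idx] = mid
    mid.parent = parent
    below.parent = mid
    mid.children.append(below)
    leaf = mid.add(Node(label))
    return leaf


def _remove_leaf(tree: Tree, leaf: Node) -> None:
    parent = leaf.parent
    leaf.detach()
    if parent is not None and len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        gp = parent.parent
        idx = gp.children.index(parent)
        gp.children[idx] = only
        only.parent = gp
        parent.children = []
        parent.parent = None
    elif parent is tree.root and len(parent.children) <= 2:
        tree.normalize()


def _edges(tree: Tree):
    """All edges, as the nodes below them, in deterministic preorder."""
    return [n for n in tree.preorder() if n.parent is not None]


def _nni_neighbors(tree: Tree):
    """Distinct NNI rearrangements around every internal edge (binary trees)."""
    out = []
    base = tree.copy()
    nodes = [
        n
        for n in base.preorder()
        if n.parent is not None and not n.is_leaf and not n.parent.is_leaf
    ]
    # enumerate by (edge index, side) on fresh copies to keep surgery simple
    n_edges = len(nodes)
    for ei in range(n_edges):
        for side in range(2):
            cand = tree.copy()
            cnodes = [
                n
                for n in cand.preorder()
                if n.parent is not None and not n.is_leaf and not n.parent.is_leaf
            ]
            v = cnodes[ei]
            u = v.parent
            _reanchor(cand, u)
            others = [c for c in u.children if c is not v]
            if not others or not v.children:
                continue
            a = v.children[0]
            if side >= len(others):
                continue
            b = others[side]
            a.detach()
            b.detach()
            u.add(a)
            v.add(b)
            out.append(cand)
    return out


def _spr_neighbors(tree: Tree):
    """Subtree-prune-regraft rearrangements, lazily generated."""
    n_edges = len(_edges(tree))
    for pi in range(n_edges):
        base = tree.copy()
        prune = _edges(base)[pi]
        parent = prune.parent
        prune.detach()
        # suppress the degree-2 node left behind
        if parent.parent is not None and len(parent.children) == 1:
            only = parent.children[0]
            gp = parent.parent
            idx = gp.children.index(parent)
            gp.children[idx] = only
            only.parent = gp
            parent.children = []
            parent.parent = None
        elif parent is base.root and len(parent.children) == 2:
            base.normalize()
        if base.root.is_leaf or len(base.root.children) < 2:
            continue
        remainder_edges = len(_edges(base))
        for ti in range(remainder_edges):
            cand_rest = base.copy()
            # copy the pruned subtree for each candidate
            sub = Tree(prune).copy().root
            target = _edges(cand_rest)[ti]
            tparent = target.parent
            mid = Node()
            idx = tparent.children.index(target)
            tparent.children[idx] = mid
            mid.parent = tparent
            target.parent = mid
            mid.children.append(target)
            mid.add(sub)
            yield cand_rest.normalize()


# ---------------------------------------------------------------------- #
# search
# ---------------------------------------------------------------------- #
def _greedy_addition_tree(matrix, bits, order) -> Tree:
    root = Node()
    tree = Tree(root)
    for label in order[:3]:
        root.add(Node(label))
    if len(order) == 3:
        return tree
    for label in order[3:]:
        best = None
        best_score = None
        for below in _edges(tree):
            leaf = _insert_leaf_on_edge(tree, below, label)
            s = bits.score(tree)
            mid = leaf.parent
            _remove_leaf(tree, leaf)
            # undo subdivision
            only = mid.children[0] if mid.children else None
            if only is not None and mid.parent is not None:
                gp = mid.parent
                idx = gp.children.index(mid)
                gp.children[idx] = only
                only.parent = gp
                mid.children = []
                mid.parent = None
            if best_score is None or s < best_score:
                best_score, best = s, below
        _insert_leaf_on_edge(tree, best, label)
    return tree


def _hill_climb(tree, score_fn, moves, collect=None, cap=100):
    """Strict-improvement hill climbing; optionally collects equal-score
    topologies seen along the way into ``collect`` (a dict key -> tree)."""
    current = tree
    cur_score = score_fn(current)
    improved = True
    while improved:
        improved = False
        if "nni" in moves:
            for cand in _nni_neighbors(current):
                s = score_fn(cand)
                if s < cur_score:
                    current, cur_score = cand, s
                    improved = True
                    break
                if collect is not None and s == cur_score and len(collect) < cap:
                    collect.setdefault(cand.topology_key(), cand)
            if improved:
                continue
        if "spr" in moves:
            for cand in _spr_neighbors(current):
                s = score_fn(cand)
                if s < cur_score:
                    current, cur_score = cand, s
                    improved = True
                    break
    return current, cur_score


def _drop_uninformative_rows(matrix: CharacterMatrix) -> CharacterMatrix:
    keep = [i for i in range(matrix.ntax) if (matrix.data[i] != MISSING).any()]
    if len(keep) == matrix.ntax:
        return matrix
    dropped = [matrix.taxa[i] for i in range(matrix.ntax) if i not in keep]
    warnings.warn(f"dropping unplaceable all-missing taxa: {dropped}")
    return CharacterMatrix(
        taxa=[matrix.taxa[i] for i in keep],
        data=matrix.data[keep],
        provenance=list(matrix.provenance),
    )


def mp_search(matrix: CharacterMatrix, config: MPSearchConfig | None = None):
    """Heuristic MP search; returns (equally-best trees, ScoreReport).

    Each start builds a random-addition greedy tree, then hill-climbs under
    the configured move set; optional ratchet rounds perturb column weights
    and re-search. Distinct best-scoring topologies found along the way are
    retained (deduplicated, capped at ``config.max_trees``).
    """
    config = config or MPSearchConfig()
    matrix = _drop_uninformative_rows(matrix)
    if matrix.ntax < 4:
        raise ValueError("MP search needs a matrix with >= 4 placeable taxa")
    bits = _BitData(matrix)
    best_score = None
    best: dict = {}
    for start in range(config.n_starts):
        rng = random.Random(config.seed * 1000003 + start)
        order = list(matrix.taxa)
        rng.shuffle(order)
        tree = _greedy_addition_tree(matrix, bits, order)
        collect: dict = {}
        tree, score = _hill_climb(tree, bits.score, config.moves, collect, config.max_trees)
        for _ in range(config.ratchet_rounds):
            weights = np.ones(matrix.ncol)
            picked = rng.sample(range(matrix.ncol), max(1, int(config.ratchet_fraction * matrix.ncol)))
            weights[picked] = 2.0
            sets = _matrix_state_sets(matrix)

            def wscore(t, _w=weights, _s=sets):
                return float(np.dot(_hartigan_changes(t, _s, matrix.ncol), _w))

            perturbed, _ = _hill_climb(tree.copy(), wscore, ("nni",))
            cand, cand_score = _hill_climb(perturbed, bits.score, config.moves)
            if cand_score < score:
                tree, score = cand, cand_score
        if best_score is None or score < best_score:
            best_score = score
            best = {tree.topology_key(): tree}
            for key, t in collect.items():
                if bits.score(t) == best_score and len(best) < config.max_trees:
                    best.setdefault(key, t)
        elif score == best_score:
            if len(best) < config.max_trees:
                best.setdefault(tree.topology_key(), tree)
            for key, t in collect.items():
                if bits.score(t) == best_score and len(best) < config.max_trees:
                    best.setdefault(key, t)
    trees = sorted(best.values(), key=lambda t: t.newick(lengths=False))
    report = ScoreReport(mp_score=int(best_score), ncol=matrix.ncol, ntax=matrix.ntax)
    return trees, report


def mp_search_constrained(matrix: CharacterMatrix, constraint: Tree, config=None):
    """MP search over refinements of ``constraint`` only.

    Every returned tree displays all of the constraint's bipartitions; with a
    binary constraint the constraint itself is returned.
    """
    config = config or MPSearchConfig()
    matrix = _drop_uninformative_rows(matrix)
    if set(matrix.taxa) - set(constraint.leaf_labels):
        raise ValueError("constraint tree is missing matrix taxa")
    required = constraint.topology_key()
    bits = _BitData(matrix)

    def admissible(t):
        return required <= t.topology_key()

    best_score = None
    best: dict = {}
    for start in range(config.n_starts):
        rng = random.Random(config.seed * 1000003 + 7919 * (start + 1))
        tree = random_refinement(constraint, rng)
        score = bits.score(tree)
        improved = True
        while improved:
            improved = False
            neighbors = _nni_neighbors(tree)
            if "spr" in config.moves:
                neighbors = list(neighbors) + list(_spr_neighbors(tree))
            for cand in neighbors:
                s = bits.score(cand)
                if s < score and admissible(cand):
                    tree, score = cand, s
                    improved = True
                    break
        if best_score is None or score < best_score:
            best_score, best = score, {tree.topology_key(): tree}
        elif score == best_score and len(best) < config.max_trees:
            best.setdefault(tree.topology_key(), tree)
    trees = sorted(best.values(), key=lambda t: t.newick(lengths=False))
    report = ScoreReport(mp_score=int(best_score), ncol=matrix.ncol, ntax=matrix.ntax)
    return trees, report
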