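"""Synthetic source-tree profiles with clade-plus-scaffold structure.

A binary model tree is drawn from a Yule-type growth process with
exponential branch lengths (mean 0.1 substitutions/site). A profile
consists of a number of clade-based source trees — the model tree restricted
to *all* taxa of a randomly chosen clade (dense sampling) — plus one
scaffold tree: the model restricted to a uniform random sample of a
proportion (the scaffold density) of all taxa. Estimation error, when
requested, is introduced either by simulating binary characters on each
source tree under the symmetric 2-state model and re-estimating the
topology by MP (error shrinks as sites grow), or by a Poisson number of
random NNI moves.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np

from .encoding import MISSING, ONE, ZERO, CharacterMatrix
from .parsimony import MPSearchConfig, _nni_neighbors, mp_search
from .trees import Node, SourceProfile, Tree, restrict

__all__ = [
    "SimDesign",
    "simulate_model_tree",
    "sample_clade_tree",
    "sample_scaffold_tree",
    "simulate_characters",
    "add_estimation_error",
    "make_profile",
]


@dataclass
class SimDesign:
    """Study-design knobs for one simulated profile.

    Defaults mirror the published clade-plus-scaffold design at its smaller
    problem size: 500 taxa, 15 clade trees, clade sizes uniform between
    n/20 and n/4, one scaffold tree at the given density. The characters
    error mode simulates ``error_sites`` binary sites per source tree and
    re-estimates its topology by MP.
    """

    n_taxa: int = 500
    n_clade_trees: int = 15
    scaffold_density: float = 1.0
    clade_size_range: tuple | None = None  # default (n/20, n/4)
    error_mode: str = "none"  # {"none", "characters", "nni"}
    error_sites: int = 250
    nni_rate: float = 0.1
    branch_length_mean: float = 0.1
    ensure_connected: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.scaffold_density <= 1.0:
            raise ValueError("scaffold density must lie in (0, 1]")
        if self.scaffold_density * self.n_taxa < 4:
            raise ValueError("scaffold would have fewer than 4 taxa")
        if self.clade_size_range is None:
            lo = max(4, self.n_taxa // 20)
            hi = max(lo, self.n_taxa // 4)
            self.clade_size_range = (lo, hi)
        if self.clade_size_range[0] < 4:
            raise ValueError("clades need at least 4 taxa")
        if self.error_mode not in ("none", "characters", "nni"):
            raise ValueError(f"unknown error mode: {self.error_mode}")


def simulate_model_tree(n: int, seed, branch_length_mean: float = 0.1) -> Tree:
    """A random binary model tree on taxa t0001..t{n} with positive lengths.

    Topology grows by splitting a uniformly chosen pendant edge (Yule
    process); branch lengths are i.i.d. exponential.
    """
    if n < 3:
        raise ValueError("need at least 3 taxa")
    rng = random.Random(seed) if not isinstance(seed, random.Random) else seed
    labels = [f"t{i + 1:04d}" for i in range(n)]
    root = Node()
    pendants = []
    for lb in labels[:3]:
        pendants.append(root.add(Node(lb)))
    for lb in labels[3:]:
        target = rng.choice(pendants)
        parent = target.parent
        mid = Node()
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        target.parent = mid
        mid.children.append(target)
        leaf = mid.add(Node(lb))
        pendants.append(leaf)
    tree = Tree(root)
    for node in tree.preorder():
        if node.parent is not None:
            node.length = rng.expovariate(1.0 / branch_length_mean)
            node.length = max(node.length, 1e-6)
    return tree


def _clades(tree: Tree, lo: int, hi: int):
    """Edge-delimited taxon groups (either side of any edge) within size."""
    n = tree.n_leaves
    below = {}
    out = []
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is not None:
            side = below[id(node)]
            if lo <= len(side) <= hi:
                out.append(side)
            other = n - len(side)
            if lo <= other <= hi:
                out.append(tree.leaf_labels - side)
    return sorted(set(out), key=lambda s: tuple(sorted(s)))


def sample_clade_tree(model: Tree, size_range, seed) -> Tree:
    """The model tree restricted to every taxon of one random in-range clade."""
    rng = random.Random(seed) if not isinstance(seed, random.Random) else seed
    lo, hi = size_range
    clades = _clades(model, lo, hi)
    if not clades:
        raise ValueError(f"no clade of size within [{lo}, {hi}]")
    return restrict(model, rng.choice(clades))


def sample_scaffold_tree(model: Tree, density: float, seed) -> Tree:
    """The model tree restricted to ceil(density * n) uniform random taxa."""
    rng = random.Random(seed) if not isinstance(seed, random.Random) else seed
    taxa = sorted(model.leaf_labels)
    k = int(np.ceil(density * len(taxa)))
    if k < 4:
        raise ValueError("scaffold must keep at least 4 taxa")
    return restrict(model, rng.sample(taxa, k))


def simulate_characters(tree: Tree, n_sites: int, seed, site_rates=None) -> CharacterMatrix:
    """Simulate binary characters on a tree under the symmetric 2-state model.

    The root state is a fair coin; a state flips across a branch of length t
    at relative site rate r with probability (1 - exp(-2 r t)) / 2.
    ``site_rates`` (length n_sites) models rate heterogeneity; default 1.
    """
    rng = np.random.default_rng(seed)
    rates = np.ones(n_sites) if site_rates is None else np.asarray(site_rates, float)
    states = {}
    root = tree.root
    states[id(root)] = rng.integers(0, 2, size=n_sites)
    for node in tree.preorder():
        if node is root:
            continue
        if node.length is None or node.length < 0:
            raise ValueError("simulation requires non-negative branch lengths")
        p_flip = 0.5 * (1.0 - np.exp(-2.0 * rates * node.length))
        flips = rng.random(n_sites) < p_flip
        states[id(node)] = np.where(flips, 1 - states[id(node.parent)], states[id(node.parent)])
    taxa = sorted(tree.leaf_labels)
    leaf_states = {n.label: states[id(n)] for n in tree.leaves()}
    data = np.vstack([leaf_states[t] for t in taxa]).astype(np.uint8)
    return CharacterMatrix(taxa=taxa, data=data)


def add_estimation_error(tree: Tree, mode: str, seed, n_sites: int = 250,
                         nni_rate: float = 0.1) -> Tree:
    """A noisy re-estimate of a source tree.

    characters mode: simulate ``n_sites`` binary characters on the tree and
    re-estimate the topology with the MP heuristic, so error arises from
    finite data and vanishes as n_sites grows. nni mode: apply a
    Poisson(rate * (n-3)) number of random NNI rearrangements.
    """
    if mode == "none":
        return tree.copy()
    rng = random.Random(seed) if not isinstance(seed, random.Random) else seed
    if mode == "characters":
        matrix = simulate_characters(tree, n_sites, rng.randrange(2**31))
        trees, _ = mp_search(
            matrix,
            MPSearchConfig(n_starts=1, moves=("nni", "spr"), seed=rng.randrange(2**31)),
        )
        return trees[0]
    if mode == "nni":
        n_moves = np.random.default_rng(rng.randrange(2**31)).poisson(
            nni_rate * max(tree.n_leaves - 3, 0)
        )
        out = tree.copy()
        for _ in range(n_moves):
            neighbors = _nni_neighbors(out)
            if not neighbors:
                break
            out = rng.choice(neighbors)
        return out
    raise ValueError(f"unknown error mode: {mode}")


def _connected(trees) -> bool:
    """Whether the greedy >= 2-overlap merger can reach a single tree."""
    leafsets = [t.leaf_labels for t in trees]
    merged = leafsets[0]
    remaining = leafsets[1:]
    progress = True
    while remaining and progress:
        progress = False
        for ls in list(remaining):
            if len(merged & ls) >= 2:
                merged |= ls
                remaining.remove(ls)
                progress = True
    return not remaining


def make_profile(design: SimDesign):
    """Generate (SourceProfile, model tree) per the clade + scaffold design.

    Profiles whose overlap structure cannot support a merger are resampled
    with a perturbed seed (mirroring the exclusion of replicates without
    sufficient taxonomic overlap); ``ensure_connected=False`` keeps the
    first draw and only warns.
    """
    for attempt in range(50):
        rng = random.Random((design.seed + 1) * 100003 + attempt)
        model = simulate_model_tree(design.n_taxa, rng, design.branch_length_mean)
        sources = []
        for _ in range(design.n_clade_trees):
            sources.append(sample_clade_tree(model, design.clade_size_range, rng))
        sources.append(sample_scaffold_tree(model, design.scaffold_density, rng))
        sources = [
            add_estimation_error(
                t, design.error_mode, rng, n_sites=design.error_sites,
                nni_rate=design.nni_rate,
            )
            for t in sources
        ]
        if _connected(sources):
            return SourceProfile(sources), model
        if not design.ensure_connected:
            warnings.warn("profile overlap structure too sparse for a full merger")
            return SourceProfile(sources), model
    raise RuntimeError("could not draw a connected profile in 50 attempts")
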