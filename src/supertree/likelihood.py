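"""Symmetric 2-state (CFN) likelihood with discrete-gamma rates: the MRL engine.

The model has states {0,1}, stationary frequencies (1/2, 1/2) and a single
exchange rate, normalized so branch lengths are expected substitutions per
site; the probability of observing a change across a branch of length t at
relative rate r is (1 - exp(-2 r t)) / 2. Rate heterogeneity uses Yang's
equal-probability discrete gamma with mean-1 categories (k = 1 reduces
exactly to equal rates). '?' cells contribute a flat (1,1) tip partial.

Likelihoods are computed by Felsenstein pruning, vectorized over columns and
rate categories. Branch lengths are optimized one edge at a time against the
edge's inside/outside conditional likelihoods; a cheap whole-sweep update is
tried first and the method falls back to exact per-edge recomputation
whenever that sweep fails to improve, so the returned log-likelihood never
decreases.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _opt
from scipy import special as _sp

from .encoding import MISSING, ONE, ZERO, CharacterMatrix
from .parsimony import MPSearchConfig, _nni_neighbors, mp_search
from .report import ScoreReport
from .trees import Tree, random_refinement

__all__ = [
    "GammaRates",
    "S2Model",
    "MLSearchConfig",
    "transition_probabilities",
    "site_log_likelihood",
    "tree_log_likelihood",
    "optimize_branch_lengths",
    "optimize_alpha",
    "ml_search",
    "mrl_score",
    "with_branch_lengths",
]

_LL_FLOOR = 1e-300  # columns cannot be less likely than this before log


@dataclass(frozen=True)
class S2Model:
    """The symmetric 2-state substitution model (fixed; kept for reference)."""

    states: tuple = (0, 1)
    frequencies: tuple = (0.5, 0.5)


def transition_probabilities(t: float, rate: float = 1.0):
    """(P(same), P(change)) across a branch of length t at relative rate r."""
    if t < 0:
        raise ValueError("negative branch length")
    p_change = 0.5 * (1.0 - math.exp(-2.0 * rate * t))
    return 1.0 - p_change, p_change


@dataclass
class GammaRates:
    """Mean-1 discrete gamma rates: k equal-probability categories, each
    represented by its within-category mean (Yang's discretization)."""

    alpha: float
    k: int = 4
    rates: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.k < 1:
            raise ValueError("need at least one rate category")
        if self.rates is None:
            self.rates = _discrete_gamma_rates(self.alpha, self.k)
        self.rates = np.asarray(self.rates, dtype=float)
        if abs(self.rates.mean() - 1.0) > 1e-9:
            raise ValueError("category rates must average to 1")
        if np.any(np.diff(self.rates) < 0):
            raise ValueError("category rates must be non-decreasing")

    @classmethod
    def equal(cls) -> "GammaRates":
        return cls(alpha=1.0, k=1)


def _discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    if k == 1:
        return np.array([1.0])
    # X ~ Gamma(shape a, scale 1/a), mean 1. Bin edges at quantiles i/k;
    # the mean within a bin follows from the shape a+1 identity:
    # E[X; x<b] = F_{a+1}(b) for this parameterization.
    quantiles = np.arange(k + 1) / k
    edges = _sp.gammaincinv(alpha, quantiles)  # in units of a*x
    cdf_upper = _sp.gammainc(alpha + 1.0, edges)
    rates = k * np.diff(cdf_upper)
    return np.sort(np.maximum(rates, 1e-12))


@dataclass
class MLSearchConfig:
    """Knobs of the ML (MRL) search heuristic."""

    start: str = "mp"  # {"mp", "random", "given"}
    categories: int = 4
    bl_bounds: tuple = (1e-8, 20.0)
    alpha_bounds: tuple = (0.02, 100.0)
    tolerance: float = 1e-3  # accept a rearrangement only above this gain
    per_site_categories: bool = False
    n_candidates: int = 2  # neighbors fully re-optimized per NNI round
    max_rounds: int = 50
    fit_rounds: int = 2  # (lengths, shape) alternations per scored topology
    fit_sweeps: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


# ---------------------------------------------------------------------- #
# pruning engine
# ---------------------------------------------------------------------- #
def _tip_partials(matrix: CharacterMatrix):
    cached = getattr(matrix, "_tip_cache", None)
    if cached is not None:
        return cached
    tips = {}
    for i, taxon in enumerate(matrix.taxa):
        row = matrix.data[i]
        arr = np.ones((1, matrix.ncol, 2))
        arr[0, row == ZERO, 1] = 0.0
        arr[0, row == ONE, 0] = 0.0
        tips[taxon] = arr
    matrix._tip_cache = tips  # matrices are treated as immutable
    return tips


class _Engine:
    """Pruning machinery bound to one tree's node objects.

    Branch lengths are read from / written to the tree's nodes, so the tree
    handed in is mutated by the optimizers (callers pass copies).
    """

    def __init__(self, tree: Tree, matrix: CharacterMatrix, rates, bl_bounds=(1e-8, 20.0)):
        self.tree = tree
        self.ncol = matrix.ncol
        self.rates = np.asarray(rates, dtype=float)
        self.bl_bounds = bl_bounds
        self.nodes = list(tree.postorder())  # children precede parents
        tips = _tip_partials(matrix)
        flat = np.ones((1, matrix.ncol, 2))
        self.tip = {}
        for node in self.nodes:
            if node.is_leaf:
                self.tip[id(node)] = tips.get(node.label, flat)
                if node.label not in tips and matrix.ncol:
                    pass  # leaf absent from matrix: flat partial
        for node in self.nodes:
            if node.parent is not None:
                if node.length is None:
                    raise ValueError("branch lengths required for likelihood")
                if node.length < 0:
                    raise ValueError("negative branch length")
        self.D: dict = {}
        self.m: dict = {}
        self.U: dict = {}

    def set_rates(self, rates) -> None:
        self.rates = np.asarray(rates, dtype=float)

    # -- transition application ------------------------------------------ #
    def _probs(self, t: float):
        pc = 0.5 * (1.0 - np.exp(-2.0 * self.rates * t))
        return (1.0 - pc)[:, None, None], pc[:, None, None]

    def _apply(self, t: float, arr):
        ps, pc = self._probs(t)
        return ps * arr + pc * arr[..., ::-1]

    # -- passes ----------------------------------------------------------- #
    def downpass(self):
        D, m = self.D, self.m
        for node in self.nodes:
            if node.is_leaf:
                D[id(node)] = self.tip[id(node)]
            else:
                prod = None
                for child in node.children:
                    prod = m[id(child)] if prod is None else prod * m[id(child)]
                D[id(node)] = prod
            if node.parent is not None:
                m[id(node)] = self._apply(node.length, D[id(node)])

    def uppass(self):
        U, m = self.U, self.m
        for node in reversed(self.nodes):  # parents before children
            kids = node.children
            if not kids:
                continue
            msgs = [m[id(c)] for c in kids]
            if node.parent is None:
                base = np.full((1, self.ncol, 2), 0.5)
            else:
                base = self._apply(node.length, U[id(node)])
            # product over siblings, excluding each child in turn
            n = len(msgs)
            prefix = [None] * (n + 1)
            suffix = [None] * (n + 1)
            prefix[0] = base
            for i in range(n):
                prefix[i + 1] = prefix[i] * msgs[i]
            suffix[n] = 1.0
            for i in range(n - 1, -1, -1):
                suffix[i] = msgs[i] * suffix[i + 1] if i < n - 1 else msgs[i]
            for i, child in enumerate(kids):
                excl = prefix[i]
                if i < n - 1:
                    excl = excl * suffix[i + 1]
                U[id(child)] = excl

    def _column_likelihoods(self):
        root = self.nodes[-1]
        prod = None
        for child in root.children:
            prod = self.m[id(child)] if prod is None else prod * self.m[id(child)]
        return 0.5 * prod.sum(axis=-1)  # (k, ncol)

    def full_ll(self, per_site_max: bool = False) -> float:
        self.downpass()
        L = self._column_likelihoods()
        if per_site_max:
            return float(np.log(np.maximum(L.max(axis=0), _LL_FLOOR)).sum())
        return float(np.log(np.maximum(L.mean(axis=0), _LL_FLOOR)).sum())

    # -- per-edge optimization -------------------------------------------- #
    def edge_ll_function(self, node):
        """ll(t) for the edge above ``node`` with everything else fixed."""
        U, D = self.U[id(node)], self.D[id(node)]
        A = np.broadcast_to((U * D).sum(axis=-1), (len(self.rates), self.ncol))
        C = np.broadcast_to((U * D[..., ::-1]).sum(axis=-1), A.shape) - A
        rates = self.rates[:, None]

        def ll(t):
            pc = 0.5 * (1.0 - np.exp(-2.0 * rates * t))
            E = A + pc * C
            return float(np.log(np.maximum(E.mean(axis=0), _LL_FLOOR)).sum())

        def ll_grad(t):
            expo = np.exp(-2.0 * rates * t)
            E = A + 0.5 * (1.0 - expo) * C
            L = np.maximum(E.mean(axis=0), _LL_FLOOR)
            dE = (rates * expo) * C
            d2E = (-2.0 * rates * rates * expo) * C
            g1 = dE.mean(axis=0) / L
            g2 = d2E.mean(axis=0) / L - g1 * g1
            return float(np.log(L).sum()), float(g1.sum()), float(g2.sum())

        return ll, ll_grad

    def optimize_edge(self, node) -> float:
        """Safeguarded Newton maximization of one branch length."""
        ll, ll_grad = self.edge_ll_function(node)
        lo, hi = self.bl_bounds
        t = min(max(node.length, lo), hi)
        f0, g1, g2 = ll_grad(t)
        best_t, best_f = t, f0
        bracket_lo, bracket_hi = lo, hi
        for _ in range(20):
            if g1 > 0:
                bracket_lo = t
            else:
                bracket_hi = t
            if g2 < 0:
                step = -g1 / g2
                t_new = t + step
            else:
                t_new = 0.5 * (bracket_lo + bracket_hi)
            if not bracket_lo <= t_new <= bracket_hi:
                t_new = 0.5 * (bracket_lo + bracket_hi)
            if abs(t_new - t) < 1e-8:
                break
            t = t_new
            f, g1, g2 = ll_grad(t)
            if f > best_f:
                best_t, best_f = t, f
            if abs(g1) < 1e-10:
                break
        # also probe the lower bound: zero-length edges are common
        f_lo = ll(lo)
        if f_lo > best_f:
            best_t, best_f = lo, f_lo
        node.length = float(best_t)
        return best_f

    def ll_and_gradient(self):
        """Log-likelihood and its gradient in every branch length at once.

        One down pass and one up pass give, for each edge, the inside and
        outside conditional likelihoods; the derivative of the per-column
        change probability then yields the full gradient analytically.
        """
        self.downpass()
        self.uppass()
        edges = [n for n in self.tree.preorder() if n.parent is not None]
        L = np.maximum(self._column_likelihoods().mean(axis=0), _LL_FLOOR)
        ll = float(np.log(L).sum())
        k = len(self.rates)
        shape = (k, self.ncol, 2)
        Us = np.stack([np.broadcast_to(self.U[id(n)], shape) for n in edges])
        Ds = np.stack([np.broadcast_to(self.D[id(n)], shape) for n in edges])
        ts = np.array([n.length for n in edges])
        C = (Us * Ds[..., ::-1]).sum(axis=-1) - (Us * Ds).sum(axis=-1)  # (E,k,ncol)
        rates = self.rates[None, :, None]
        expo = np.exp(-2.0 * rates * ts[:, None, None])
        grad = ((rates * expo * C).mean(axis=1) / L).sum(axis=-1)
        return ll, grad, edges

    def polish(self, maxiter: int = 30) -> float:
        """Joint quasi-Newton refinement of all branch lengths (keep-best)."""
        edges = [n for n in self.tree.preorder() if n.parent is not None]
        x0 = np.array([n.length for n in edges])

        def neg(x):
            for n, t in zip(edges, x):
                n.length = float(t)
            ll, grad, _ = self.ll_and_gradient()
            return -ll, -grad

        res = _opt.minimize(
            neg, x0, jac=True, method="L-BFGS-B",
            bounds=[self.bl_bounds] * len(edges),
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if -res.fun >= -neg(x0)[0]:
            for n, t in zip(edges, res.x):
                n.length = float(t)
            return float(-res.fun)
        for n, t in zip(edges, x0):
            n.length = float(t)
        return float(-neg(x0)[0])

    def sweep(self, exact: bool) -> None:
        """One coordinate sweep over all edges.

        Non-exact: one down/up pass, then every edge optimized against those
        (stale-after-the-first-update) partials. Exact: partials recomputed
        before each edge, so every step is a true coordinate ascent.
        """
        edges = [n for n in self.tree.preorder() if n.parent is not None]
        if not exact:
            self.downpass()
            self.uppass()
            for node in edges:
                self.optimize_edge(node)
        else:
            for node in edges:
                self.downpass()
                self.uppass()
                self.optimize_edge(node)


def _engine(tree, matrix, gamma, bl_bounds=(1e-8, 20.0)):
    rates = gamma.rates if isinstance(gamma, GammaRates) else np.asarray(gamma, float)
    return _Engine(tree, matrix, rates, bl_bounds)


# ---------------------------------------------------------------------- #
# public scoring
# ---------------------------------------------------------------------- #
def _column_matrix(tree: Tree, column: dict) -> CharacterMatrix:
    code = {0: ZERO, 1: ONE, "0": ZERO, "1": ONE, "?": MISSING, None: MISSING}
    taxa = sorted(tree.leaf_labels)
    data = np.full((len(taxa), 1), MISSING, dtype=np.uint8)
    for i, t in enumerate(taxa):
        if t in column:
            data[i, 0] = code[column[t]]
    return CharacterMatrix(taxa=taxa, data=data)


def site_log_likelihood(tree: Tree, column: dict, model: S2Model | None = None,
                        rate: float = 1.0) -> float:
    """Log-likelihood of a single column at one relative rate.

    Branch lengths must be set; '?' leaves contribute a flat partial; the
    value is invariant to the traversal anchor.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    eng = _Engine(tree, _column_matrix(tree, column), np.array([rate]))
    return eng.full_ll()


def tree_log_likelihood(tree: Tree, matrix: CharacterMatrix, gamma: GammaRates) -> float:
    """Sum over columns of the log discrete-gamma mixture likelihood."""
    return _engine(tree, matrix, gamma).full_ll()


def with_branch_lengths(tree: Tree, default: float = 0.1) -> Tree:
    """A copy of ``tree`` with missing branch lengths set to ``default``."""
    out = tree.copy()
    for node in out.preorder():
        if node.parent is not None and node.length is None:
            node.length = default
    return out


def optimize_branch_lengths(tree: Tree, matrix: CharacterMatrix, gamma: GammaRates,
                            tolerance: float = 1e-6, max_sweeps: int = 20,
                            bl_bounds=(1e-8, 20.0), polish: bool = True):
    """Branch-length optimization on a fixed topology.

    Cheap coordinate sweeps (one edge at a time against its inside/outside
    partials) warm-start a joint quasi-Newton polish with the analytic
    gradient, which handles the strongly coupled ridges coordinate ascent
    converges into slowly. Returns ``(tree_with_lengths, log_likelihood)``;
    the log-likelihood never decreases (every stage keeps the better state).
    """
    work = with_branch_lengths(tree)
    eng = _engine(work, matrix, gamma, bl_bounds)
    prev = eng.full_ll()
    edges = [n for n in work.preorder() if n.parent is not None]
    for _ in range(max_sweeps):
        saved = [n.length for n in edges]
        eng.sweep(exact=False)
        new = eng.full_ll()
        if new < prev:
            for n, t in zip(edges, saved):
                n.length = t
            eng.sweep(exact=True)
            new = eng.full_ll()
            if new < prev:  # numerically stuck: keep the better state
                for n, t in zip(edges, saved):
                    n.length = t
                new = prev
        if new - prev < tolerance:
            prev = max(prev, new)
            break
        prev = new
    if polish:
        prev = max(prev, eng.polish())
    return work, prev


def optimize_alpha(tree: Tree, matrix: CharacterMatrix, k: int = 4,
                   bounds=(0.02, 100.0)):
    """Maximize the mixture likelihood over the gamma shape (log scale).

    Returns ``(GammaRates, log_likelihood, at_bound)``; branch lengths are
    taken from the tree as given.
    """
    if k == 1:
        gamma = GammaRates.equal()
        return gamma, tree_log_likelihood(tree, matrix, gamma), False
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    eng = _engine(tree, matrix, GammaRates(1.0, k))

    def neg(log_a):
        eng.set_rates(_discrete_gamma_rates(math.exp(log_a), k))
        return -eng.full_ll()

    res = _opt.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                               options={"xatol": 1e-2, "maxiter": 25})
    alpha = math.exp(res.x)
    at_bound = alpha < bounds[0] * 1.05 or alpha > bounds[1] * 0.95
    gamma = GammaRates(alpha, k)
    return gamma, -res.fun, at_bound


def _fit_lengths_and_alpha(tree, matrix, k, rounds=1, sweeps=2, tolerance=1e-4,
                           bl_bounds=(1e-8, 20.0), alpha_bounds=(0.02, 100.0),
                           extra_polish_inits=()):
    """Alternate branch-length and shape optimization on a fixed topology.

    The protocol is (lengths, shape) x rounds followed by one final length
    pass under the fitted shape. ``extra_polish_inits`` adds joint polishes
    from flat alternative length initializations — on data-poor matrices the
    length surface can be multimodal, and a second basin occasionally beats
    the warm-started one.
    """
    work = with_branch_lengths(tree)
    gamma = GammaRates(1.0, k)
    at_bound = False
    for _ in range(rounds):
        work, _ll = optimize_branch_lengths(work, matrix, gamma,
                                            tolerance=tolerance,
                                            max_sweeps=sweeps, bl_bounds=bl_bounds,
                                            polish=False)
        gamma, _ll, at_bound = optimize_alpha(work, matrix, k=k, bounds=alpha_bounds)
    work, ll = optimize_branch_lengths(work, matrix, gamma, tolerance=tolerance,
                                       max_sweeps=1, bl_bounds=bl_bounds)
    for init in extra_polish_inits:
        alt = work.copy()
        for node in alt.preorder():
            if node.parent is not None:
                node.length = init
        ll_alt = _engine(alt, matrix, gamma, bl_bounds).polish(maxiter=40)
        if ll_alt > ll:
            gamma, _ll, at_bound = optimize_alpha(alt, matrix, k=k, bounds=alpha_bounds)
            work, ll = optimize_branch_lengths(alt, matrix, gamma,
                                               tolerance=tolerance,
                                               max_sweeps=1, bl_bounds=bl_bounds)
    return work, gamma, ll, at_bound


def mrl_score(tree: Tree, matrix: CharacterMatrix, categories: int = 4,
              return_report: bool = False):
    """The MRL score of a topology: its gamma-mixture log-likelihood after
    optimizing branch lengths and the gamma shape on the fixed topology.

    Non-binary trees are scored as-is (pruning handles polytomies); the
    report flags them.
    """
    work, gamma, ll, at_bound = _fit_lengths_and_alpha(tree, matrix, categories)
    if return_report:
        notes = []
        if not tree.is_binary():
            notes.append("scored with polytomies")
        if at_bound:
            notes.append("alpha at bound")
        report = ScoreReport(
            log_likelihood=ll, alpha=gamma.alpha, ncol=matrix.ncol,
            ntax=matrix.ntax, notes=notes,
        )
        return ll, report
    return ll


# ---------------------------------------------------------------------- #
# ML tree search
# ---------------------------------------------------------------------- #
def ml_search(matrix: CharacterMatrix, config: MLSearchConfig | None = None,
              start_tree: Tree | None = None):
    """NNI hill climbing under the S2+gamma criterion.

    Starts from the MP tree (default) or a random topology; neighbors are
    screened at current branch lengths, the most promising ones are fully
    re-optimized, and a move is accepted only if the optimized likelihood
    improves. Returns ``(tree, ScoreReport)``.
    """
    config = config or MLSearchConfig()
    if matrix.ntax < 4:
        raise ValueError("ML search needs >= 4 taxa")
    rng = random.Random(config.seed * 1000003 + 17)
    if config.start == "given":
        if start_tree is None:
            raise ValueError("start='given' requires start_tree")
        current = start_tree.copy()
    elif config.start == "random":
        from .trees import Node

        root = Node()
        labels = sorted(set(matrix.taxa))
        for lb in labels:
            root.add(Node(lb))
        current = random_refinement(Tree(root), rng)
    else:  # mp
        trees, _ = mp_search(
            matrix, MPSearchConfig(n_starts=2, moves=("nni", "spr"), seed=config.seed)
        )
        current = trees[0]
    if not current.is_binary():
        current = random_refinement(current, rng)

    def fit(tree):
        return _fit_lengths_and_alpha(
            tree, matrix, config.categories, rounds=config.fit_rounds,
            sweeps=config.fit_sweeps, bl_bounds=config.bl_bounds,
            alpha_bounds=config.alpha_bounds, extra_polish_inits=(0.3,),
        )

    current, gamma, cur_ll, _ = fit(current)
    for _ in range(config.max_rounds):
        scored = []
        for cand in _nni_neighbors(current):
            cand = with_branch_lengths(cand)
            raw = _engine(cand, matrix, gamma, config.bl_bounds).full_ll(
                per_site_max=config.per_site_categories
            )
            scored.append((raw, cand))
        scored.sort(key=lambda pair: -pair[0])
        accepted = False
        for raw, cand in scored[: config.n_candidates]:
            opt_tree, opt_gamma, opt_ll, _ = fit(cand)
            if opt_ll > cur_ll + config.tolerance:
                current, gamma, cur_ll = opt_tree, opt_gamma, opt_ll
                accepted = True
                break
        if not accepted:
            break
    report = ScoreReport(
        log_likelihood=cur_ll, alpha=gamma.alpha, ncol=matrix.ncol,
        ntax=matrix.ntax,
    )
    return current, report
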