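# Methods

This package estimates supertrees: given a *profile* of unrooted source
trees on overlapping taxon subsets, it builds a tree on the union of all
taxa. It implements the two matrix-based optimality criteria (MRP and MRL),
the strict consensus merger (SCM), the SuperFine divide-and-conquer
refinement of the SCM tree, the standard topological error metrics, and a
synthetic profile generator shaped like the clade-plus-scaffold simulation
designs used to benchmark these methods.

## Matrix encoding

Each internal edge of each source tree becomes one column over {0,1,?}
(Baum–Ragan coding): 1 for the taxa on one side of the edge, 0 for the
other side, ? for taxa absent from that tree. Under reversible (equal-cost)
Fitch parsimony the polarity of a column is irrelevant, so it is fixed
deterministically: state 1 goes to the side not containing the
lexicographically smallest taxon of that source tree. Columns are ordered
by source tree, then by a deterministic traversal of the tree's edges.
Matrices are written as relaxed PHYLIP or NEXUS (`datatype=standard`);
`-` is read as an alias of `?` but never written.

## MRP (matrix representation with parsimony)

Column scores are minimum 0↔1 change counts with `?` leaves free. Two
scoring paths exist and are cross-checked against a brute-force
minimization over all internal (and missing-leaf) state assignments:

- a bit-parallel Fitch pass over Python integers (one bit per column),
  exact for binary trees — this drives the search;
- a vectorized Hartigan pass (state-count maximization per node), exact for
  arbitrary multifurcating trees — this is the general `mp_score`.

The search is a standard heuristic: random-addition greedy construction
(insert each taxon on the edge minimizing the score), then hill climbing
under NNI and SPR with strict-improvement acceptance and deterministic
tie-breaking, with an optional parsimony-ratchet perturbation (temporarily
double the weight of a random fraction of columns, re-search, restore).
Equally-best topologies encountered are retained (deduplicated by canonical
bipartition sets, capped at `max_trees`, default 100) and combined by
greedy consensus, mirroring how MP analyses are summarized in practice. The
search is a faithful stand-in for large-scale parsimony programs, not a
reimplementation of any of them; `seed` fixes the entire trajectory.

## MRL (matrix representation with likelihood)

The same matrix is scored under the symmetric two-state model (CFN):
states {0,1}, stationary frequencies (½,½), branch lengths in expected
substitutions per site, change probability (1 − e^(−2rt))/2 across a branch
of length t at relative rate r. Rate heterogeneity uses Yang's discrete
gamma: k equal-probability categories (default k = 4, a convention exposed
as a flag) represented by their within-category means, with the shape α
optimized on a log scale within [0.02, 100]. `?` cells contribute a flat
(1,1) tip partial. Likelihoods come from Felsenstein pruning vectorized
over columns and categories; partials are kept in linear space (safe for
the few-hundred-taxon scale this package targets — beyond ~1000 nodes
per-node rescaling would be needed, a known limitation).

Branch lengths on a fixed topology are optimized in two stages: cheap
coordinate passes, where each edge is optimized by safeguarded Newton
against its inside/outside conditional likelihoods, then a joint L-BFGS-B
polish using the analytic gradient in all lengths at once. The polish
matters: on data-poor matrices the length surface is strongly coupled and
can be multimodal, and coordinate ascent alone stalls measurably short of
the optimum. The fit protocol used by the tree search adds one extra
polish from a flat 0.3 initialization to escape the occasional bad basin.
Every stage keeps the better of (previous, new) state, so the reported
log-likelihood never decreases.

The **MRL score** of any topology — including partially unresolved ones,
which are scored as-is — is its mixture log-likelihood after optimizing
lengths and α on that fixed topology; this is the single scoring protocol
applied to every method's output tree. The ML *search* is NNI hill
climbing: neighbors are screened at current lengths, the most promising
few are fully re-fitted, and a move is accepted only when it improves the
fitted log-likelihood by more than a tolerance (default 10⁻³, the
observed noise floor of the fit protocol — chasing smaller differences
means chasing optimizer noise). A per-site best-category scoring mode
exists as an optional screening speedup; reported scores always use the
full gamma mixture.

## Strict consensus merger

Trees are merged pairwise, always picking the pair of current trees with
the largest shared-taxon count (ties: larger resulting union, then lowest
original index). One merge: restrict both trees to the shared taxa X, take
the strict consensus of the restrictions as the backbone, then re-attach
each maximal subtree of tree-exclusive taxa at the backbone image of its
attachment point. The attachment point is located by the position of the
subtree in its own tree relative to X: either a surviving node of the
restriction, or a point on a suppressed path, which maps to a backbone
edge. Edges contracted by the strict consensus map their attachments to
the merged node.

Collision semantics (a committed interpretation, since the operation is
folklore): a *collision* is a backbone **edge** receiving exclusive
subtrees from both trees; it is resolved by contracting that edge and
attaching all involved subtrees at the resulting polytomy. Attachments
meeting at the same backbone **node** are not collisions. On a pendant
edge (which cannot be contracted) the colliding subtrees join a single new
attachment node instead. Attachments from a single tree along one edge are
re-inserted as a path in their original order. Minimum accepted overlap is
2 shared taxa (legal but topology-free).

A note on what SCM can and cannot guarantee: merging restrictions of a
single model tree never *conflicts* with any source tree, and under the
clade-plus-full-scaffold design it recovers the model exactly. But two
exclusive leaves attached at the same node legitimately merge into a
cherry that some other common supertree of the sources does not contain,
so "false positives" measured against one particular common refinement
need not be exactly zero for arbitrary compatible inputs — only low, which
is SCM's characteristic error profile (high FN, low FP).

## SuperFine

Each polytomy v (degree d ≥ 4) of the SCM tree defines a partition of the
taxa into the d components of SCM − v. Components are numbered canonically
(by smallest member), every leaf of every source tree is relabeled by its
component, and same-label sibling leaves are collapsed until each label
occurs at most once per tree (trees retaining < 4 distinct labels are
dropped). The base method — MRP (greedy consensus of the equally-best
trees) or MRL — run on these label-reduced trees yields a resolution of
the polytomy, which is grafted back; labels absent from every reduced tree
stay attached at the polytomy's center. Because each refinement depends
only on the partition and the source trees, polytomies are independent and
the processing order cannot affect the output; per-polytomy RNG streams
are derived from the global seed and a digest of the partition so this
holds even with stochastic base searches. The canonical component
numbering is what makes base-method tie-breaking orientation-independent.

## Metrics

FN (missing branch) rate = percent of the reference tree's internal edges
absent from the estimate; FP rate = percent of the estimate's internal
edges absent from the reference; RF distance = size of the bipartition
symmetric difference. For binary pairs FN = FP; against a binary reference
FP ≤ FN always. Sum-FN = percent of source-tree internal edges missing
from the supertree restricted to each source's taxa (equal to half the
summed RF, relative to total source edges, when everything is binary).
Reports carry the raw edge counts so partially resolved trees remain
auditable.

p-ECR moves (contract p uniformly chosen internal edges, then randomly
refine) generate tree neighborhoods for the correlation protocol: for each
input supertree, 100 neighbors with p uniform on [0, ⌈0.25·(number of its
internal edges)⌉]; the originals and neighbors are scored with the MP
score, the MRL score and Sum-FN, and each score's Spearman rank
correlation (average ranks on ties, via scipy) with the FN rate is
reported. MRL scores are negated before correlating so that, like the
other two scores, larger means worse. Non-binary input supertrees are
randomly refined (seeded) first so rates are comparable;
`keep_polytomies=True` disables this. Polytomy resolution in
`random_refinement` proceeds by repeatedly joining two random neighbor
subtrees — it reaches every resolution but not uniformly, which is
adequate for generating diverse neighborhoods.

## Synthetic profiles

A binary model tree on n taxa grows by splitting a uniformly chosen
pendant edge (Yule-type), with i.i.d. exponential branch lengths of mean
0.1 substitutions/site. A profile holds `n_clade_trees` clade trees — the
model restricted to *all* taxa of a random edge-delimited group whose size
falls in `clade_size_range` — plus one scaffold tree: the model restricted
to ⌈density·n⌉ uniformly sampled taxa. Estimation error is optional:

- `characters`: simulate m binary sites (default 250) on the source tree
  under the CFN process and re-estimate its topology by the MP heuristic,
  so error arises from finite data;
- `nni`: apply a Poisson(rate·(n−3)) number of random NNI moves.

Profiles whose overlap structure cannot support a full merger are redrawn
with a perturbed seed, mirroring how benchmark studies exclude replicates
with insufficient taxonomic overlap; `ensure_connected=False` keeps the
draw and warns instead.

What the generator does and does not emulate: it reproduces the *missing
data structure* (dense clades plus a sparse scaffold) and
density-controlled difficulty of the benchmark designs, but not DNA-level
evolution — sources are perturbed via binary characters or NNI moves, not
via sequence alignments. Two consequences matter for interpreting tests.
First, at mean branch length 0.1 two-state characters are partially
saturated, so MP re-estimation of source trees has a positive error floor
(it is exactly consistent only in a shorter-branch regime, which the tests
exercise separately at mean 0.02); absolute error rates are therefore much
higher than in DNA-based studies, and only *relative* method behavior and
trends are meaningful. Second, at small n the clades must span a larger
fraction of the taxa than in a 500-taxon study or sparse scaffolds cannot
connect the profile at all; the scaled study design used throughout the
tests and the acceptance script is n = 32, 6 clade trees of 8–16 taxa,
scaffold densities {0.2, 0.5, 1.0}, 250 sites of character error.

## Numerical and design choices

- Bipartitions are stored canonically as the side excluding the smallest
  taxon of the universe; all tree comparisons, consensus operations and
  deduplications run on these canonical sets.
- Branch-length bounds [10⁻⁸, 20]; per-edge Newton stops at |Δt| < 10⁻⁸;
  the α optimizer uses bounded Brent with xatol 5·10⁻³ on the log scale
  (α precision far below anything the scores are sensitive to).
- Greedy-consensus frequency ties break by lexicographic order of the
  canonical side; MP neighbor ties break by enumeration order — all
  outputs are deterministic given the seed.
- Degenerate inputs: columns with fewer than two observed states score 0
  under parsimony and contribute log 1 = 0 to the likelihood; all-missing
  matrix rows are dropped from the MP search with a warning; source trees
  with < 4 leaves are rejected at profile load.
- The SuperFine reduction's ≤-one-leaf-per-label property is guaranteed
  for SCM-derived labelings; a defensive fallback prunes (with a warning)
  duplicate labels that heavily conflicting hand-built inputs can leave.

## Known limitations

- No per-node likelihood rescaling: reliable to a few hundred taxa.
- The MP search retains at most `max_trees` equally-best trees; the greedy
  consensus can therefore be built from an incomplete sample of the
  optimum set on very flat landscapes.
- MRL scoring of very small matrices inherits the multimodality of the
  length surface; the multistart polish reduces but cannot eliminate the
  risk of a local basin.
- The SCM collision rule is one reasonable reading of an under-specified
  operation; alternatives (e.g., order-preserving merges on collision
  edges) would give different, equally defensible trees.
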