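"""End-to-end simulation study: generate profiles, run every method, score.

This is the scaled-down analogue of the published simulation design: for
each scaffold density and replicate, a clade + scaffold profile is drawn,
all supertree methods are run (MRP, MRL, SCM, SuperFine+MRP,
SuperFine+MRL), and FN/FP rates are measured against the model tree
restricted to the profile's taxa.
"""

from __future__ import annotations

import pandas as pd

from .consensus import greedy_consensus
from .encoding import encode_baum_ragan
from .likelihood import MLSearchConfig, ml_search
from .metrics import error_report
from .parsimony import MPSearchConfig, mp_search
from .scm import resolution, scm_tree
from .superfine import superfine
from .synthetic import SimDesign, make_profile
from .trees import restrict

__all__ = ["estimate_all", "density_study"]

METHODS = ("mrp", "mrl", "scm", "superfine_mrp", "superfine_mrl")


def estimate_all(profile, seed: int = 0, methods=METHODS,
                 mp_config: MPSearchConfig | None = None,
                 ml_config: MLSearchConfig | None = None) -> dict:
    """Run the requested supertree methods on one profile."""
    mp_config = mp_config or MPSearchConfig(n_starts=3, ratchet_rounds=1, seed=seed)
    ml_config = ml_config or MLSearchConfig(seed=seed)
    matrix = encode_baum_ragan(profile)
    out = {}
    if "mrp" in methods:
        trees, _ = mp_search(matrix, mp_config)
        out["mrp"] = greedy_consensus(trees)
    if "mrl" in methods:
        tree, _ = ml_search(matrix, ml_config)
        out["mrl"] = tree
    if "scm" in methods or "superfine_mrp" in methods or "superfine_mrl" in methods:
        scm, _ = scm_tree(profile)
        if "scm" in methods:
            out["scm"] = scm
    if "superfine_mrp" in methods:
        tree, _ = superfine(profile, base="mrp", config=mp_config, seed=seed)
        out["superfine_mrp"] = tree
    if "superfine_mrl" in methods:
        tree, _ = superfine(profile, base="mrl", config=ml_config, seed=seed)
        out["superfine_mrl"] = tree
    return out


def density_study(n_taxa: int = 32, n_clade_trees: int = 6,
                  densities=(0.2, 0.5, 1.0), replicates: int = 3,
                  error_mode: str = "characters", error_sites: int = 250,
                  clade_size_range=None, seed: int = 0,
                  methods=METHODS) -> pd.DataFrame:
    """FN/FP of every method across scaffold densities and replicates.

    At small problem sizes the clades must span a larger fraction of the
    taxa than in a large study, or sparse scaffolds cannot connect the
    profile; the default uses n/4 .. n/2.
    """
    if clade_size_range is None:
        clade_size_range = (max(4, n_taxa // 4), max(5, n_taxa // 2))
    rows = []
    for density in densities:
        for rep in range(replicates):
            design = SimDesign(
                n_taxa=n_taxa, n_clade_trees=n_clade_trees,
                scaffold_density=density, error_mode=error_mode,
                error_sites=error_sites, clade_size_range=clade_size_range,
                seed=seed * 10007 + rep * 101 + int(density * 1000),
            )
            profile, model = make_profile(design)
            truth = restrict(model, profile.taxa)
            estimates = estimate_all(profile, seed=design.seed, methods=methods)
            for method, tree in estimates.items():
                rep_metrics = error_report(truth, tree)
                rows.append(
                    {
                        "method": method,
                        "density": density,
                        "replicate": rep,
                        "fn": rep_metrics.fn,
                        "fp": rep_metrics.fp,
                        "rf": rep_metrics.rf,
                        "resolution": resolution(tree),
                        "n_taxa": tree.n_leaves,
                    }
                )
    return pd.DataFrame(rows)
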