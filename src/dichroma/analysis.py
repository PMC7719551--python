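"""End-to-end fitting helpers: centroid table -> per-sex ridge fits -> stats.

These are the library-level entry points shared by the permutation study,
the pipeline runner, and the acceptance checks. The two sexes are fitted
independently on the same tree but share one cross-validated ridge penalty
(rate magnitudes are compared between the sexes, so both fits must be
shrunk equally), then combined by :mod:`dichroma.dynamics`.
"""

from __future__ import annotations

import pandas as pd

from .color import centroid_matrix
from .dynamics import decompose
from .ridge import RidgeFit, RidgeSolver
from .trees import as_tree_index

__all__ = ["fit_sexes", "analyze_dataset"]


def fit_sexes(
    tree,
    centroids: pd.DataFrame,
    penalty: float | None = None,
    solver: RidgeSolver | None = None,
) -> tuple[RidgeFit, RidgeFit]:
    """Fit the phylogenetic ridge regression for each sex.

    Parameters
    ----------
    tree
        Tree / Newick / TreeIndex; ignored if ``solver`` is given.
    centroids
        Long table (species_id, sex, L, a, b) with both sexes per species.
    penalty
        Fixed ridge lambda for both sexes; if None, one shared lambda is
        selected by minimizing the summed leave-one-out CV error of the
        two sexes.
    solver
        Optional precomputed :class:`RidgeSolver` (the design SVD depends
        only on the tree, so one solver serves all permutation replicates).
    """
    if solver is None:
        solver = RidgeSolver(as_tree_index(tree))
    idx = solver.index
    ys = {sex: idx.align_traits(centroid_matrix(centroids, sex)) for sex in ("male", "female")}
    if penalty is None:
        # one lambda for both sexes (joint CV): rate magnitudes are only
        # comparable between fits shrunk by the same amount
        penalty = solver.select_penalty(list(ys.values()))
    fit_m = solver.fit(ys["male"], penalty=penalty)
    fit_f = solver.fit(ys["female"], penalty=penalty)
    return fit_m, fit_f


def analyze_dataset(
    tree,
    centroids: pd.DataFrame,
    tips_only: bool = False,
    penalty: float | None = None,
    solver: RidgeSolver | None = None,
):
    """Run the full decomposition on one dataset.

    Returns ``(table, summary, fits)``: the per-branch contribution table,
    the summary statistics dict (rate_ratio, ratio_slope, male_slope,
    female_slope, ...), and the pair of per-sex ridge fits.
    """
    fit_m, fit_f = fit_sexes(tree, centroids, penalty=penalty, solver=solver)
    table, summary = decompose(fit_m, fit_f, tips_only=tips_only)
    return table, summary, (fit_m, fit_f)
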