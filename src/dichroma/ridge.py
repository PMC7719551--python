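"""Phylogenetic ridge regression: per-branch rate vectors and ancestral states.

Tip traits are modelled as the root state plus the sum, along the root-to-tip
path, of branch length times a branch-specific rate. Writing X for the
(tips x branches) path-length design matrix, the per-axis rates beta minimize

    || y - (mu * 1 + X beta) ||^2 + lambda * ||beta||^2,

with the root state mu unpenalized. Because every tree has more branches than
tips the unpenalized system is singular; the ridge penalty lambda > 0 both
identifies the rates and shrinks their variance across branches, which is
what makes branch-wise rate estimation tractable. One lambda is shared across
the trait axes (for CIELAB colors the axes share a perceptual unit, so a
common penalty keeps the 3-D rate vector geometrically meaningful); it is
chosen by exact leave-one-out cross-validation over tip values unless given.

Ancestral node states are obtained by accumulating rate x length from the
root down, so the reconstruction is path-consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import TreeIndex, as_tree_index

__all__ = ["RidgeFit", "RidgeSolver", "fit_rrphylo", "select_penalty"]

# singular values below this (relative to the largest) are treated as zero
_RANK_RTOL = 1e-12


@dataclass
class RidgeFit:
    """Result of one phylogenetic ridge regression (one sex, k trait axes).

    Attributes
    ----------
    root_state : ndarray (k,)
        Estimated trait value at the root.
    branch_rates : ndarray (n_branches, k)
        Rate vector on each branch, in trait units per Myr, canonical
        branch order of the TreeIndex.
    node_states : ndarray (n_nodes, k)
        Ancestral (and fitted tip) states at every node, preorder.
    penalty : float
        Ridge tuning value lambda actually used.
    """

    index: TreeIndex
    root_state: np.ndarray
    branch_rates: np.ndarray
    node_states: np.ndarray
    penalty: float

    def tip_states(self) -> np.ndarray:
        """Fitted trait values at the tips, in ``index.tip_labels`` order."""
        rows = [self.index.node_row(lab) for lab in self.index.tip_labels]
        return self.node_states[rows]

    def node_frame(self, columns=("L", "a", "b")) -> pd.DataFrame:
        cols = list(columns)[: self.node_states.shape[1]]
        df = pd.DataFrame(self.node_states, columns=cols)
        df.insert(0, "node_id", self.index.node_ids)
        return df

    def branch_frame(self, columns=("L", "a", "b")) -> pd.DataFrame:
        cols = [f"rate_{c}" for c in list(columns)[: self.branch_rates.shape[1]]]
        df = pd.DataFrame(self.branch_rates, columns=cols)
        df.insert(0, "branch_id", self.index.branch_ids)
        df.insert(1, "parent", self.index.branch_parent_ids)
        df.insert(2, "child", self.index.branch_ids)
        df.insert(3, "length", self.index.branch_lengths)
        return df


class RidgeSolver:
    """Reusable ridge machinery for one tree.

    The design matrix depends only on the tree, so its (centered) SVD is
    computed once and shared across sexes, penalty grids, and permutation
    replicates. With the root state unpenalized, the fit is equivalent to
    ridge on column-centered X with centered y, plus mu = ybar - xbar' beta.
    """

    def __init__(self, index: TreeIndex):
        self.index = index
        X = index.design_matrix
        self.n, self.p = X.shape
        self._colmean = X.mean(axis=0)
        Xc = X - self._colmean
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        keep = s > _RANK_RTOL * s[0]
        self._U, self._s, self._Vt = U[:, keep], s[keep], Vt[keep]
        self._U2 = self._U**2

    # -- core linear algebra -------------------------------------------------

    def _prepare(self, y: np.ndarray):
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] != self.n:
            y = y.T
        if y.shape[0] != self.n:
            raise ValueError(f"traits must have {self.n} rows (one per tip)")
        ymean = y.mean(axis=0)
        return y, ymean, self._U.T @ (y - ymean)

    def fit(self, tip_traits, penalty: float | None = None) -> RidgeFit:
        """Fit rates and ancestral states; select the penalty if not given."""
        y, ymean, uty = self._prepare(tip_traits)
        if penalty is None:
            penalty = self.select_penalty(y)
        lam = float(penalty)
        if lam < 0:
            raise ValueError("penalty must be nonnegative")
        if lam == 0 and len(self._s) < self.p:
            raise ValueError(
                "the penalized system is singular at lambda = 0 (a tree always "
                "has more branches than tips); use a penalty > 0"
            )
        shrink = self._s / (self._s**2 + lam)
        beta = self._Vt.T @ (shrink[:, None] * uty)
        root = ymean - self._colmean @ beta
        node_states = root + self.index.node_paths @ beta
        return RidgeFit(self.index, root, beta, node_states, lam)

    def loocv_error(self, tip_traits, penalties) -> np.ndarray:
        """Exact leave-one-out squared prediction error, summed over tips
        and trait axes, for each penalty value.

        Penalties small enough that some leverage reaches 1 put the fit in
        the interpolation regime where leave-one-out prediction is
        undefined; those entries are reported as +inf so selection never
        lands there.
        """
        y, ymean, uty = self._prepare(tip_traits)
        lams = np.atleast_1d(np.asarray(penalties, dtype=float))
        s2 = self._s**2
        errs = np.empty(lams.shape)
        yc = y - ymean
        for i, lam in enumerate(lams):
            f = s2 / (s2 + lam)  # spectral shrinkage factors
            h = 1.0 / self.n + self._U2 @ f  # leverages incl. intercept
            if h.max() > 1.0 - 1e-3:
                errs[i] = np.inf
                continue
            resid = yc - self._U @ (f[:, None] * uty)
            loo = resid / (1.0 - h)[:, None]
            errs[i] = float(np.sum(loo**2))
        return errs

    def penalty_grid(self, n_coarse: int = 31) -> np.ndarray:
        """Deterministic log-spaced grid spanning no-shrinkage to full-shrinkage."""
        s2 = self._s**2
        lo, hi = s2.min() * 1e-4, s2.max() * 1e3
        return np.geomspace(lo, hi, n_coarse)

    def select_penalty(self, tip_traits, n_refine: int = 21) -> float:
        """Penalty minimizing LOO CV error on a coarse grid with one local
        log-scale refinement; deterministic given the inputs.

        ``tip_traits`` may be a list/tuple of trait matrices, in which case
        one penalty is chosen to minimize their summed CV error. This is how
        a common lambda is selected for the two sexes: rate magnitudes are
        only comparable between fits shrunk by the same amount.
        """
        ys = tip_traits if isinstance(tip_traits, (list, tuple)) else [tip_traits]

        def total_error(lams):
            return sum(self.loocv_error(y, lams) for y in ys)

        grid = self.penalty_grid()
        errs = total_error(grid)
        if not np.any(np.isfinite(errs)):
            raise RuntimeError("CV error is non-finite over the whole penalty grid")
        k = int(np.nanargmin(np.where(np.isfinite(errs), errs, np.nan)))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        fine = np.geomspace(lo, hi, n_refine)
        fine_errs = total_error(fine)
        j = int(np.nanargmin(np.where(np.isfinite(fine_errs), fine_errs, np.nan)))
        return float(fine[j])


def fit_rrphylo(tree, tip_traits, penalty: float | None = None) -> RidgeFit:
    """Phylogenetic ridge regression of tip traits on root-to-tip paths.

    Parameters
    ----------
    tree
        A dendropy Tree, Newick string/path, or TreeIndex.
    tip_traits
        (tips x k) array in the index's tip order, or a DataFrame indexed by
        tip label (any order).
    penalty
        Ridge lambda; selected by leave-one-out CV when None.
    """
    index = as_tree_index(tree)
    if index.n_tips < 2:
        raise ValueError("need at least 2 tips")
    y = index.align_traits(tip_traits)
    return RidgeSolver(index).fit(y, penalty=penalty)


def select_penalty(tree, tip_traits) -> float:
    """Leave-one-out cross-validated ridge penalty for this tree and traits."""
    index = as_tree_index(tree)
    y = index.align_traits(tip_traits)
    return RidgeSolver(index).select_penalty(y)
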