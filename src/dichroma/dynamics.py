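"""Decomposition of dichromatism change into male- and female-driven parts.

Given the two sexes' ridge fits on the same tree, each branch carries a male
rate vector m and a female rate vector f (CIELAB units per Myr) and, at its
parent node, an ancestral dichromatism vector D = c_m - c_f. Projecting the
rate vectors on the unit vector Dhat gives the effective rates of
dichromatism change:

    s_m = m . Dhat        (male contribution)
    s_f = -f . Dhat       (female contribution)
    s   = s_m + s_f = (m - f) . Dhat

s is, to first order, the time-derivative of ||D|| along the branch: positive
s means the sexes are diverging in color, negative s that they are
converging. Because D points female -> male, a male moving along D and a
female moving against it both increase dichromatism, hence the sign on s_f.

Headline statistics:

* ``sex_rate_ratio`` -- mean ||m|| over branches divided by mean ||f||; > 1
  means male color evolves faster on average.
* ``ratio_vs_dichromatism`` -- OLS of log(||m||/||f||) on ancestral ||D||; a
  positive slope means rate imbalance grows with dichromatism. The slope
  equals the sex x dichromatism interaction in the stacked regression
  log(rate) ~ dichromatism * sex, since log m - log f = log(m/f).
* ``contribution_slopes`` -- OLS slopes of s_m on s and s_f on s. They sum
  to 1 because s = s_m + s_f row-wise; equal male/female contributions give
  (0.5, 0.5), a Darwinian (male-driven) history pushes the male slope up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ridge import RidgeFit

__all__ = [
    "branch_sex_table",
    "project_contributions",
    "sex_rate_ratio",
    "ratio_vs_dichromatism",
    "contribution_slopes",
    "decompose",
]

#: ancestral ||D|| below this is treated as exactly monochromatic; the
#: projection direction is then undefined and the branch is flagged
DEGENERATE_D = 1e-9

#: rate magnitudes below this are excluded from log-ratio analyses
MIN_LOG_RATE = 1e-12


def project_contributions(m_vec, f_vec, anc_D_vec, eps: float = DEGENERATE_D):
    """Scalar projections (s_m, s_f, s) of the sex rate vectors on the
    ancestral dichromatism direction; vectorized over branches.

    Returns (s_m, s_f, s, degenerate) where ``degenerate`` marks branches
    whose ancestral ||D|| < eps: their projections are set to 0 and they are
    excluded from contribution regressions downstream.
    """
    m = np.atleast_2d(np.asarray(m_vec, dtype=float))
    f = np.atleast_2d(np.asarray(f_vec, dtype=float))
    d = np.atleast_2d(np.asarray(anc_D_vec, dtype=float))
    mag = np.linalg.norm(d, axis=1)
    degenerate = mag < eps
    dhat = np.where(degenerate[:, None], 0.0, d / np.where(degenerate, 1.0, mag)[:, None])
    s_m = np.einsum("ij,ij->i", m, dhat)
    s_f = -np.einsum("ij,ij->i", f, dhat)
    return s_m, s_f, s_m + s_f, degenerate


def branch_sex_table(fit_m: RidgeFit, fit_f: RidgeFit) -> pd.DataFrame:
    """Per-branch table combining the two sexes' fits.

    Columns: branch/parent/child ids, branch length, terminal-branch flag,
    the rate vectors and their magnitudes, the ancestral dichromatism vector
    and magnitude (evaluated at the branch's parent node, i.e. before the
    change along the branch), and the projections s_m, s_f, s.
    """
    if fit_m.index is not fit_f.index and fit_m.index.branch_ids != fit_f.index.branch_ids:
        raise ValueError("male and female fits must share one tree index")
    idx = fit_m.index
    d_nodes = fit_m.node_states - fit_f.node_states  # D at every node
    parent_rows = [idx.node_row(p) for p in idx.branch_parent_ids]
    anc_d = d_nodes[parent_rows]
    s_m, s_f, s, degen = project_contributions(fit_m.branch_rates, fit_f.branch_rates, anc_d)

    tbl = pd.DataFrame(
        {
            "branch_id": idx.branch_ids,
            "parent": idx.branch_parent_ids,
            "child": idx.branch_ids,
            "length": idx.branch_lengths,
            "is_tip": idx.branch_is_tip,
            "m_mag": np.linalg.norm(fit_m.branch_rates, axis=1),
            "f_mag": np.linalg.norm(fit_f.branch_rates, axis=1),
            "anc_D_mag": np.linalg.norm(anc_d, axis=1),
            "s_m": s_m,
            "s_f": s_f,
            "s": s,
            "degenerate_D": degen,
        }
    )
    for j, ax in enumerate(("L", "a", "b")):
        tbl[f"m_{ax}"] = fit_m.branch_rates[:, j]
        tbl[f"f_{ax}"] = fit_f.branch_rates[:, j]
        tbl[f"anc_D_{ax}"] = anc_d[:, j]
    return tbl


def sex_rate_ratio(table: pd.DataFrame) -> float:
    """Ratio of mean male to mean female rate magnitude across branches."""
    if len(table) < 1:
        raise ValueError("need at least one branch")
    mf = float(table["f_mag"].mean())
    if mf == 0:
        raise ValueError("all female rates are zero; the rate ratio is undefined")
    return float(table["m_mag"].mean()) / mf


@dataclass
class RegressionLine:
    """Slope/intercept summary of one OLS fit."""

    slope: float
    intercept: float
    p_value: float
    n_used: int
    n_excluded: int = 0


def _ols_line(x: np.ndarray, y: np.ndarray, n_excluded: int = 0) -> RegressionLine:
    X = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return RegressionLine(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        n_used=len(x),
        n_excluded=n_excluded,
    )


def ratio_vs_dichromatism(table: pd.DataFrame) -> RegressionLine:
    """OLS of log(male rate / female rate) on ancestral dichromatism.

    Branches where either rate magnitude is below ``MIN_LOG_RATE`` are
    excluded (the log-ratio is undefined there); the number excluded is
    recorded on the result.
    """
    ok = (table["m_mag"] > MIN_LOG_RATE) & (table["f_mag"] > MIN_LOG_RATE)
    sub = table[ok]
    if len(sub) < 3:
        raise ValueError("fewer than 3 branches with usable rate magnitudes")
    logratio = np.log(sub["m_mag"].to_numpy() / sub["f_mag"].to_numpy())
    return _ols_line(sub["anc_D_mag"].to_numpy(), logratio, n_excluded=int((~ok).sum()))


def contribution_slopes(table: pd.DataFrame) -> tuple[RegressionLine, RegressionLine]:
    """OLS slopes of s_m on s (male) and s_f on s (female).

    Branches flagged degenerate (monochromatic ancestor) are excluded. The
    two slopes sum to exactly 1 because s = s_m + s_f on every row.
    """
    sub = table[~table["degenerate_D"]]
    if len(sub) < 3:
        raise ValueError("fewer than 3 non-degenerate branches for contribution slopes")
    s = sub["s"].to_numpy()
    if np.var(s) == 0:
        raise ValueError("s has zero variance; contribution slopes are undefined")
    male = _ols_line(s, sub["s_m"].to_numpy(), n_excluded=int(table["degenerate_D"].sum()))
    female = _ols_line(s, sub["s_f"].to_numpy(), n_excluded=male.n_excluded)
    return male, female


def decompose(fit_m: RidgeFit, fit_f: RidgeFit, tips_only: bool = False):
    """Full per-branch decomposition plus summary statistics.

    Parameters
    ----------
    fit_m, fit_f
        Ridge fits of the male and female centroids on the same tree.
    tips_only
        Restrict all statistics to terminal branches (per-species reading);
        default uses every branch of the tree.

    Returns
    -------
    (table, summary) : the per-branch DataFrame from
    :func:`branch_sex_table` (possibly restricted) and a dict with keys
    ``rate_ratio``, ``ratio_slope``, ``male_slope``, ``female_slope`` plus
    the full regression lines.
    """
    table = branch_sex_table(fit_m, fit_f)
    if tips_only:
        table = table[table["is_tip"]].reset_index(drop=True)
    ratio = sex_rate_ratio(table)
    line = ratio_vs_dichromatism(table)
    male, female = contribution_slopes(table)
    summary = {
        "rate_ratio": ratio,
        "ratio_slope": line.slope,
        "male_slope": male.slope,
        "female_slope": female.slope,
        "ratio_line": line,
        "male_line": male,
        "female_line": female,
        "n_branches": int(len(table)),
    }
    return table, summary
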