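"""Diagnostic plots for the decomposition results.

Matplotlib renditions of the two standard displays: the male/female rate
ratio against ancestral dichromatism (log-scale y; 1 = equal rates), and
the per-branch contribution scatters s_m ~ s and s_f ~ s, optionally with
permutation-null regression lines in the background.
"""

from __future__ import annotations

import numpy as np

from .dynamics import MIN_LOG_RATE

__all__ = ["plot_ratio_vs_dichromatism", "plot_contributions"]


def _line(ax, slope, intercept, x, **kw):
    xs = np.linspace(float(np.min(x)), float(np.max(x)), 50)
    ax.plot(xs, intercept + slope * xs, **kw)


def plot_ratio_vs_dichromatism(table, line=None, null_lines=(), ax=None):
    """Scatter of log(male/female rate) vs ancestral dichromatism.

    ``line`` is the observed RegressionLine; ``null_lines`` an iterable of
    (slope, intercept) pairs drawn in light gray behind it.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ok = (table["m_mag"] > MIN_LOG_RATE) & (table["f_mag"] > MIN_LOG_RATE)
    x = table.loc[ok, "anc_D_mag"].to_numpy()
    y = np.log(table.loc[ok, "m_mag"].to_numpy() / table.loc[ok, "f_mag"].to_numpy())
    for slope, intercept in null_lines:
        _line(ax, slope, intercept, x, color="0.8", lw=0.5, zorder=1)
    ax.scatter(x, y, s=8, alpha=0.5, zorder=2)
    if line is not None:
        _line(ax, line.slope, line.intercept, x, color="crimson", lw=2, zorder=3)
    ax.axhline(0.0, color="0.3", lw=0.8, ls="--")
    ax.set_xlabel("ancestral dichromatism $\\|\\vec{D}\\|$")
    ax.set_ylabel("log(male rate / female rate)")
    return ax


def plot_contributions(table, male_line=None, female_line=None, null_lines=(), axes=None):
    """Two-panel scatter of s_m and s_f against the net rate s.

    ``null_lines`` is an iterable of (male_slope, male_intercept) pairs;
    the female panel mirrors them as (1 - slope, -intercept) since the two
    slopes sum to 1.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    sub = table[~table["degenerate_D"]]
    s = sub["s"].to_numpy()
    for ax, col, line, mirror in (
        (axes[0], "s_m", male_line, False),
        (axes[1], "s_f", female_line, True),
    ):
        for slope, intercept in null_lines:
            if mirror:
                slope, intercept = 1.0 - slope, -intercept
            _line(ax, slope, intercept, s, color="0.8", lw=0.5, zorder=1)
        ax.scatter(s, sub[col].to_numpy(), s=8, alpha=0.5, zorder=2)
        if line is not None:
            _line(ax, line.slope, line.intercept, s, color="crimson", lw=2, zorder=3)
        _line(ax, 0.5, 0.0, s, color="0.3", lw=0.8, ls="--")
        ax.set_xlabel("net effective rate $s$")
        ax.set_ylabel(f"${col}$")
    return axes
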