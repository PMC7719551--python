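"""Permutation inference by within-species sex-label swapping.

The null hypothesis is that color evolution carries no sex-specific signal:
which centroid is called "male" and which "female" is exchangeable within
each species. The permutation scheme therefore swaps the sex labels of each
species independently with probability 1/2, leaving the phylogeny and the
within-species color pair untouched, and the entire pipeline (including
penalty selection) is re-run on every permuted dataset. Observed statistics
are compared two-tailed against the resulting null draws after re-centering
each statistic at its theoretical null value (1 for rate ratios, on the log
scale; 0 for regression slopes of the log-ratio model; 0.5 for contribution
slopes), with the add-one estimator p = (1 + #extreme) / (R + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import analyze_dataset
from .ridge import RidgeSolver
from .trees import as_tree_index

__all__ = [
    "permute_sexes",
    "permutation_pvalue",
    "run_permutation_study",
    "PermutationResult",
    "STATISTIC_CENTERS",
]

#: statistic name -> (null center, compare on log scale?)
STATISTIC_CENTERS = {
    "rate_ratio": (0.0, True),  # log(ratio) centered at 0
    "ratio_slope": (0.0, False),
    "male_slope": (0.5, False),
    "female_slope": (0.5, False),
}


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null draws, and the p-value."""

    statistic_name: str
    observed: float
    null_values: np.ndarray = field(repr=False)
    p_two_tailed: float

    @property
    def R(self) -> int:
        return len(self.null_values)

    def null_quantiles(self, qs=(0.025, 0.5, 0.975)) -> dict:
        return {f"q{q}": float(np.quantile(self.null_values, q)) for q in qs}


def permute_sexes(centroids: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Swap the sex labels of each species independently with probability 1/2.

    Requires exactly one male and one female row per species; returns a new
    table with the same rows and species but with the 'sex' values of the
    swapped species exchanged.
    """
    counts = centroids.groupby(["species_id", "sex"]).size().unstack(fill_value=0)
    for sex in ("male", "female"):
        if sex not in counts.columns or (counts[sex] != 1).any():
            raise ValueError("each species needs exactly one male and one female row")
    rng = np.random.default_rng(seed)
    species = counts.index.to_numpy()
    swap = rng.random(len(species)) < 0.5
    swapped = set(species[swap])
    out = centroids.copy()
    flip = {"male": "female", "female": "male"}
    mask = out["species_id"].isin(swapped)
    out.loc[mask, "sex"] = out.loc[mask, "sex"].map(flip)
    return out


def permutation_pvalue(
    observed: float,
    null_values,
    center: float = 0.0,
    log_scale: bool = False,
) -> float:
    """Two-tailed permutation p-value with add-one correction.

    The statistic is re-centered at its theoretical null value (optionally
    after a log transform, appropriate for ratios whose null is 1) and
    extremeness is measured by absolute deviation from that center:
    p = (1 + #{|null - c| >= |obs - c|}) / (R + 1). Always in (0, 1].
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    obs = float(observed)
    if log_scale:
        obs, null = np.log(obs), np.log(null)
    extreme = np.abs(null - center) >= np.abs(obs - center) - 1e-12
    return float((1 + int(extreme.sum())) / (null.size + 1))


def run_permutation_study(
    tree,
    centroids: pd.DataFrame,
    statistics=("rate_ratio", "ratio_slope", "male_slope", "female_slope"),
    R: int = 1000,
    seed=None,
    tips_only: bool = False,
) -> dict[str, PermutationResult]:
    """Observed statistics plus a sex-swap permutation null for each.

    Every replicate re-runs the full pipeline on the permuted table: both
    sexes' ridge regressions are refitted with the penalty re-selected, and
    all requested statistics recomputed. Per-replicate seeds derive
    deterministically from ``seed`` via numpy's SeedSequence spawning, so
    the study is reproducible and replicates are independent.
    """
    unknown = set(statistics) - set(STATISTIC_CENTERS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    if R < 1:
        raise ValueError("R must be >= 1")
    index = as_tree_index(tree)
    solver = RidgeSolver(index)  # tree-only work shared across replicates

    _, observed, _ = analyze_dataset(index, centroids, tips_only=tips_only, solver=solver)

    child_seeds = np.random.SeedSequence(seed).spawn(R)
    null = {name: np.empty(R) for name in statistics}
    for r, ss in enumerate(child_seeds):
        perm = permute_sexes(centroids, seed=ss)
        try:
            _, stats_r, _ = analyze_dataset(index, perm, tips_only=tips_only, solver=solver)
        except Exception as exc:  # propagate with context per replicate
            raise RuntimeError(f"permutation replicate {r} failed: {exc}") from exc
        for name in statistics:
            null[name][r] = stats_r[name]

    results = {}
    for name in statistics:
        center, log_scale = STATISTIC_CENTERS[name]
        results[name] = PermutationResult(
            statistic_name=name,
            observed=float(observed[name]),
            null_values=null[name],
            p_two_tailed=permutation_pvalue(
                observed[name], null[name], center=center, log_scale=log_scale
            ),
        )
    return results
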