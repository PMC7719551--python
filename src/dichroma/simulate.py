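"""Synthetic phylogenies and paired-sex color data with known ground truth.

The generator emulates the structure of a comparative dichromatism dataset:
an ultrametric pure-birth (Yule) phylogeny; male and female CIELAB centroids
evolving by Brownian motion with a large shared component (the sexes'
colors are strongly correlated, as in real butterflies) plus smaller
independent sex-specific components; optional clade-localized directional
displacement of one sex, which is what creates heritable dichromatism; and
a fraction of species that are exactly monochromatic.

Scenarios
---------
* ``darwinian`` -- dichromatism arises because the male is driven away from
  the shared phenotype in some clades (sexual selection on males).
* ``wallacean`` -- the mirror image: the female is driven (natural selection
  for female crypsis). With the same seed it is the Darwinian dataset with
  the sex labels exchanged, exactly.
* ``shared_null`` -- no directional drive; the sexes are exchangeable, so
  any sex-specific signal found downstream is a false positive.
* ``mixed`` -- driven clades alternate between male- and female-driven.

Every per-branch increment is stored, so tests can replay the simulation
from the root and verify tip values exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trees import TreeIndex, as_tree_index, read_tree

__all__ = [
    "ScenarioParams",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_colors",
    "simulate_dataset",
    "SCENARIOS",
]

_AXES = ("L", "a", "b")


@dataclass(frozen=True)
class ScenarioParams:
    """Generator settings; defaults sketch a European-butterfly-like study.

    Rates are per-Myr (the tree is scaled to ``root_age`` Myr); sigma values
    are Brownian step standard deviations per sqrt(Myr) per CIELAB axis.
    ``drive_strength`` is the deterministic displacement, in CIELAB units
    per Myr, applied to the driven sex along one fixed random unit direction
    per driven clade (sustained directional selection toward a new color).
    """

    n_tips: int = 150
    birth_rate: float = 0.1
    root_age: float = 100.0
    root_color: tuple = (50.0, 0.0, 0.0)
    sigma_shared: float = 3.0
    sigma_sex: float = 1.0
    drive: str = "none"  # none | male | female | mixed
    drive_strength: float = 2.0
    driven_clade_fraction: float = 0.3
    mono_fraction: float = 0.15
    seed: int | None = None

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        for name in ("birth_rate", "sigma_shared", "sigma_sex", "drive_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("driven_clade_fraction", "mono_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.drive not in {"none", "male", "female", "mixed"}:
            raise ValueError("drive must be one of none/male/female/mixed")
        if self.drive != "none" and self.drive_strength == 0:
            warnings.warn("drive set but drive_strength is 0; no directional signal")


#: named presets for the four study conditions
SCENARIOS = {
    "darwinian": {"drive": "male"},
    "wallacean": {"drive": "female"},
    "shared_null": {"drive": "none"},
    "mixed": {"drive": "mixed"},
}


def simulate_tree(n_tips: int, birth_rate: float = 0.1, seed=None, root_age: float = 100.0):
    """Ultrametric Yule (pure-birth) tree with ``n_tips`` extant tips.

    Lineages split at rate ``birth_rate`` each; after the n-th lineage
    appears, one further exponential waiting time is added so terminal
    branches are strictly positive. Node times are then rescaled so the
    root sits at ``root_age`` Myr. Tips are labelled s001, s002, ... in
    Newick traversal order; the same seed yields the identical Newick.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    children: dict[int, list] = {0: []}
    time_of = {0: 0.0}
    active = [0]
    # root is node 0 and splits immediately into the first two lineages
    next_id = 1
    t = 0.0
    for nid in (1, 2):
        children[0].append(nid)
        children[nid] = []
        next_id = nid + 1
    active = [1, 2]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        parent = active.pop(int(rng.integers(k)))
        time_of[parent] = t
        for _ in range(2):
            children[parent].append(next_id)
            children[next_id] = []
            active.append(next_id)
            next_id += 1
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for nid in active:
        time_of[nid] = t_end

    scale = root_age / t_end
    label = {"count": 0}

    def newick(nid: int, parent_time: float) -> str:
        bl = (time_of[nid] - parent_time) * scale
        if not children[nid]:
            label["count"] += 1
            return f"s{label['count']:03d}:{bl:.10f}"
        inner = ",".join(newick(c, time_of[nid]) for c in children[nid])
        return f"({inner}):{bl:.10f}" if nid != 0 else f"({inner});"

    return read_tree(newick(0, 0.0))


@dataclass
class SyntheticDataset:
    """One simulated study: tree, per-sex tip centroids, and ground truth.

    ``increments`` holds, per branch, the realized change of each sex
    (columns m_L.. / f_L..) and the shared component; accumulating them from
    ``params.root_color`` down the tree reproduces the tip centroids
    exactly. ``driven_clades`` records (branch_id of the clade stem, driven
    sex, unit direction); ``mono_species`` lists tips forced monochromatic.
    """

    index: TreeIndex
    centroids: pd.DataFrame
    increments: pd.DataFrame
    driven_clades: list
    mono_species: list
    params: ScenarioParams
    scenario: str = ""
    tip_states: dict = field(default_factory=dict, repr=False)

    @property
    def tree(self):
        return self.index.tree

    def centroid_table(self, clip: bool = False) -> pd.DataFrame:
        """Long (species_id, sex, L, a, b) table; ``clip`` restricts values
        to the CIELAB gamut box (L in [0,100], |a|,|b| < 128) for export."""
        df = self.centroids.copy()
        if clip:
            df["L"] = df["L"].clip(0.0, 100.0)
            for c in ("a", "b"):
                df[c] = df[c].clip(-127.999, 127.999)
        return df

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.index.tree.write(path=str(out / "tree.nwk"), schema="newick",
                              suppress_rooting=True)
        self.centroid_table(clip=True).to_csv(out / "centroids.csv", index=False)
        self.increments.to_csv(out / "true_increments.csv", index=False)


def _select_driven_clades(index: TreeIndex, frac: float, drive: str, rng) -> list:
    """Pick disjoint internal clades covering ~frac of the tips; returns
    (branch position, driven sex, unit direction) per clade."""
    X = index.design_matrix
    tip_counts = (X > 0).sum(axis=0)
    n = index.n_tips
    max_size = max(3, n // 3)
    candidates = [
        b for b in range(index.n_branches)
        if not index.branch_is_tip[b] and 3 <= tip_counts[b] <= max_size
    ]
    order = rng.permutation(len(candidates))
    covered = np.zeros(n, dtype=bool)
    target = frac * n
    chosen = []
    for pos in order:
        b = candidates[pos]
        tips_b = X[:, b] > 0
        if np.any(covered & tips_b):
            continue
        covered |= tips_b
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        sex = {"male": "male", "female": "female"}.get(drive)
        if drive == "mixed":
            sex = "male" if len(chosen) % 2 == 0 else "female"
        chosen.append((b, sex, u))
        if covered.sum() >= target:
            break
    return chosen


def simulate_colors(tree, params: ScenarioParams, seed=None) -> SyntheticDataset:
    """Evolve paired-sex CIELAB centroids along the tree under ``params``.

    Each branch receives a shared Brownian increment (applied to both
    sexes), independent per-sex Brownian increments, and -- on branches
    inside a driven clade -- a directional displacement of the driven sex.
    ``mono_fraction`` of the tips then have their sex-specific deviations
    cancelled on the terminal branch so the sexes match exactly (the
    increments table reflects the cancellation, keeping replay exact).

    With the same seed, a ``drive='female'`` run is the ``drive='male'``
    run with the sex labels exchanged, exactly: the driven sex always
    consumes the same random draws.
    """
    index = as_tree_index(tree)
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n, nb = index.n_tips, index.n_branches

    driven = (
        _select_driven_clades(index, params.driven_clade_fraction, params.drive, rng)
        if params.drive != "none" and params.drive_strength > 0
        else []
    )
    # branch -> (sex, direction) for branches inside a driven clade
    drive_of: dict[int, tuple] = {}
    for b, sex, u in driven:
        for b2 in range(nb):
            child_row = index.node_row(index.branch_ids[b2])
            if index.node_paths[child_row, b] > 0:
                drive_of[b2] = (sex, u)

    n_mono = int(round(params.mono_fraction * n))
    mono = sorted(rng.choice(index.tip_labels, size=n_mono, replace=False).tolist()) if n_mono else []

    # state arrays over all nodes (preorder): shared-only and per sex
    n_nodes = len(index.node_ids)
    root = np.asarray(params.root_color, dtype=float)
    shared_state = np.tile(root, (n_nodes, 1))
    state = {"male": shared_state.copy(), "female": shared_state.copy()}
    inc = {"male": np.zeros((nb, 3)), "female": np.zeros((nb, 3))}
    inc_shared = np.zeros((nb, 3))
    # the scenario's driven sex consumes the first per-sex draw on every
    # branch, which makes male- and female-driven runs exact mirrors
    first_sex = params.drive if params.drive in ("male", "female") else "male"
    second_sex = "female" if first_sex == "male" else "male"

    node_row = index.node_row
    for b in range(nb):  # branch order is preorder: parents precede children
        t = index.branch_lengths[b]
        child = node_row(index.branch_ids[b])
        parent = node_row(index.branch_parent_ids[b])
        sq = np.sqrt(t)
        shared = rng.normal(0.0, params.sigma_shared * sq, 3)
        e_first = rng.normal(0.0, params.sigma_sex * sq, 3)
        e_second = rng.normal(0.0, params.sigma_sex * sq, 3)
        inc_shared[b] = shared
        inc[first_sex][b] = shared + e_first
        inc[second_sex][b] = shared + e_second
        if b in drive_of:
            sex, u = drive_of[b]
            inc[sex][b] += params.drive_strength * t * u
        shared_state[child] = shared_state[parent] + shared
        for sex in ("male", "female"):
            state[sex][child] = state[sex][parent] + inc[sex][b]

    # force selected tips exactly monochromatic: both sexes end at the
    # shared-only state, by adjusting the terminal-branch increments
    for lab in mono:
        b = index.branch_ids.index(lab)
        child = node_row(lab)
        parent = node_row(index.branch_parent_ids[b])
        for sex in ("male", "female"):
            inc[sex][b] = shared_state[child] - state[sex][parent]
            state[sex][child] = shared_state[child]

    tip_rows = {lab: node_row(lab) for lab in index.tip_labels}
    records = []
    for lab in index.tip_labels:
        for sex in ("male", "female"):
            L, a, bb = state[sex][tip_rows[lab]]
            records.append({"species_id": lab, "sex": sex, "L": L, "a": a, "b": bb})
    centroids = pd.DataFrame.from_records(records)

    inc_df = pd.DataFrame({
        "branch_id": index.branch_ids,
        "parent": index.branch_parent_ids,
        "length": index.branch_lengths,
        "driven_sex": [drive_of.get(b, ("", None))[0] for b in range(nb)],
    })
    for j, ax in enumerate(_AXES):
        inc_df[f"shared_{ax}"] = inc_shared[:, j]
        inc_df[f"m_{ax}"] = inc["male"][:, j]
        inc_df[f"f_{ax}"] = inc["female"][:, j]

    clades = [(index.branch_ids[b], sex, u) for b, sex, u in driven]
    return SyntheticDataset(
        index=index,
        centroids=centroids,
        increments=inc_df,
        driven_clades=clades,
        mono_species=mono,
        params=params,
        scenario=params.drive,
        tip_states={"male": state["male"], "female": state["female"], "shared": shared_state},
    )


def simulate_dataset(scenario: str = "darwinian", seed=None, **overrides) -> SyntheticDataset:
    """Simulate a tree and colors for a named scenario in one call.

    The master seed is split deterministically into a tree seed and a color
    seed, so the same seed reproduces the whole dataset.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    params = ScenarioParams(**{**SCENARIOS[scenario], **overrides})
    tree_seed, color_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2)
    )
    tree = simulate_tree(params.n_tips, params.birth_rate, seed=tree_seed,
                         root_age=params.root_age)
    ds = simulate_colors(tree, params, seed=color_seed)
    ds.scenario = scenario
    return ds
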