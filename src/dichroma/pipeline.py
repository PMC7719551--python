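"""End-to-end orchestration: images/centroids -> fits -> statistics -> report.

One run analyzes one wing surface (dorsal or ventral): it loads or computes
the per-sex CIELAB centroids, fits the phylogenetic ridge regression for
each sex, decomposes dichromatism change into male/female contributions,
optionally runs the sex-swap permutation test and the Pagel's-lambda signal
estimate, and writes every intermediate plus a JSON report. Dorsal and
ventral analyses are two independent runs over two centroid tables.

Seeds for the stochastic stages (pixel sampling, permutations, bootstrap)
are derived from the master seed by numpy SeedSequence spawning in a fixed
order, so a run is fully determined by its config. The summary report is
byte-identical across reruns; wall-clock timings go to a separate file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import analyze_dataset
from .color import (
    centroid,
    dichromatism_table,
    read_centroid_table,
    sample_pixels,
    write_centroid_table,
)
from .permutation import run_permutation_study
from .signal import pagel_lambda
from .trees import as_tree_index

__all__ = ["RunConfig", "run_full_analysis", "centroids_from_images"]

log = logging.getLogger("dichroma")

_IMAGE_EXTS = {".png", ".jpg", ".jpeg"}


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    tree: str
    centroids: str | None = None  # CSV path; alternative to images
    images: str | None = None  # directory of <species>_<sex>.png files
    surface: str = "dorsal"  # label echoed into outputs
    n_pixels: int = 50_000
    k_palette: int = 50
    R_perm: int = 1000
    R_boot: int = 1000
    seed: int | None = None
    out: str = "results"
    tips_only: bool = False
    background: tuple | None = None  # RGB color keyed out of images
    penalty: float | None = None  # fixed ridge lambda (None = CV per sex)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.centroids is None) == (self.images is None):
            raise ValueError("provide exactly one of 'centroids' or 'images'")
        for name in ("n_pixels", "k_palette"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for path in (self.tree, self.centroids, self.images):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


@dataclass
class RunReport:
    """Summary statistics of one run plus provenance."""

    version: str
    config: dict
    statistics: dict
    timings: dict = field(default_factory=dict)


def centroids_from_images(images_dir, n_pixels: int, seed=None, background=None) -> pd.DataFrame:
    """Compute per-species, per-sex centroids from a directory of images.

    Files are named ``<species>_male.<ext>`` / ``<species>_female.<ext>``;
    a file named just ``<species>.<ext>`` is sampled twice, once per sex
    (the convention for monochromatic species depicted by a single image).
    Each image gets its own child seed, in sorted-filename order.
    """
    paths = sorted(p for p in Path(images_dir).iterdir() if p.suffix.lower() in _IMAGE_EXTS)
    if not paths:
        raise FileNotFoundError(f"no images found in {images_dir}")
    seeds = np.random.SeedSequence(seed).spawn(len(paths))
    rows = []
    for path, ss in zip(paths, seeds):
        stem = path.stem
        if stem.endswith(("_male", "_female")):
            species, sex = stem.rsplit("_", 1)
            sexes = [sex]
        else:
            species, sexes = stem, ["male", "female"]
        for sex in sexes:
            sample = sample_pixels(path, n_pixels, seed=ss, species_id=species,
                                   sex=sex, background=background)
            c = centroid(sample)
            rows.append({"species_id": species, "sex": sex, "L": c.L, "a": c.a, "b": c.b})
    return pd.DataFrame(rows)


def _perm_json(results) -> dict:
    out = {}
    for name, res in results.items():
        out[name] = {
            "observed": res.observed,
            "p_two_tailed": res.p_two_tailed,
            "R": res.R,
            "null_quantiles": res.null_quantiles(),
        }
    return out


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute every stage and write all outputs under ``config.out``."""
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    seed_colors, seed_perm, seed_boot = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(3)
    )

    def stage(name):
        log.info("stage %s (surface=%s)", name, config.surface)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    try:
        stage("colors")
        if config.images is not None:
            centroids = centroids_from_images(
                config.images, config.n_pixels, seed=seed_colors, background=config.background
            )
            write_centroid_table(centroids, outdir / "centroids.csv")
        else:
            centroids = read_centroid_table(config.centroids)
        dichro = dichromatism_table(centroids)
        dichro.to_csv(outdir / "dichromatism.csv", index=False)
        done("colors")

        stage("ridge")
        index = as_tree_index(config.tree)
        table, summary, (fit_m, fit_f) = analyze_dataset(
            index, centroids, tips_only=config.tips_only, penalty=config.penalty
        )
        for sex, fit in (("male", fit_m), ("female", fit_f)):
            fit.node_frame().to_csv(outdir / f"node_states_{sex}.csv", index=False)
            fit.branch_frame().to_csv(outdir / f"branch_rates_{sex}.csv", index=False)
        table.to_csv(outdir / "contributions.csv", index=False)
        done("ridge")

        stats = {
            "surface": config.surface,
            "rate_ratio": summary["rate_ratio"],
            "ratio_slope": summary["ratio_slope"],
            "male_slope": summary["male_slope"],
            "female_slope": summary["female_slope"],
            "penalty_male": fit_m.penalty,
            "penalty_female": fit_f.penalty,
            "n_branches": summary["n_branches"],
        }

        if config.R_perm > 0:
            stage("permutation")
            perm = run_permutation_study(
                index, centroids, R=config.R_perm, seed=seed_perm, tips_only=config.tips_only
            )
            perm_payload = _perm_json(perm)
            (outdir / "permutation.json").write_text(json.dumps(perm_payload, indent=2))
            pd.DataFrame({k: v.null_values for k, v in perm.items()}).to_csv(
                outdir / "permutation_null.csv", index=False
            )
            stats["p_values"] = {k: v["p_two_tailed"] for k, v in perm_payload.items()}
            done("permutation")

        if config.R_boot > 0:
            stage("lambda")
            trait = dichro.set_index("species_id")["D_mag"]
            lam = pagel_lambda(index, trait, R_boot=config.R_boot, seed=seed_boot)
            stats["pagel_lambda"] = {
                "estimate": lam.lambda_hat,
                "ci_low": lam.ci_low,
                "ci_high": lam.ci_high,
                "R_boot": lam.R_boot,
            }
            done("lambda")
    except Exception:
        log.exception("run failed; partial outputs retained in %s", outdir)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    report = RunReport(version=__version__, config=asdict(config), statistics=stats,
                       timings=timings)
    payload = {"version": report.version, "config": report.config, "statistics": stats}
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "timings.json").write_text(json.dumps(timings, indent=2))
    return report
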