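"""Compare this package's statistics with the published European-butterfly
dorsal-surface results, using the archived dataset (not bundled here).

The original study of dorsal wing coloration in all European non-hesperiid
butterflies reported, for the dorsal surface:

    rate ratio  ||m||/||f||       ~ 1.26
    male contribution slope       ~ 0.71
    female contribution slope     ~ 0.29
    Pagel's lambda (dichromatism) ~ 0.79  [95% CI 0.66-0.86]

This script recomputes those quantities from a user-supplied copy of the
archived centroid table and MCC tree and prints both side by side. The
comparison is informational, not asserted: the original analysis used a
ridge implementation whose penalty-selection rule is not published, so the
recomputed values are expected to agree only approximately (as a guide:
within ~10-20% for the ratio and slopes). Differences beyond that suggest a
data-alignment problem (tip labels vs species ids) rather than a numerical
one.

Usage:
    python scripts/compare_published.py --tree mcc_tree.nwk \
        --centroids dorsal_centroids.csv [--r-boot 1000] [--seed 1]

The centroid CSV must have columns species_id, sex, L, a, b with tip labels
matching the tree.
"""

from __future__ import annotations

import argparse
import json

import dichroma as dc

REFERENCE = {
    "rate_ratio": 1.26,
    "male_slope": 0.71,
    "female_slope": 0.29,
    "pagel_lambda": 0.79,
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tree", required=True)
    ap.add_argument("--centroids", required=True)
    ap.add_argument("--r-boot", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    centroids = dc.read_centroid_table(args.centroids)
    index = dc.TreeIndex(dc.read_tree(args.tree))
    _, summary, _ = dc.analyze_dataset(index, centroids)
    dichro = dc.dichromatism_table(centroids).set_index("species_id")["D_mag"]
    lam = dc.pagel_lambda(index, dichro, R_boot=args.r_boot, seed=args.seed)

    recomputed = {
        "rate_ratio": summary["rate_ratio"],
        "male_slope": summary["male_slope"],
        "female_slope": summary["female_slope"],
        "pagel_lambda": lam.lambda_hat,
    }
    print(f"{'statistic':<16}{'published':>12}{'recomputed':>14}")
    for key, ref in REFERENCE.items():
        print(f"{key:<16}{ref:>12.2f}{recomputed[key]:>14.3f}")
    if lam.ci_low is not None:
        print(f"lambda 95% CI   [0.66, 0.86]  [{lam.ci_low:.3f}, {lam.ci_high:.3f}]")
    print(json.dumps({"recomputed": recomputed}, indent=2))


if __name__ == "__main__":
    main()
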