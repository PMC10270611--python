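#!/usr/bin/env python
"""The phylogeographic round: spherical diffusion over the dated tree.

Takes the MCC tree and clade table of the dating round, keeps clades with
posterior support >= 0.70 as constraints (heights free within their 95%
ranges), samples internal-node locations and the diffusion precision τ, and
exports branch movements plus 80% HPD regions as GeoJSON under
results/geography/.
"""

import argparse
from pathlib import Path

import pandas as pd

from lexiclade.geo import GeoConfig, GeoLocation
from lexiclade.pipeline import run_phylogeography
from lexiclade.summarize import CladeSummary, MCCResult
from lexiclade.trees import Tree

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--run-dir", type=Path, default=ROOT / "results" / "phylogeny")
    ap.add_argument("--coords", type=Path, default=ROOT / "results" / "data" / "coords.tsv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "geography")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--iterations", type=int, default=30_000)
    ap.add_argument("--support", type=float, default=0.70)
    args = ap.parse_args()

    tree = Tree.from_newick((args.run_dir / "mcc.nwk").read_text())
    hpd = pd.read_csv(args.run_dir / "hpd.tsv", sep="\t")
    clades = [CladeSummary(frozenset(str(r["clade"]).split(",")), float(r["support"]),
                           float(r["mean_height"]),
                           (float(r["hpd_low"]), float(r["hpd_high"])))
              for _, r in hpd.iterrows()]
    pts = pd.read_csv(args.coords, sep="\t")
    coords = {str(r["doculect"]): GeoLocation(float(r["lat"]), float(r["lon"]))
              for _, r in pts.iterrows()}

    args.out.mkdir(parents=True, exist_ok=True)
    post = run_phylogeography(
        MCCResult(tree, clades), coords,
        GeoConfig(iterations=args.iterations, seed=args.seed),
        support_threshold=args.support,
        out_path=args.out / "dispersal.geojson",
    )
    root_mean = post.node_mean(tree.root)
    import numpy as np

    print(f"root location posterior mean: ({root_mean.lat:.2f}, {root_mean.lon:.2f})")
    print(f"diffusion precision τ median: {np.median(post.tau_samples):.0f}")
    print(f"wrote {args.out / 'dispersal.geojson'}")


if __name__ == "__main__":
    main()
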