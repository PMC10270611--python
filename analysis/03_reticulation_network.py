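#!/usr/bin/env python
"""Reticulation diagnostics: NeighborNet, δ-scores and Q-residuals.

Distances are 1 - shared cognacy.  Writes the circular split system as a
SPLITS-block NEXUS (readable by standard network viewers) and the quartet
scores as JSON under results/network/.
"""

import argparse
import json
from pathlib import Path

from lexiclade import nexus
from lexiclade.cognacy import cognacy_matrix
from lexiclade.splits import cognacy_distance, delta_scores, neighbor_net
from lexiclade.wordlist import read_wordlist

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--wordlist", type=Path, default=ROOT / "results" / "data" / "wordlist.tsv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "network")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    w = read_wordlist(args.wordlist)
    d = cognacy_distance(cognacy_matrix(w))
    qs = delta_scores(d, seed=args.seed)
    net = neighbor_net(d)

    args.out.mkdir(parents=True, exist_ok=True)
    nexus.write_splits_nexus(net, args.out / "neighbor_net.nex")
    (args.out / "quartet_scores.json").write_text(json.dumps({
        "delta_score": qs.delta_overall,
        "q_residual": qs.q_overall,
        "n_quartets": qs.n_quartets,
        "delta_per_taxon": dict(zip(qs.taxa, qs.delta_per_taxon.tolist())),
        "q_per_taxon": dict(zip(qs.taxa, qs.q_per_taxon.tolist())),
    }, indent=1))

    print(f"δ-score {qs.delta_overall:.4f}, Q-residual {qs.q_overall:.6f} "
          f"over {qs.n_quartets} quartets")
    print(f"{len(net.splits)} weighted splits; wrote {args.out}")


if __name__ == "__main__":
    main()
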