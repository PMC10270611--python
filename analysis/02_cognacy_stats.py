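#!/usr/bin/env python
"""Descriptive cognacy statistics of the dataset.

Computes the pairwise shared-cognacy matrix, the cognacy diversity
(C - M)/(W - M), and per-concept TIGER rates; writes cognacy.tsv and
stats.json under results/stats/ and prints the headline numbers.
"""

import argparse
import json
from pathlib import Path

from lexiclade.cognacy import cognacy_diversity, cognacy_matrix, tiger_rates
from lexiclade.wordlist import read_wordlist

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--wordlist", type=Path, default=ROOT / "results" / "data" / "wordlist.tsv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "stats")
    args = ap.parse_args()

    w = read_wordlist(args.wordlist)
    cm = cognacy_matrix(w)
    div = cognacy_diversity(w)
    rep = tiger_rates(w)

    args.out.mkdir(parents=True, exist_ok=True)
    with open(args.out / "cognacy.tsv", "w") as fh:
        fh.write("taxon\t" + "\t".join(cm.taxa) + "\n")
        for i, t in enumerate(cm.taxa):
            fh.write(t + "\t" + "\t".join(f"{v:.4f}" for v in cm.values[i]) + "\n")
    (args.out / "stats.json").write_text(json.dumps({
        "cognacy_diversity": div,
        "tiger_mean": rep.mean,
        "tiger_sd": rep.sd,
        "tiger_scores": dict(zip(rep.concepts, rep.scores.tolist())),
    }, indent=1))

    print(f"cognacy diversity: {100 * div:.1f}%")
    print(f"TIGER mean {rep.mean:.2f} (±{rep.sd:.2f}) over {len(rep.scores)} concepts")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
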