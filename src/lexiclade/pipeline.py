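"""Two-round study orchestration.

Round one turns a wordlist into a dated tree: filter concepts by
missingness (or restrict to a named list such as a Swadesh subset), encode
as binary characters, split into two balanced partitions, run the covarion
MCMC and summarise as an MCC tree with common-ancestor heights.  Round two
takes the well-supported clades of that tree (posterior support >= 0.70 by
default) with their 95% height ranges and runs the spherical
phylogeographic reconstruction with the topology fixed.

Every run writes a manifest (inputs digests, config echo, seeds) so results
can be traced back to their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nexus
from .cognacy import cognacy_diversity, cognacy_matrix, tiger_rates
from .geo import GeoConfig, GeoLocation, export_geojson, sample_geography
from .mcmc import PosteriorTrace, mcmc_sample
from .priors import MCMCConfig
from .summarize import MCCResult, mcc_tree
from .splits import cognacy_distance, delta_scores, neighbor_net
from .wordlist import Wordlist, encode_binary, filter_by_missingness, filter_concepts, partition_characters

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    name: str = "full"
    concepts: Optional[Sequence[str]] = None      # None = all concepts
    max_missing: float = 0.2                      # 0.2 full study, 0.3 swadesh
    clock_kind: str = "ucln"
    n_partitions: int = 2
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    drop_singletons: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0,1]")


@dataclass
class StudyResult:
    mcc: MCCResult
    trace: PosteriorTrace
    stats: dict
    manifest: dict


def swadesh_concepts() -> list[str]:
    """The packaged 100-item basic-vocabulary concept list (user-overridable:
    pass any concept list to StudyConfig instead)."""
    path = Path(__file__).parent / "data" / "swadesh100.txt"
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_study(cfg: StudyConfig, wordlist: Wordlist, out_dir=None) -> StudyResult:
    """filter -> encode -> partition -> infer -> summarise."""
    stage = "filter"
    try:
        w = wordlist
        if cfg.concepts is not None:
            w = filter_concepts(w, list(cfg.concepts))
        w = filter_by_missingness(w, cfg.max_missing)
        if not w.concepts:
            raise ValueError("no concepts survive the missingness filter")

        stage = "stats"
        stats = {
            "n_doculects": len(w.doculects),
            "n_concepts": len(w.concepts),
            "cognacy_diversity": cognacy_diversity(w),
        }
        try:
            rep = tiger_rates(w)
            stats["tiger_mean"], stats["tiger_sd"] = rep.mean, rep.sd
        except ValueError:
            pass

        stage = "encode"
        m = encode_binary(w, drop_singletons=cfg.drop_singletons)
        m = partition_characters(m, cfg.n_partitions)
        stats["n_characters"] = m.n_chars

        stage = "infer"
        mc = dataclasses.replace(cfg.mcmc, clock_kind=cfg.clock_kind)
        trace = mcmc_sample(m, mc)

        stage = "summarise"
        mcc = mcc_tree(trace, mc.burn_in)
    except Exception as err:
        raise RuntimeError(f"study {cfg.name!r} failed at stage {stage}: {err}") from err

    manifest = {
        "study": cfg.name,
        "seed": cfg.mcmc.seed,
        "wordlist_digest": _digest([(e.doculect_id, e.concept_id, e.cognate_set_id)
                                    for e in wordlist.entries]),
        "config_echo": {
            "max_missing": cfg.max_missing,
            "clock": cfg.clock_kind,
            "iterations": cfg.mcmc.iterations,
            "root_prior": list(cfg.mcmc.root_prior),
        },
        "stats": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                  for k, v in stats.items()},
    }
    manifest["manifest_digest"] = _digest(manifest)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nexus.write_nexus(m, out / "matrix.nex")
        (out / "mcc.nwk").write_text(mcc.tree.to_newick() + "\n")
        with open(out / "hpd.tsv", "w") as fh:
            fh.write("clade\tsupport\tmean_height\thpd_low\thpd_high\n")
            for c in mcc.clades:
                fh.write(f"{','.join(sorted(c.taxa))}\t{c.support:.4f}\t"
                         f"{c.mean_height:.1f}\t{c.hpd[0]:.1f}\t{c.hpd[1]:.1f}\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        _write_trace(trace, out / "trace.tsv")
    return StudyResult(mcc, trace, stats, manifest)


def _write_trace(trace: PosteriorTrace, path) -> None:
    names = sorted(trace.scalars)
    with open(path, "w") as fh:
        fh.write("iteration\t" + "\t".join(names) + "\n")
        for k, it in enumerate(trace.iterations):
            fh.write(str(it) + "\t" + "\t".join(f"{trace.scalars[n][k]:.6g}" for n in names) + "\n")


def reticulation_report(wordlist: Wordlist, seed: int = 0) -> dict:
    """Cognacy matrix, diversity, δ/Q scores and NeighborNet in one bundle."""
    cm = cognacy_matrix(wordlist)
    d = cognacy_distance(cm)
    scores = delta_scores(d, seed=seed)
    net = neighbor_net(d)
    return {
        "cognacy": cm,
        "distances": d,
        "delta": scores.delta_overall,
        "q_residual": scores.q_overall,
        "network": net,
        "diversity": cognacy_diversity(wordlist),
    }


def run_phylogeography(
    mcc: MCCResult,
    coords: dict[str, GeoLocation],
    cfg: GeoConfig | None = None,
    support_threshold: float = 0.70,
    out_path=None,
):
    """Round two: constrain well-supported clades and sample locations.

    Clades with posterior support >= ``support_threshold`` keep their
    topology and move only within their 95% height ranges; the spherical
    diffusion posterior is exported as GeoJSON when ``out_path`` is given.
    """
    cfg = cfg or GeoConfig()
    good = [c for c in mcc.clades if c.support >= support_threshold]
    if not good:
        raise ValueError(
            f"no clade reaches support {support_threshold}; lower the threshold"
        )
    cfg.height_ranges = {tuple(sorted(c.taxa)): c.hpd for c in good}
    cfg.move_heights = True
    post = sample_geography(mcc.tree, coords, cfg)
    if out_path is not None:
        export_geojson(post, out_path, cfg.hpd_mass)
    return post
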