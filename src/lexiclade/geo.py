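"""Phylogeography on the sphere.

Internal-node locations of a dated tree are inferred under an isotropic
diffusion: the displacement along a branch of duration t has central angle
θ distributed with density proportional to exp(-θ²/(2v))·sinθ on [0, π],
where v = t/τ and τ is the diffusion precision (large τ = slow spread).
The Gaussian-on-angle kernel, numerically normalized over the sphere, is a
documented approximation to the exact spherical heat kernel; it is isolated
in :func:`angle_log_density` so the exact series could be swapped in.

Sampling is Metropolis-Hastings over internal node locations (tangent-plane
Gaussian proposals), the precision τ, and optionally the node heights within
user-supplied uniform ranges (the two-round design: height ranges come from
the dating stage's 95% HPDs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import quad


from .trees import Tree

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoLocation:
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90 <= self.lat <= 90:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180 < self.lon <= 180:
            raise ValueError(f"longitude {self.lon} out of range")

    def to_xyz(self) -> np.ndarray:
        la, lo = math.radians(self.lat), math.radians(self.lon)
        return np.array([math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo), math.sin(la)])

    @staticmethod
    def from_xyz(v: np.ndarray) -> "GeoLocation":
        v = v / np.linalg.norm(v)
        lat = math.degrees(math.asin(np.clip(v[2], -1, 1)))
        lon = math.degrees(math.atan2(v[1], v[0]))
        if lon <= -180:
            lon += 360
        return GeoLocation(lat, lon)


def great_circle_angle(a: GeoLocation, b: GeoLocation) -> float:
    """Central angle in [0, π] via the haversine formula (stable near 0, π)."""
    la1, lo1 = math.radians(a.lat), math.radians(a.lon)
    la2, lo2 = math.radians(b.lat), math.radians(b.lon)
    h = math.sin((la2 - la1) / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    return 2.0 * math.asin(min(1.0, math.sqrt(h)))


_NORM_CACHE: dict[float, float] = {}


def _log_norm(v: float) -> float:
    """log ∫_0^π exp(-θ²/(2v)) sinθ dθ (cached on the rounded variance)."""
    key = round(math.log(v), 6)
    if key not in _NORM_CACHE:
        val, _ = quad(lambda th: math.exp(-th * th / (2 * v)) * math.sin(th), 0, math.pi,
                      limit=200)
        _NORM_CACHE[key] = math.log(max(val, 1e-300))
    return _NORM_CACHE[key]


def angle_log_density(theta: float, v: float) -> float:
    """log density of the central angle θ for branch variance v."""
    if v <= 0:
        raise ValueError("variance must be positive")
    return -theta * theta / (2 * v) - _log_norm(v)


@dataclass
class GeoTree:
    tree: Tree
    locations: dict[int, GeoLocation]    # node -> location (all nodes)
    tau: float                           # diffusion precision, years per unit variance

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def geo_log_likelihood(g: GeoTree) -> float:
    """Sum over branches of the angle kernel log density."""
    t = g.tree
    total = 0.0
    for i in range(t.n_nodes):
        if i == t.root:
            continue
        dur = t.heights[t.parent[i]] - t.heights[i]
        if dur <= 0:
            dur = 1e-9
        v = dur / g.tau
        theta = great_circle_angle(g.locations[i], g.locations[t.parent[i]])
        total += angle_log_density(theta, v)
    return total


# ---------------------------------------------------------------------------
# sampling


@dataclass
class GeoConfig:
    iterations: int = 20_000
    thinning: int = 20
    seed: int = 1
    burn_in: float = 0.5
    tau_prior_log_sd: float = 2.0        # lognormal around the init value
    height_ranges: dict = field(default_factory=dict)  # clade -> (lo, hi)
    move_heights: bool = False
    step_angle: float = 0.1              # radians, tangent proposal scale
    hpd_mass: float = 0.80


@dataclass
class GeoPosterior:
    tree: Tree
    node_samples: dict[int, np.ndarray]   # node -> (k, 2) lat/lon samples
    tau_samples: np.ndarray
    height_samples: dict[int, np.ndarray]
    tip_locations: dict[str, GeoLocation] = field(default_factory=dict)

    def node_mean(self, node: int) -> GeoLocation:
        xyz = np.stack([GeoLocation(a, b).to_xyz() for a, b in self.node_samples[node]])
        return GeoLocation.from_xyz(xyz.mean(axis=0))

    def node_hpd_polygon(self, node: int, mass: float = 0.80) -> list[tuple[float, float]]:
        """Convex polygon (lon, lat ring) around the densest ``mass`` of samples."""
        from scipy.spatial import ConvexHull

        pts = self.node_samples[node]
        center = self.node_mean(node)
        d = np.array([great_circle_angle(center, GeoLocation(a, b)) for a, b in pts])
        k = max(int(np.ceil(mass * len(pts))), 3)
        keep = pts[np.argsort(d)[:k]]
        lonlat = np.stack([keep[:, 1], keep[:, 0]], axis=1)
        if len(np.unique(lonlat, axis=0)) < 3:
            p = lonlat[0]
            eps = 1e-6
            ring = [(p[0] - eps, p[1] - eps), (p[0] + eps, p[1] - eps), (p[0], p[1] + eps)]
        else:
            hull = ConvexHull(lonlat, qhull_options="QJ")
            ring = [tuple(lonlat[i]) for i in hull.vertices]
        ring.append(ring[0])
        return ring


def sample_geography(
    tree: Tree,
    tips: dict[str, GeoLocation],
    cfg: GeoConfig,
    init_tau: float | None = None,
) -> GeoPosterior:
    """MH posterior over internal locations, τ and (optionally) heights."""
    missing = [lb for lb in tree.labels if lb not in tips]
    if missing:
        raise ValueError(f"tips without coordinates: {missing}")
    rng = np.random.default_rng(cfg.seed)
    t = tree.copy()
    loc: dict[int, GeoLocation] = {}
    for i, lb in enumerate(t.labels):
        loc[i] = tips[lb]
    # init internals at the spherical mean of their descendant tips
    sets = t.tipsets()
    for i in t.postorder():
        if not t.is_tip(i):
            xyz = np.stack([tips[lb].to_xyz() for lb in sets[i]]).mean(axis=0)
            loc[i] = GeoLocation.from_xyz(xyz)
    if init_tau is None:
        init_tau = max(t.heights[t.root], 1.0)
    g = GeoTree(t, loc, init_tau)
    logp = _geo_posterior(g, init_tau, cfg)

    internals = [i for i in range(t.n_nodes) if not t.is_tip(i)]
    clades = t.clades()
    range_of: dict[int, tuple[float, float]] = {}
    for taxa, rng_h in cfg.height_ranges.items():
        key = frozenset(taxa)
        if key in clades:
            range_of[clades[key]] = rng_h

    node_samples: dict[int, list] = {i: [] for i in internals}
    height_samples: dict[int, list] = {i: [] for i in internals}
    taus: list[float] = []
    mean_dur = float(np.mean([d for d in t.branch_durations() if d > 0])) or 1.0

    for it in range(cfg.iterations + 1):
        if it % cfg.thinning == 0:
            for i in internals:
                node_samples[i].append((g.locations[i].lat, g.locations[i].lon))
                height_samples[i].append(float(g.tree.heights[i]))
            taus.append(g.tau)
        if it == cfg.iterations:
            break
        kind = rng.random()
        if kind < 0.7:  # move one internal location, step matched to diffusion scale
            step = min(max(cfg.step_angle * math.sqrt(mean_dur / g.tau), 1e-6), 0.5)
            i = internals[rng.integers(len(internals))]
            new = _tangent_step(g.locations[i], step, rng)
            old = g.locations[i]
            g.locations[i] = new
            lp2 = _geo_posterior(g, init_tau, cfg)
            if math.log(rng.random()) < lp2 - logp:
                logp = lp2
            else:
                g.locations[i] = old
        elif kind < 0.9 or not cfg.move_heights:  # scale tau
            scale = math.exp(1.2 * (rng.random() - 0.5))
            old_tau = g.tau
            g.tau = old_tau * scale
            lp2 = _geo_posterior(g, init_tau, cfg) + math.log(scale)
            if math.log(rng.random()) < lp2 - logp:
                logp = lp2 - math.log(scale)
            else:
                g.tau = old_tau
        else:  # slide one height within its admissible window
            i = internals[rng.integers(len(internals))]
            lo = max(g.tree.heights[c] for c in g.tree.children[i])
            hi = g.tree.heights[g.tree.parent[i]] if i != g.tree.root else g.tree.heights[i] * 1.5
            if i in range_of:
                lo, hi = max(lo, range_of[i][0]), min(hi, range_of[i][1])
            if hi <= lo:
                continue
            old_h = g.tree.heights[i]
            g.tree.heights[i] = rng.uniform(lo, hi)
            lp2 = _geo_posterior(g, init_tau, cfg)
            if math.log(rng.random()) < lp2 - logp:
                logp = lp2
            else:
                g.tree.heights[i] = old_h

    k = int(len(taus) * cfg.burn_in)
    return GeoPosterior(
        t,
        {i: np.array(v[k:]) for i, v in node_samples.items()},
        np.array(taus[k:]),
        {i: np.array(v[k:]) for i, v in height_samples.items()},
        dict(tips),
    )


def _geo_posterior(g: GeoTree, tau0: float, cfg: GeoConfig) -> float:
    # lognormal prior on tau centred at the initial guess
    lt = math.log(g.tau / tau0)
    prior = -0.5 * (lt / cfg.tau_prior_log_sd) ** 2 - math.log(g.tau)
    return prior + geo_log_likelihood(g)


def _tangent_step(p: GeoLocation, step: float, rng) -> GeoLocation:
    v = p.to_xyz()
    # orthonormal tangent basis
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    d = rng.normal(scale=step, size=2)
    return GeoLocation.from_xyz(v + d[0] * e1 + d[1] * e2)


# ---------------------------------------------------------------------------
# export


def export_geojson(post: GeoPosterior, path, hpd_mass: float = 0.80) -> None:
    """FeatureCollection: branch line-strings + node HPD polygons."""
    t = post.tree
    features = []

    def node_lonlat(i: int) -> tuple[float, float]:
        if t.is_tip(i):
            loc = post.tip_locations[t.labels[i]]
            return (loc.lon, loc.lat)
        m = post.node_mean(i)
        return (m.lon, m.lat)

    sets = t.tipsets()
    for i in range(t.n_nodes):
        if i != t.root:
            p = t.parent[i]
            start = node_lonlat(p)
            end = node_lonlat(i)
            mean_height = 0.5 * (t.heights[p] + t.heights[i])
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(start), list(end)]},
                "properties": {"mean_height": float(mean_height)},
            })
    for i in range(t.n_nodes):
        if not t.is_tip(i):
            ring = post.node_hpd_polygon(i, hpd_mass)
            features.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [[list(pt) for pt in ring]]},
                "properties": {
                    "clade": sorted(sets[i]),
                    "mass": hpd_mass,
                    "mean_height": float(t.heights[i]),
                },
            })
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")
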