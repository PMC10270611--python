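import json
import math

import numpy as np
import pytest
from scipy.integrate import quad

from lexiclade.geo import (
    GeoConfig,
    GeoLocation,
    GeoTree,
    angle_log_density,
    export_geojson,
    geo_log_likelihood,
    great_circle_angle,
    sample_geography,
)
from lexiclade.trees import Tree


class TestGreatCircle:
    def test_coincident(self):
        p = GeoLocation(12.0, 34.0)
        assert great_circle_angle(p, p) == 0.0

    def test_antipodes(self):
        assert np.isclose(great_circle_angle(GeoLocation(0, 0), GeoLocation(0, 180)), math.pi)

    def test_quarter_circle(self):
        assert np.isclose(great_circle_angle(GeoLocation(0, 0), GeoLocation(0, 90)), math.pi / 2)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            GeoLocation(91.0, 0.0)
        with pytest.raises(ValueError):
            GeoLocation(0.0, -180.0)


class TestAngleDensity:
    @pytest.mark.parametrize("v", [0.01, 0.1, 1.0])
    def test_normalised_over_sphere(self, v):
        val, _ = quad(lambda th: math.exp(angle_log_density(th, v)) * math.sin(th),
                      0, math.pi, limit=200)
        assert abs(val - 1.0) < 1e-6

    def test_zero_displacement_is_mode(self):
        t = Tree.from_newick("((A:1,B:1):1,C:2);")
        t.rates[:] = 1.0
        pt = GeoLocation(5.0, 5.0)
        same = GeoTree(t, {i: pt for i in range(t.n_nodes)}, tau=1.0)
        ll_same = geo_log_likelihood(same)
        moved = {i: pt for i in range(t.n_nodes)}
        moved[t.root] = GeoLocation(6.0, 5.0)
        assert ll_same > geo_log_likelihood(GeoTree(t, moved, tau=1.0))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        t = Tree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        t.rates[:] = 1.0
        locs = {i: GeoLocation(float(rng.uniform(-60, 60)), float(rng.uniform(-120, 120)))
                for i in range(t.n_nodes)}
        base = geo_log_likelihood(GeoTree(t, locs, tau=0.7))
        # random rotation matrix
        A = rng.normal(size=(3, 3))
        Qr, _ = np.linalg.qr(A)
        if np.linalg.det(Qr) < 0:
            Qr[:, 0] *= -1
        rot = {i: GeoLocation.from_xyz(Qr @ loc.to_xyz()) for i, loc in locs.items()}
        assert abs(base - geo_log_likelihood(GeoTree(t, rot, tau=0.7))) < 1e-9

    def test_invalid_tau(self):
        t = Tree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            GeoTree(t, {}, tau=0.0)


class TestSampleGeography:
    def test_two_tips_same_point_concentrates(self):
        t = Tree.from_newick("(A:1000,B:1000);")
        t.rates[:] = 1.0
        pt = GeoLocation(-10.0, -55.0)
        post = sample_geography(t, {"A": pt, "B": pt},
                                GeoConfig(iterations=60_000, seed=1, tau_prior_log_sd=4.0))
        off = great_circle_angle(post.node_mean(t.root), pt)
        assert math.degrees(off) < 0.1

    def test_square_root_near_centroid(self):
        t = Tree.from_newick("((A:1,B:1):0.02,(C:1,D:1):0.02);")
        t.rates[:] = 1.0
        corners = {"A": GeoLocation(1, 1), "B": GeoLocation(1, -1),
                   "C": GeoLocation(-1, 1), "D": GeoLocation(-1, -1)}
        post = sample_geography(t, corners, GeoConfig(iterations=30_000, seed=2))
        centre = GeoLocation(0.0, 0.0)
        half_diag = great_circle_angle(centre, GeoLocation(1, 1))
        assert great_circle_angle(post.node_mean(t.root), centre) <= half_diag

    def test_missing_tip_coordinates_error(self):
        t = Tree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="B"):
            sample_geography(t, {"A": GeoLocation(0, 0)}, GeoConfig(iterations=10))

    def test_reproducible_under_seed(self):
        t = Tree.from_newick("((A:1,B:1):1,C:2);")
        t.rates[:] = 1.0
        tips = {"A": GeoLocation(0, 0), "B": GeoLocation(0, 5), "C": GeoLocation(5, 0)}
        p1 = sample_geography(t, tips, GeoConfig(iterations=2000, seed=7))
        p2 = sample_geography(t, tips, GeoConfig(iterations=2000, seed=7))
        assert np.array_equal(p1.tau_samples, p2.tau_samples)
        assert np.array_equal(p1.node_samples[t.root], p2.node_samples[t.root])


class TestExportGeoJSON:
    def make_post(self):
        t = Tree.from_newick("(A:1000,B:1000);")
        t.rates[:] = 1.0
        tips = {"A": GeoLocation(-10, -55), "B": GeoLocation(-12, -54)}
        return sample_geography(t, tips, GeoConfig(iterations=3000, seed=3))

    def test_two_tip_tree_features(self, tmp_path):
        post = self.make_post()
        path = tmp_path / "out.geojson"
        export_geojson(post, path)
        doc = json.loads(path.read_text())
        lines = [f for f in doc["features"] if f["geometry"]["type"] == "LineString"]
        polys = [f for f in doc["features"] if f["geometry"]["type"] == "Polygon"]
        assert len(lines) == 2 and len(polys) == 1

    def test_schema_shape_and_round_trip(self, tmp_path):
        post = self.make_post()
        path = tmp_path / "out.geojson"
        export_geojson(post, path)
        doc = json.loads(path.read_text())
        assert doc["type"] == "FeatureCollection"
        for f in doc["features"]:
            assert f["type"] == "Feature"
            assert f["geometry"]["type"] in ("LineString", "Polygon")
            assert "properties" in f
        ring = next(f for f in doc["features"]
                    if f["geometry"]["type"] == "Polygon")["geometry"]["coordinates"][0]
        assert ring[0] == ring[-1]
        # coordinates survive a JSON round trip exactly
        again = json.loads(json.dumps(doc))
        assert again == doc
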