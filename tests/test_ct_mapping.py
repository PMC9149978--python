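"""Windowed CT features and the scattered (mu, sigma) -> parameter surfaces."""

import numpy as np
import pytest

from pseudomr import (
    MappingModel,
    ParameterMaps,
    apply_mapping,
    build_mapping,
    ct_window_features,
)
from pseudomr.errors import DegenerateGeometryError, DomainError, EmptyMaskError


class TestWindowFeatures:
    def test_constant_region(self):
        ct = np.full((9, 9), 50.0)
        f = ct_window_features(ct, np.ones((9, 9), bool))
        assert f.mu[4, 4] == pytest.approx(50.0)
        assert f.sigma[4, 4] == pytest.approx(0.0, abs=1e-9)

    def test_center_of_known_patch(self):
        # 5x5 patch holding 1..25: mu = 13, sample sd = sqrt(1300/24)
        ct = np.arange(1.0, 26.0).reshape(5, 5)
        f = ct_window_features(ct, np.ones((5, 5), bool), min_count=25)
        assert f.mu[2, 2] == pytest.approx(13.0)
        assert f.sigma[2, 2] == pytest.approx(np.sqrt(1300 / 24), rel=1e-12)
        assert f.n[2, 2] == 25

    def test_boundary_pixels_dropped_by_min_count(self):
        ct = np.arange(1.0, 26.0).reshape(5, 5)
        f = ct_window_features(ct, np.ones((5, 5), bool), min_count=25)
        assert not f.mask[0, 0]  # corner window holds only 9 in-mask pixels
        assert f.mask[2, 2]

    def test_out_of_mask_neighbors_excluded(self):
        # two constant half-planes; mask covers only the left one, so windows
        # near the split must not see the right-hand values
        ct = np.full((7, 10), 10.0)
        ct[:, 5:] = 999.0
        mask = np.zeros((7, 10), bool)
        mask[:, :5] = True
        f = ct_window_features(ct, mask, min_count=6)
        assert np.allclose(f.mu[f.mask], 10.0)
        assert np.allclose(f.sigma[f.mask], 0.0, atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(DomainError):
            ct_window_features(np.ones((6, 6)), np.ones((6, 6), bool), window_size=4)

    def test_all_dropped_is_error(self):
        ct = np.ones((4, 4))
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        with pytest.raises(EmptyMaskError):
            ct_window_features(ct, mask, min_count=9)


def _toy_model(mode="piecewise_linear", fallback="nearest"):
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
    values = {
        "t1": np.array([300.0, 600.0, 900.0, 1200.0]),
        "t2": np.array([50.0, 80.0, 110.0, 140.0]),
        "rho": np.array([500.0, 600.0, 700.0, 800.0]),
    }
    return MappingModel(points=pts, values=values, mode=mode, fallback=fallback)


class TestMappingModel:
    @pytest.mark.parametrize("mode", ["piecewise_linear", "nearest"])
    def test_node_exactness(self, mode):
        model = _toy_model(mode)
        est = model.evaluate(model.points[:, 0], model.points[:, 1])
        for k in ("t1", "t2", "rho"):
            assert est[k] == pytest.approx(model.values[k], rel=1e-12)

    def test_edge_midpoint_is_endpoint_mean(self):
        model = _toy_model()
        est = model.evaluate(np.array([5.0]), np.array([0.0]))
        assert est["t1"][0] == pytest.approx((300 + 600) / 2, rel=1e-12)

    def test_outside_hull_falls_back_to_nearest_node(self):
        model = _toy_model()
        q = np.array([[12.0, -3.0], [-20.0, 4.0], [15.0, 15.0]])
        est = model.evaluate(q[:, 0], q[:, 1])
        # exhaustive nearest-point oracle
        for i, (qm, qs) in enumerate(q):
            d = np.hypot(model.points[:, 0] - qm, model.points[:, 1] - qs)
            j = int(np.argmin(d))
            assert est["t1"][i] == pytest.approx(model.values["t1"][j])

    def test_invalid_fallback_marks_nan(self):
        model = _toy_model(fallback="invalid")
        est = model.evaluate(np.array([50.0]), np.array([50.0]))
        assert np.isnan(est["t1"][0])

    def test_affine_surface_reproduced_inside_hull(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, size=(40, 2))
        a, b, c = 200.0, 3.0, -1.5
        v = a + b * pts[:, 0] + c * pts[:, 1]
        values = {"t1": v, "t2": v / 10 + 50, "rho": v + 1000}
        model = MappingModel(points=pts, values=values)
        q = rng.uniform(25, 75, size=(60, 2))  # interior queries
        est = model.evaluate(q[:, 0], q[:, 1])
        assert est["t1"] == pytest.approx(a + b * q[:, 0] + c * q[:, 1], rel=1e-9)

    def test_collinear_points_degenerate(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        values = {k: np.arange(4.0) + 1 for k in ("t1", "t2", "rho")}
        with pytest.raises(DegenerateGeometryError):
            MappingModel(points=pts, values=values, mode="piecewise_linear")
        MappingModel(points=pts, values=values, mode="nearest")  # fine

    def test_json_round_trip(self, tmp_path):
        model = _toy_model()
        path = tmp_path / "model.json"
        model.save(path)
        back = MappingModel.load(path)
        assert np.array_equal(back.points, model.points)
        est = back.evaluate(np.array([5.0]), np.array([5.0]))
        ref = model.evaluate(np.array([5.0]), np.array([5.0]))
        for k in ("t1", "t2", "rho"):
            assert est[k] == pytest.approx(ref[k])


class TestBuildApplyMapping:
    def _features_and_maps(self, mu, sigma, t1):
        shape = mu.shape
        mask = np.ones(shape, bool)
        from pseudomr.ct_mapping import CTFeatureMaps

        feats = CTFeatureMaps(
            mu=mu, sigma=sigma, n=np.full(shape, 25), mask=mask, window_size=5
        )
        maps = ParameterMaps(
            t1=t1, t2=t1 / 10 + 10, rho=t1 + 100, mask=mask
        )
        return feats, maps

    def test_round_trip_at_training_pixels(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(0, 60, (8, 8))
        sigma = rng.uniform(1, 9, (8, 8))
        t1 = 300 + 5 * mu + 20 * sigma + rng.uniform(0, 10, (8, 8))
        feats, maps = self._features_and_maps(mu, sigma, t1)
        for mode in ("piecewise_linear", "nearest"):
            model = build_mapping(feats, maps, mode=mode)
            regen = apply_mapping(model, feats)
            assert np.array_equal(regen.mask, feats.mask)
            for k in ("t1", "t2", "rho"):
                got = getattr(regen, k)[regen.mask]
                want = getattr(maps, k)[regen.mask]
                assert np.max(np.abs(got - want) / np.abs(want)) < 1e-9

    def test_duplicate_features_averaged(self):
        # two pixels share (mu, sigma) but have different parameter values
        mu = np.array([[1.0, 1.0, 5.0], [9.0, 5.0, 3.0]])
        sigma = np.array([[2.0, 2.0, 7.0], [1.0, 3.0, 9.0]])
        t1 = np.array([[100.0, 300.0, 400.0], [500.0, 600.0, 700.0]])
        feats, maps = self._features_and_maps(mu, sigma, t1)
        model = build_mapping(feats, maps, mode="nearest")
        assert model.n_points == 5
        est = model.evaluate(np.array([1.0]), np.array([2.0]))
        assert est["t1"][0] == pytest.approx(200.0)  # mean of 100 and 300

    def test_uniform_features_give_uniform_maps(self):
        from pseudomr.ct_mapping import CTFeatureMaps

        model = _toy_model("nearest")
        shape = (6, 6)
        feats = CTFeatureMaps(
            mu=np.full(shape, 0.1),
            sigma=np.full(shape, 0.2),
            n=np.full(shape, 25),
            mask=np.ones(shape, bool),
            window_size=5,
        )
        out = apply_mapping(model, feats)
        assert np.all(out.t1[out.mask] == out.t1[0, 0])

    def test_disjoint_masks_rejected(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(0, 60, (4, 4))
        feats, maps = self._features_and_maps(mu, mu / 10, 300 + mu)
        feats.mask = np.zeros((4, 4), bool)
        with pytest.raises(EmptyMaskError):
            build_mapping(feats, maps)
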