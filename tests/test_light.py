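"""Monte Carlo light transport: emitters, radiometry, and its physical
limits (single-surface absorption, multiple reflection, Beer–Lambert)."""

import math

import numpy as np
import pandas as pd
import pytest

from canophot import light
from canophot.light import (InterceptionMap, OpticalProps, SkyCondition,
                            TraceConfig, beer_lambert_profile, make_sources)
from canophot.solar import SunPosition

from conftest import leaves_plant, square_leaf

OVERHEAD = SunPosition(zenith=0.0, azimuth=0.0)
UNIT_BOUNDS = (np.array([-0.5, -0.5, 0.0]), np.array([0.5, 0.5, 1.0]))


class TestSources:
    def test_pure_diffuse_has_no_beam(self):
        sky = SkyCondition(1000.0, 1.0)
        srcs = make_sources(sky, OVERHEAD, UNIT_BOUNDS)
        assert [s["kind"] for s in srcs] == ["diffuse"]
        assert srcs[0]["flux_per_area"] == pytest.approx(1000.0, abs=1e-9)

    def test_pure_beam_has_no_diffuse(self):
        sky = SkyCondition(1000.0, 0.0)
        srcs = make_sources(sky, OVERHEAD, UNIT_BOUNDS)
        assert [s["kind"] for s in srcs] == ["beam"]
        assert srcs[0]["flux_per_area"] == pytest.approx(1000.0, abs=1e-9)

    def test_split_sums_to_global(self):
        sky = SkyCondition(800.0, 0.3)
        srcs = make_sources(sky, OVERHEAD, UNIT_BOUNDS)
        assert sum(s["flux_per_area"] for s in srcs) == pytest.approx(
            800.0, abs=1e-9)

    def test_low_sun_folds_beam_into_diffuse(self):
        low = SunPosition(zenith=88.0, azimuth=270.0)
        srcs = make_sources(SkyCondition(200.0, 0.3), low, UNIT_BOUNDS)
        assert [s["kind"] for s in srcs] == ["diffuse"]
        assert srcs[0]["flux_per_area"] == pytest.approx(200.0, abs=1e-9)

    def test_night_gives_diffuse_only(self):
        night = SunPosition(zenith=120.0, azimuth=0.0)
        srcs = make_sources(SkyCondition(5.0, 0.2), night, UNIT_BOUNDS)
        assert [s["kind"] for s in srcs] == ["diffuse"]


class TestTracePhysics:
    def test_single_leaf_absorbs_one_minus_rho_tau(self):
        geom = light.flatten_scene(leaves_plant([square_leaf(1.0)]),
                                   include_stems=False)
        srcs = make_sources(SkyCondition(1000.0, 0.0), OVERHEAD, geom.bounds)
        imap = light.trace(geom, srcs,
                           config=TraceConfig(n_rays=1_000_000, rng_seed=3))
        row = imap.per_leaf.iloc[0]
        assert abs(row.absorbed_umol_m2_s - 830.0) < 3 * row.mc_se + 1e-9
        assert abs(imap.balance_residual) < 1e-9 * imap.emitted_total

    def test_empty_scene_all_rays_escape(self):
        geom = light.flatten_scene(leaves_plant([]), include_stems=False)
        srcs = make_sources(SkyCondition(500.0, 0.0), OVERHEAD, UNIT_BOUNDS)
        imap = light.trace(geom, srcs, config=TraceConfig(n_rays=2000))
        assert imap.absorbed_total == 0.0
        assert imap.escaped_total == pytest.approx(imap.emitted_total,
                                                   rel=1e-12)

    def test_stacked_leaves_multiple_reflection_series(self):
        """Lower of two near-touching horizontal leaves receives the
        transmitted beam amplified by inter-leaf reflections:
        0.83·(1000·0.07)/(1−0.1·0.1) ≈ 58.69."""
        plant = leaves_plant([square_leaf(1.0, leaf_id=0),
                              square_leaf(1.0 - 5e-4, leaf_id=1)])
        geom = light.flatten_scene(plant, include_stems=False)
        srcs = make_sources(SkyCondition(1000.0, 0.0), OVERHEAD, geom.bounds)
        imap = light.trace(geom, srcs,
                           config=TraceConfig(n_rays=1_000_000, rng_seed=5))
        lower = imap.per_leaf.set_index("leaf_id").loc[1]
        expected = 0.83 * 70.0 / (1.0 - 0.01)
        assert abs(lower.absorbed_umol_m2_s - expected) < 3 * lower.mc_se + 0.15
        assert abs(imap.balance_residual) < 1e-9 * imap.emitted_total

    @pytest.mark.parametrize("tilt", [0.0, 30.0, 60.0])
    def test_tilted_leaf_cosine_law(self, tilt):
        geom = light.flatten_scene(leaves_plant([square_leaf(1.0,
                                                             tilt_deg=tilt)]),
                                   include_stems=False)
        srcs = make_sources(SkyCondition(1000.0, 0.0), OVERHEAD, geom.bounds)
        imap = light.trace(geom, srcs,
                           config=TraceConfig(n_rays=500_000, rng_seed=7))
        row = imap.per_leaf.iloc[0]
        expected = 830.0 * math.cos(math.radians(tilt))
        assert abs(row.absorbed_umol_m2_s - expected) < 3 * row.mc_se + 1e-9

    def test_black_leaf_shadowing_monotone(self):
        """With black leaves, adding an occluder above a leaf can never
        increase its absorbed flux (same seed => identical ray set)."""
        cfg = TraceConfig(n_rays=200_000, rng_seed=11)
        target = square_leaf(0.5, size=1.0, leaf_id=0)
        occluder = square_leaf(1.0, size=0.5, leaf_id=1, center=(0.1, 0.1))
        black = OpticalProps(0.0, 0.0)

        def absorbed(leaves):
            plant = leaves_plant(leaves)
            geom = light.flatten_scene(plant, include_stems=False)
            srcs = [{"kind": "beam", "rect": (-0.6, 0.6, -0.6, 0.6), "z": 1.5,
                     "direction": (0.0, 0.0, -1.0), "flux_per_area": 1000.0}]
            imap = light.trace(geom, srcs, optics=black, config=cfg)
            return float(imap.per_leaf.set_index("leaf_id")
                         .loc[0, "absorbed_umol_s"])

        assert absorbed([target, occluder]) < absorbed([target])

    def test_beer_lambert_turbid_medium_limit(self):
        """Randomly placed small horizontal black leaves reproduce
        exponential extinction with k = 1 within 5% down to LAI 3.  The
        exponential holds in expectation over placements, so the profile is
        averaged over a few seeded leaf arrangements (a single arrangement
        carries a few-percent clumping deviation of its own)."""
        side = 0.02
        a = side * side
        n = int(3.0 / a)
        density = n * a  # LAI per unit depth
        depths = (0.6, 0.3, 0.0)
        sums = {zq: 0.0 for zq in depths}
        n_place = 4
        for place_seed in range(n_place):
            rng = np.random.default_rng(42 + place_seed)
            leaves = [square_leaf(rng.uniform(0, 1), size=side, leaf_id=i,
                                  center=(rng.uniform(0, 1),
                                          rng.uniform(0, 1)))
                      for i in range(n)]
            geom = light.flatten_scene(leaves_plant(leaves),
                                       include_stems=False)
            # emit over an interior window to avoid low-density edge strips
            srcs = [{"kind": "beam", "rect": (0.05, 0.95, 0.05, 0.95),
                     "z": 1.2, "direction": (0.0, 0.0, -1.0),
                     "flux_per_area": 1000.0}]
            imap = light.trace(geom, srcs, optics=OpticalProps(0.0, 0.0),
                               config=TraceConfig(n_rays=300_000,
                                                  rng_seed=7 + place_seed))
            df = imap.per_leaf.copy()
            zs = np.array([l.mesh.vertices[0, 2] for l in leaves])
            for zq in depths:
                absorbed_above = df.loc[zs > zq, "absorbed_umol_s"].sum()
                sums[zq] += (imap.emitted_total - absorbed_above) \
                    / imap.emitted_total * 1000.0
        for zq in depths:
            expected = beer_lambert_profile(1000.0, 1.0,
                                            density * (1.0 - zq))
            assert sums[zq] / n_place == pytest.approx(expected, rel=0.05)

    def test_mc_se_shrinks_with_ray_budget(self):
        geom = light.flatten_scene(leaves_plant([square_leaf(0.5)]),
                                   include_stems=False)
        srcs = make_sources(SkyCondition(1000.0, 1.0), None, geom.bounds)

        def se(n, seed):
            imap = light.trace(geom, srcs,
                               config=TraceConfig(n_rays=n, rng_seed=seed))
            return float(imap.per_leaf.iloc[0].mc_se)

        # quadrupling the budget should roughly halve the SE
        ratio = se(50_000, 1) / se(200_000, 1)
        assert 1.2 < ratio < 3.3

    def test_same_seed_reproducible(self):
        geom = light.flatten_scene(leaves_plant([square_leaf(0.5)]),
                                   include_stems=False)
        srcs = make_sources(SkyCondition(900.0, 0.4), OVERHEAD, geom.bounds)
        cfg = TraceConfig(n_rays=30_000, rng_seed=8)
        a = light.trace(geom, srcs, config=cfg)
        b = light.trace(geom, srcs, config=cfg)
        assert a.per_leaf.absorbed_umol_s.iloc[0] == \
            b.per_leaf.absorbed_umol_s.iloc[0]


class TestLayerMeans:
    def _imap(self, rows):
        df = pd.DataFrame(rows)
        df["absorbed_umol_s"] = df["absorbed_umol_m2_s"] * df["area_m2"]
        df["mc_se"] = 0.0
        df["plant"] = 0
        df["stem"] = 0
        df["node"] = df["leaf_id"]
        return InterceptionMap(df, float(df.absorbed_umol_s.sum()), 0.0, 0.0,
                               0.0)

    def test_area_weighted_mean(self):
        imap = self._imap([
            {"leaf_id": 0, "area_m2": 1.0, "absorbed_umol_m2_s": 40.0},
            {"leaf_id": 1, "area_m2": 3.0, "absorbed_umol_m2_s": 80.0}])
        means = light.layer_means(imap, {0: 1, 1: 1})
        assert means.loc[1] == pytest.approx(70.0)

    def test_uniform_irradiance_every_layer_equal(self):
        imap = self._imap([
            {"leaf_id": i, "area_m2": 0.5 + 0.1 * i,
             "absorbed_umol_m2_s": 100.0} for i in range(6)])
        means = light.layer_means(imap, {i: i // 2 + 1 for i in range(6)})
        assert np.allclose(means.to_numpy(), 100.0)

    def test_fully_shaded_layer_is_zero(self):
        imap = self._imap([
            {"leaf_id": 0, "area_m2": 1.0, "absorbed_umol_m2_s": 200.0},
            {"leaf_id": 1, "area_m2": 1.0, "absorbed_umol_m2_s": 0.0}])
        means = light.layer_means(imap, {0: 1, 1: 2})
        assert means.loc[2] == 0.0


@pytest.mark.parametrize("i0,k,lai,expected", [
    (1000.0, 0.5, 0.0, 1000.0),
    (1000.0, 0.0, 2.0, 1000.0),
    (1000.0, 0.5, 2.0, 1000.0 * math.exp(-1.0)),
])
def test_beer_lambert_closed_form(i0, k, lai, expected):
    assert beer_lambert_profile(i0, k, lai) == pytest.approx(expected,
                                                             rel=1e-12)


def test_optical_props_validation():
    with pytest.raises(ValueError):
        OpticalProps(0.6, 0.5)
    assert OpticalProps().absorptance == pytest.approx(0.83)
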