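"""The forward-model generator: spectrum solver, scenes, matchups, series."""

import numpy as np
import pytest

from lake_tsi.calibration import fit_type_model
from lake_tsi.indices import DEFAULT_COEFFICIENTS, abi, get_sensor
from lake_tsi.pipeline import CLASS_CODES, classify_spectrum
from lake_tsi.synthetic import (
    InfeasibleTarget,
    LakeSpec,
    SceneRecipe,
    archive_recipes,
    noise_sd_for_r2,
    simulate_annual_series,
    simulate_matchups,
    simulate_scene,
    solve_bands_for_abi,
)

from conftest import three_lake_recipe


class TestSolveBandsForAbi:
    @pytest.mark.parametrize("sensor_id", ["OLI", "TM"])
    @pytest.mark.parametrize(
        "water_type, target",
        [(1, -0.004), (1, 0.0), (1, 0.02), (1, 0.06),
         (2, -0.01), (2, 0.0), (2, 0.03),
         (3, -0.09), (3, -0.05), (3, -0.01)],
    )
    def test_round_trip_abi_and_class(self, sensor_id, water_type, target):
        sensor = get_sensor(sensor_id)
        for rng in (None, np.random.default_rng(3)):
            spec = solve_bands_for_abi(target, water_type, sensor, rng)
            got = abi(spec["B"], spec["R"], spec["NIR"], sensor)
            assert got == pytest.approx(target, abs=1e-9)
            assert classify_spectrum(spec["B"], spec["G"], spec["R"], spec["NIR"],
                                     spec["SWIR"], sensor) == f"type{water_type}"
            assert all(0.0 <= v <= 0.6 for v in spec.values())

    def test_zero_target_feasible_every_type(self, oli):
        for wt in (1, 2, 3):
            spec = solve_bands_for_abi(0.0, wt, oli)
            assert abi(spec["B"], spec["R"], spec["NIR"], oli) == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_target_raises(self, oli):
        with pytest.raises(InfeasibleTarget):
            solve_bands_for_abi(10.0, 3, oli)
        with pytest.raises(InfeasibleTarget):
            solve_bands_for_abi(-0.6, 2, oli)

    def test_unknown_type(self, oli):
        with pytest.raises(ValueError):
            solve_bands_for_abi(0.0, 4, oli)


class TestSimulateScene:
    def test_forward_inverse_consistency_noise_free(self, clean_scene):
        """classify->invert recovers type and TSI exactly at zero noise."""
        from lake_tsi.runner import process_scene

        scene, truth = clean_scene
        for res in process_scene(scene, truth.outlines):
            typed = np.isin(res.labels, [CLASS_CODES["type1"], CLASS_CODES["type2"],
                                         CLASS_CODES["type3"]])
            assert typed.any()
            assert (res.labels[typed] == truth.class_map[typed]).all()
            assert np.nanmax(np.abs(res.tsi.values[typed] - truth.tsi[typed])) < 1e-6

    def test_bit_reproducible_under_seed(self):
        r = three_lake_recipe(shape=(96, 96), noise_sd=0.005, seed=11)
        s1, t1 = simulate_scene(r)
        s2, t2 = simulate_scene(r)
        for b in s1.bands:
            assert (s1.bands[b] == s2.bands[b]).all()
        assert (t1.class_map == t2.class_map).all()

    def test_seed_changes_reflectance_not_truth(self):
        base = three_lake_recipe(shape=(96, 96), noise_sd=0.005, cloud_fraction=0.0, seed=1)
        other = three_lake_recipe(shape=(96, 96), noise_sd=0.005, cloud_fraction=0.0, seed=2)
        s1, t1 = simulate_scene(base)
        s2, t2 = simulate_scene(other)
        assert (t1.class_map == t2.class_map).all()
        assert not (s1.bands["G"] == s2.bands["G"]).all()

    def test_class_fractions_within_one_pixel(self):
        lake = LakeSpec("L", (48, 48), (30, 30),
                        fractions={"type1": 0.5, "type2": 0.3, "type3": 0.15, "scum": 0.05})
        scene, truth = simulate_scene(SceneRecipe(shape=(96, 96), lakes=(lake,), seed=3))
        n_lake = int(np.isin(truth.class_map,
                             [CLASS_CODES[c] for c in ("type1", "type2", "type3",
                                                       "scum", "vegetation")]).sum())
        for cls, frac in lake.fractions.items():
            realized = int((truth.class_map == CLASS_CODES[cls]).sum())
            assert abs(realized - frac * n_lake) <= 1

    def test_full_cloud_cover_blocks_everything(self):
        from lake_tsi.runner import process_scene

        r = three_lake_recipe(shape=(96, 96), cloud_fraction=1.0)
        scene, truth = simulate_scene(r)
        assert (scene.qa == 3).all()
        for res in process_scene(scene, truth.outlines):
            assert res.valid_count == 0 and res.mean_tsi is None

    def test_invalid_recipe_rejected(self):
        bad = SceneRecipe(lakes=(LakeSpec("L", (10, 10), (6, 6),
                                          fractions={"type1": 0.9, "type2": 0.3}),))
        with pytest.raises(ValueError, match="sum <= 1"):
            bad.validate()
        with pytest.raises(ValueError, match="cloud_fraction"):
            SceneRecipe(cloud_fraction=2.0).validate()


class TestSimulateMatchups:
    def test_noise_free_refit_exact(self):
        ms = simulate_matchups(50, 2, seed=5)
        c = fit_type_model(ms, 2)
        assert c.slope == pytest.approx(DEFAULT_COEFFICIENTS[2].slope, rel=1e-9)
        assert c.intercept == pytest.approx(DEFAULT_COEFFICIENTS[2].intercept, rel=1e-9)
        assert c.r2 == pytest.approx(1.0)

    def test_r2_calibration(self):
        """Noise tuned for r2 ~ 0.66 lands in (0.56, 0.76) across seeds."""
        sd = noise_sd_for_r2(0.66)
        r2s = [
            fit_type_model(simulate_matchups(310, 1, tsi_noise_sd=sd, seed=s), 1).r2
            for s in range(30)
        ]
        assert all(0.56 < r2 < 0.76 for r2 in r2s)
        assert np.mean(r2s) == pytest.approx(0.66, abs=0.03)

    def test_tsi_range_and_reproducibility(self):
        ms = simulate_matchups(200, 1, tsi_noise_sd=0.0, seed=9)
        tsi = np.array([m.tsi_measured for m in ms])
        assert tsi.min() >= 20.0 and tsi.max() <= 90.0
        again = simulate_matchups(200, 1, tsi_noise_sd=0.0, seed=9)
        assert [m.abi for m in ms] == [m.abi for m in again]

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            simulate_matchups(0, 1)


class TestSimulateAnnualSeries:
    def test_deterministic_trend_free(self):
        years, vals = simulate_annual_series(10, base=50, slope=0.0, noise_sd=0.0, seed=0)
        assert vals == [50.0] * 10
        assert years == list(range(1984, 1994))

    def test_missing_fraction(self):
        _, vals = simulate_annual_series(40, missing_fraction=0.25, seed=1)
        assert sum(v is None for v in vals) == 10
        _, gone = simulate_annual_series(8, missing_fraction=1.0, seed=1)
        assert all(v is None for v in gone)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            simulate_annual_series(3)


class TestArchiveRecipes:
    def test_trend_shifts_tsi_ranges(self):
        base = three_lake_recipe(shape=(64, 64))
        dated = archive_recipes(base, n_years=3, scenes_per_year=2,
                                trend_by_lake={"L1": 0.5}, start_year=2000, seed=0)
        assert len(dated) == 6
        first_year = dated[0][1].lakes[0].tsi_range[1]
        last_year = dated[-1][1].lakes[0].tsi_range[1]
        assert last_year[0] == pytest.approx(first_year[0] + 1.0)
        seeds = {r.seed for _, r in dated}
        assert len(seeds) == 6  # distinct seeds per scene
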