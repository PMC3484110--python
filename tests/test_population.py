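"""Population pipeline: simulation, noise, partitioning, sweeps."""

import numpy as np
import pytest

from erkpop import population as pop
from erkpop.cascade import ProteinTotals
from erkpop.ras_input import fit_for_dose
from erkpop.cascade import simulate_timecourse


class TestSimulatePopulation:
    def test_seed_determinism(self):
        a = pop.simulate_population("NF", 5, seed=3, dose_indices=(4,))
        b = pop.simulate_population("NF", 5, seed=3, dose_indices=(4,))
        np.testing.assert_array_equal(a.ppERK, b.ppERK)
        c = pop.simulate_population("NF", 5, seed=4, dose_indices=(4,))
        assert not np.array_equal(a.ppERK, c.ppERK)

    def test_degenerate_population_matches_deterministic_run(self, totals, nf_params,
                                                             schedule):
        # huge shape parameter -> every draw collapses onto its mean
        resp = pop.simulate_population("NF", 1, k_shape=1e9, seed=0, dose_indices=(4,))
        traj = simulate_timecourse(totals, nf_params, fit_for_dose(schedule, 4),
                                   [0.0, 2, 5, 10, 30])
        np.testing.assert_allclose(resp.ppERK[0, 0], traj.ppMAPK[1:], rtol=1e-3,
                                   atol=0.5)

    def test_noiseless_values_bounded_by_own_erk_pool(self, nf_population):
        # fixture carries noise; re-simulate a small noiseless population
        resp = pop.simulate_population("NF", 30, seed=9, dose_indices=(4, 6))
        bound = resp.cell_totals[:, 2][:, None, None]
        assert np.nanmax(resp.ppERK - bound) <= 1e-6

    def test_tidy_frame_shape(self):
        resp = pop.simulate_population("US", 4, seed=1, dose_indices=(1, 4))
        df = resp.to_frame()
        assert len(df) == 4 * 2 * 4
        assert set(df.columns) == {"cell_id", "dose_nM", "time_min", "ppERK_nM", "failed"}


class TestNoise:
    def test_added_component_statistics(self):
        resp = pop.simulate_population("NF", 40, seed=2, dose_indices=(4,))
        big = pop.PopulationResponse(
            topology="NF", ppERK=np.zeros((100_000, 1, 1)), times=(5.0,),
            schedule=resp.schedule, mean_totals=resp.mean_totals,
            k_shape=resp.k_shape, seed=0)
        noisy = pop.add_measurement_noise(big, seed=7)
        delta = noisy.ppERK.ravel()
        assert delta.mean() == pytest.approx(10.0, abs=0.15)
        assert delta.std() == pytest.approx(10.0, abs=0.15)

    def test_zero_sd_is_uniform_shift(self):
        resp = pop.simulate_population("NF", 5, seed=2, dose_indices=(4,))
        shifted = pop.add_measurement_noise(resp, pop.NoiseModel(mean=10, sd=0), seed=0)
        np.testing.assert_allclose(shifted.ppERK, resp.ppERK + 10.0)

    def test_double_application_refused(self):
        resp = pop.simulate_population("NF", 5, seed=2, dose_indices=(4,))
        noisy = pop.add_measurement_noise(resp, seed=0)
        with pytest.raises(ValueError):
            pop.add_measurement_noise(noisy, seed=1)

    def test_noise_seed_determinism(self):
        resp = pop.simulate_population("NF", 5, seed=2, dose_indices=(4,))
        a = pop.add_measurement_noise(resp, seed=5)
        b = pop.add_measurement_noise(resp, seed=5)
        np.testing.assert_array_equal(a.ppERK, b.ppERK)


class TestPartition:
    def test_direct_rule(self):
        res = pop.partition_on_off([50.0, 150.0, 250.0], cutoff=100.0)
        assert sorted(res.on_values) == [150.0, 250.0]
        assert list(res.off_values) == [50.0]
        assert res.n_on + res.n_off == 3

    def test_boundary_value_is_off(self):
        res = pop.partition_on_off([100.0, 100.0001], cutoff=100.0)
        assert res.n_on == 1 and res.n_off == 1
        assert res.off_values[0] == 100.0

    def test_all_off(self):
        res = pop.partition_on_off(np.zeros(10), cutoff=100.0)
        assert res.n_on == 0 and res.on_fraction == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pop.partition_on_off([], cutoff=100.0)
        with pytest.raises(ValueError):
            pop.partition_on_off([np.nan, np.nan], cutoff=100.0)


class TestErkOnMeans:
    def _resp(self, values):
        arr = np.asarray(values, float).reshape(-1, 1, 1)
        return pop.PopulationResponse(
            topology="NF", ppERK=arr, times=(5.0,),
            schedule=pop.build_dose_schedule(), mean_totals=ProteinTotals(),
            k_shape=5.4, seed=0)

    def test_exactly_min_cells_on_is_undefined(self):
        vals = [500.0] * 10 + [0.0] * 30   # 10 on-cells: "greater than 10" fails
        means, counts = pop.erk_on_mean_matrix(self._resp(vals), cutoff=100, min_cells=10)
        assert counts[0, 0] == 10
        assert np.isnan(means[0, 0])

    def test_known_mean_with_enough_cells(self):
        on_vals = list(np.linspace(200, 420, 12))
        vals = on_vals + [0.0] * 20
        means, counts = pop.erk_on_mean_matrix(self._resp(vals), cutoff=100, min_cells=10)
        assert counts[0, 0] == 12
        assert means[0, 0] == pytest.approx(np.mean(on_vals))

    def test_nf_dose_and_time_trends(self, nf_population):
        means, counts = pop.erk_on_mean_matrix(nf_population, cutoff=100.0)
        for k, t in enumerate(nf_population.times):
            if t not in (2.0, 5.0):
                continue
            col = means[:, k]
            ok = np.flatnonzero(~np.isnan(col))
            assert len(ok) >= 3
            # ERK-on mean increases with dose at short times
            assert col[ok[-1]] > col[ok[0]]
            assert np.all(np.diff(col[ok]) > -25.0)  # monotone up to sampling noise
        # and decreases with time at a fixed dose (highest dose, 2 -> 30 min)
        top = means[-1]
        assert top[0] > top[-1]


class TestSteadySweep:
    def test_single_mean_cell_reproduces_deterministic_curves(self, totals, nf_params):
        from erkpop.cascade import sweep_steady_states

        grid = np.arange(0.0, 101.0, 10.0)
        res = pop.population_steady_sweep("NF", n_cells=1, ras_grid=grid,
                                          k_shape=1e9, seed=0)
        det = sweep_steady_states(grid, totals, nf_params)[:, 7]
        np.testing.assert_allclose(res["up"][0], det, rtol=0.02, atol=0.5)

    def test_percentile_bands_ordered(self):
        grid = np.arange(0.0, 101.0, 20.0)
        res = pop.population_steady_sweep("NF", n_cells=12, ras_grid=grid, seed=3)
        assert np.all(res["up_p5"] <= res["up_mean"] + 1e-9)
        assert np.all(res["up_mean"] <= res["up_p95"] + 1e-9)

    def test_nf_half_activation_point_varies_across_cells(self):
        grid = np.arange(0.0, 101.0, 5.0)
        res = pop.population_steady_sweep("NF", n_cells=25, ras_grid=grid, seed=11)
        ec50 = []
        for row in res["up"]:
            top = row[-1]
            if top < 50:
                continue
            ec50.append(grid[np.searchsorted(row, top / 2)])
        ec50 = np.array(ec50, float)
        assert len(ec50) >= 15
        assert ec50.std() / ec50.mean() > 0.1


class TestNormalization:
    def test_proportional_signal_collapses(self):
        tot = np.random.default_rng(0).gamma(5.4, 100, 500)
        out = pop.normalize_by_total(3.0 * tot, tot)
        np.testing.assert_allclose(out, 1.0, rtol=1e-12)

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(1)
        out = pop.normalize_by_total(rng.random(1000), rng.random(1000) + 0.5)
        assert out.mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_totals_rejected(self):
        with pytest.raises(ValueError):
            pop.normalize_by_total([1.0, 2.0], [1.0, 0.0])


class TestExperimentConfig:
    def test_yaml_roundtrip_drives_simulation(self, tmp_path):
        cfg = tmp_path / "exp.yaml"
        cfg.write_text(
            "topology: NF\nn_cells: 4\nseed: 3\ndose_indices: [4]\n"
            "times: [5.0]\nnoise:\n  mean: 10.0\n  sd: 10.0\n")
        resp = pop.run_experiment_config(cfg)
        assert resp.noisy and resp.ppERK.shape == (4, 1, 1)
        again = pop.run_experiment_config({"topology": "NF", "n_cells": 4, "seed": 3,
                                           "dose_indices": [4], "times": [5.0]})
        np.testing.assert_array_equal(resp.ppERK, again.ppERK)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            pop.run_experiment_config({"n_cells": 3})


class TestPopulationBistability:
    def test_pf_population_mean_remains_bistable(self):
        grid = np.arange(0.0, 101.0, 5.0)
        res = pop.population_steady_sweep("PF", n_cells=8, ras_grid=grid, seed=4)
        gap = np.nanmax(res["down_mean"] - res["up_mean"])
        assert gap > 50.0  # hysteresis survives averaging over cells
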