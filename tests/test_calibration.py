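"""Objective arithmetic and genetic-algorithm machinery."""

import numpy as np
import pytest

from cortexfold.calibration import (GAConfig, W1, W2, default_bounds,
                                    evolve, objective)
from cortexfold.params import ModelParameters
from cortexfold.profiles import (DensityProfile, ExperimentalDataset,
                                 PROFILE_KEYS)


def toy_dataset(n_points=20, scale=1.0, length_scale=1.0):
    rngl = np.random.default_rng(99)
    grid = np.linspace(0, 1, n_points)
    ds = ExperimentalDataset()
    profiles = {}
    for cohort, tp in PROFILE_KEYS:
        dens = scale * (1e-5 + 1e-5 * rngl.random(n_points))
        profiles[(cohort, tp)] = DensityProfile(grid, dens, 1000.0 * tp,
                                                cohort, tp)
    ds.profiles = profiles
    ds.lengths = {tp: length_scale * 1000.0 * tp for tp in (1, 2, 3)}
    return ds


class TestObjective:
    def test_weights_match_profile_and_length_counts(self):
        assert W1 == pytest.approx(11 / 8)
        assert W2 == pytest.approx(11 / 3)

    def test_zero_on_identical_inputs(self):
        ds = toy_dataset()
        sim_lengths = dict(ds.lengths)
        assert objective(ds.profiles, sim_lengths, ds) == pytest.approx(0.0)

    def test_doubled_densities_give_eleven(self):
        ds = toy_dataset()
        doubled = {k: DensityProfile(p.normalized_position, 2 * p.density,
                                     p.length, p.cohort, p.timepoint)
                   for k, p in ds.profiles.items()}
        val = objective(doubled, dict(ds.lengths), ds)
        assert val == pytest.approx(11.0, rel=1e-12)

    def test_doubled_lengths_give_eleven(self):
        ds = toy_dataset()
        lengths = {k: 2 * v for k, v in ds.lengths.items()}
        assert objective(ds.profiles, lengths, ds) == pytest.approx(
            11.0, rel=1e-12)

    def test_invariant_to_profile_term_ordering(self):
        ds = toy_dataset()
        sim = dict(ds.profiles)
        keys_fwd = tuple(sorted(ds.profiles))
        keys_rev = keys_fwd[::-1]
        a = objective(sim, dict(ds.lengths), ds, keys=keys_fwd)
        b = objective(sim, dict(ds.lengths), ds, keys=keys_rev)
        assert a == pytest.approx(b, rel=1e-14)

    def test_degenerate_dataset_rejected(self):
        ds = toy_dataset()
        key = (1, 1)
        p = ds.profiles[key]
        ds.profiles[key] = DensityProfile(p.normalized_position,
                                          np.zeros_like(p.density),
                                          p.length, 1, 1)
        with pytest.raises(ValueError, match="degenerate"):
            objective(ds.profiles, dict(ds.lengths), ds)


class TestEvolve:
    def _setup(self, n=10, g=4, seed=0):
        rng = np.random.default_rng(seed)
        bounds = np.array([[0.0, 1.0]] * g)
        pop = rng.uniform(0, 1, (n, g))
        return pop, bounds, rng

    def test_no_variation_keeps_population(self):
        pop, bounds, rng = self._setup()
        ga = GAConfig(crossover_prob=0.0, mutation_prob=0.0,
                      diff_move_prob=0.0, elitism=1)
        fit = np.arange(len(pop), dtype=float)
        nxt = evolve(pop, fit, ga, bounds, rng)
        # children are copies of tournament winners: all rows of the
        # next population already exist in the current one
        for row in nxt:
            assert any(np.allclose(row, p) for p in pop)

    def test_elitism_preserves_best(self):
        pop, bounds, rng = self._setup()
        fit = np.linspace(1, 2, len(pop))
        nxt = evolve(pop, fit, GAConfig(), bounds, rng)
        np.testing.assert_allclose(nxt[0], pop[0])

    def test_bounds_respected_over_generations(self):
        pop, bounds, rng = self._setup()
        ga = GAConfig()
        for _ in range(100):
            fit = ((pop - 0.3) ** 2).sum(axis=1)
            pop = evolve(pop, fit, ga, bounds, rng)
            assert np.all(pop >= bounds[:, 0]) and np.all(pop <= bounds[:, 1])

    def test_sphere_function_convergence(self):
        """2-parameter sphere, 10 genomes, <= 50 generations."""
        rng = np.random.default_rng(5)
        bounds = np.array([[-2.0, 2.0], [-2.0, 2.0]])
        pop = rng.uniform(-2, 2, (10, 2))
        ga = GAConfig()
        best = np.inf
        for gen in range(50):
            fit = (pop ** 2).sum(axis=1)
            best = min(best, fit.min())
            sigma = 0.1 * (0.005 / 0.1) ** (gen / 49)
            pop = evolve(pop, fit, ga, bounds, rng, sigma=sigma)
        assert best < 1e-3

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            evolve(np.empty((0, 3)), np.empty(0), GAConfig(),
                   np.array([[0, 1]] * 3), np.random.default_rng(0))


class TestSensitivityScan:
    def test_local_minimum_and_direction(self, noiseless_dataset):
        """On data generated at the center point, the objective surface
        has its minimum at the center and is far more sensitive to the
        division rate than to the diffusion coefficient."""
        from cortexfold.calibration import sensitivity_scan
        from cortexfold import ModelParameters
        ds, _ = noiseless_dataset
        table = sensitivity_scan(ds, ModelParameters(),
                                 pairs=(("Gc", "D"),), rel_range=0.2,
                                 n_grid=3, ga=GAConfig(dt=0.1))
        assert len(table) == 9
        assert np.isfinite(table.f_obj).all()
        center = table[(table.value1 == ModelParameters().Gc)
                       & (table.value2 == ModelParameters().D)]
        assert center.f_obj.iloc[0] == table.f_obj.min()
        # axis variations through the center
        gc_axis = table[table.value2 == ModelParameters().D].f_obj
        d_axis = table[table.value1 == ModelParameters().Gc].f_obj
        assert gc_axis.max() > d_axis.max()


class TestCalibrationModes:
    @pytest.fixture(scope="class")
    def small_ga(self):
        return GAConfig(dt=0.15, n_generations=10, n_elems=60)

    @pytest.fixture(scope="class")
    def dataset(self):
        from cortexfold.synthetic import (SyntheticConfig,
                                          generate_profile_dataset)
        ds, truth = generate_profile_dataset(
            SyntheticConfig(noise="none", dt=0.15))
        return ds, truth

    @pytest.fixture(scope="class")
    def three_cohort_fit(self, dataset, small_ga):
        from cortexfold.calibration import calibrate
        return calibrate(dataset[0], "three_cohort", ga=small_ga, seed=2)

    def test_best_trace_nonincreasing(self, three_cohort_fit):
        trace = three_cohort_fit.best_trace
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_leave_out_t3_validates_on_held_out_data(self, dataset,
                                                     small_ga,
                                                     three_cohort_fit):
        """Fitting on the first two timepoints still predicts the third:
        the held-out t3 misfit is finite and within 2x of the full fit's
        t3 misfit."""
        from cortexfold.calibration import (_apply_genome, calibrate,
                                            forward_profiles, objective)
        from cortexfold import ModelParameters
        ds, _ = dataset
        rec = calibrate(ds, "leave_out_t3", ga=small_ga, seed=2)
        t3_keys = tuple(k for k in sorted(ds.profiles) if k[1] == 3)

        def t3_error(record):
            p = _apply_genome(ModelParameters(), record.best_genome.names,
                              record.best_genome.values, "three_cohort")
            prof, lens = forward_profiles(p, small_ga)
            return objective(prof, lens, ds, keys=t3_keys)

        held_out = t3_error(rec)
        full_fit = t3_error(three_cohort_fit)
        assert np.isfinite(held_out) and held_out > 0
        assert held_out <= 2.0 * full_fit, (held_out, full_fit)

    def test_single_cohort_inflates_division_rate(self, dataset, small_ga,
                                                  three_cohort_fit):
        """One cohort must produce all cells of three birth pulses, so
        the recovered division rate exceeds the three-cohort one."""
        from cortexfold.calibration import calibrate
        ds, _ = dataset
        rec = calibrate(ds, "single_cohort", ga=small_ga, seed=2)
        assert rec.best_genome.as_dict()["Gc"] > \
            three_cohort_fit.best_genome.as_dict()["Gc"]

    def test_unknown_mode_rejected(self, dataset, small_ga):
        from cortexfold.calibration import calibrate
        with pytest.raises(ValueError):
            calibrate(dataset[0], "two_cohort", ga=small_ga)


class TestBounds:
    def test_literature_ranges(self):
        b = default_bounds("three_cohort", ModelParameters())
        assert b["Gc"] == (1.0e-6, 1.5e-5)
        assert b["v_base"] == (230.0, 4752.0)
        assert b["D"] == (25000.0, 35000.0)
        lo, hi = b["delta_1v"]
        assert 0 < lo < hi <= 239.0

    def test_single_cohort_genome_shape(self):
        b = default_bounds("single_cohort", ModelParameters())
        assert "delta_v" in b and "delta_1v" not in b
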