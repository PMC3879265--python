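"""Tests of the chi-square estimation pipeline."""

import numpy as np
import pytest
from scipy.stats import norm, spearmanr

from memphen.fitting import (
    FitConfig,
    ModelSpec,
    PMDispersion,
    bootstrap_parameter_sets,
    chi_square,
    combination_average,
    enumerate_model_specs,
    estimate_fixed,
    fit_cohort,
    fit_quality,
    fit_subject,
    fits_to_frame,
    grid_candidates,
    hill_climb,
    select_model,
)
from memphen.fitting import _grid_only_mean_chi2, _top_k_indices
from memphen.task_model import (
    PARAM_NAMES,
    ModelParameters,
    ParameterRanges,
    expected_pms_batch,
)


class TestChiSquare:
    def test_identity_is_zero(self, unit_dispersion):
        pm = np.arange(8.0)
        assert chi_square(pm, pm, unit_dispersion) == 0.0

    def test_one_sd_residual_is_one(self):
        disp = PMDispersion(np.full(8, 4.0))
        obs = np.zeros(8)
        mod = np.zeros(8)
        mod[2] = 2.0  # one cohort SD
        assert chi_square(obs, mod, disp) == pytest.approx(1.0)

    def test_weighted_residual(self):
        disp = PMDispersion(np.array([4.0] + [1.0] * 7))
        obs = np.zeros(8)
        mod = np.r_[1.0, np.zeros(7)]
        assert chi_square(obs, mod, disp) == pytest.approx(0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            PMDispersion(np.zeros(8))

    def test_cohort_variance_floor(self):
        constant = np.tile(np.arange(8.0), (5, 1))
        disp = PMDispersion.from_cohort(constant)
        assert np.all(disp.variances == 0.25)


class TestFitQuality:
    def test_perfect_fit(self):
        assert fit_quality(0.0, 3) == 1.0

    def test_survival_at_cohort_mean_chi2(self):
        # independent closed form for nu=3: 2*(1-Phi(sqrt(x))) + sqrt(2x/pi)*exp(-x/2)
        x = 1.5057
        closed = 2 * (1 - norm.cdf(np.sqrt(x))) + np.sqrt(2 * x / np.pi) * np.exp(-x / 2)
        assert fit_quality(x, 3) == pytest.approx(closed, abs=1e-10)
        assert fit_quality(x, 3) == pytest.approx(0.681, abs=1e-3)

    def test_critical_value(self):
        assert fit_quality(7.815, 3) == pytest.approx(0.05, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_quality(-1.0, 3)
        with pytest.raises(ValueError):
            fit_quality(1.0, 0)


class TestGrids:
    def test_full_resolution_counts(self, default_spec, ranges):
        free, fixed = grid_candidates(default_spec, ranges)
        assert free.shape == (32768, 5)
        assert fixed.shape == (64, 3)

    def test_reduced_free_levels(self, default_spec, ranges):
        free, _ = grid_candidates(default_spec, ranges, free_levels=2)
        assert free.shape == (32, 5)

    def test_level_positions(self, default_spec, ranges):
        free, fixed = grid_candidates(default_spec, ranges)
        # alpha range [0.3, 3.5]: first level at 0.3 + 3.2/16 = 0.5
        assert free[:, 0].min() == pytest.approx(0.5)
        assert free[:, 0].max() == pytest.approx(0.3 + 15 / 16 * 3.2)
        # fixed gamma range (0, 0.8]: levels at 1/8, 3/8, 5/8, 7/8 of 0.8
        assert sorted(set(np.round(fixed[:, 0], 9))) == pytest.approx(
            [0.1, 0.3, 0.5, 0.7]
        )

    def test_tie_break_is_lexicographic(self):
        free = np.array([[2.0, 1.0], [1.0, 1.0], [1.0, 2.0]])
        chi2 = np.zeros(3)
        order = _top_k_indices(chi2, free, 3)
        assert [tuple(free[i]) for i in order] == [(1, 1), (1, 2), (2, 1)]


class TestHillClimb:
    names = ("alpha", "beta")

    def quadratic(self, target):
        return lambda x: float(np.sum((x - target) ** 2))

    def test_local_minimum_returns_start(self, ranges):
        start = np.array([1.9, 1.3])
        x, fx, _ = hill_climb(start, self.quadratic(start), 0.05, ranges,
                              order_seed=1, names=self.names)
        assert np.allclose(x, start)
        assert fx == 0.0

    def test_convex_objective_reaches_lattice_optimum(self, ranges):
        """On a convex objective the endpoint coincides with the brute-force
        minimiser of the stepped lattice reachable from the start."""
        target = np.array([2.8])
        start = np.array([0.5])
        step = 0.05 * ranges["alpha"].width
        obj = self.quadratic(target)
        x, fx, _ = hill_climb(start, obj, 0.05, ranges, order_seed=3,
                              names=("alpha",))
        lattice = start[0] + step * np.arange(-100, 101)
        lattice = lattice[(lattice >= 0.3) & (lattice <= 3.5)]
        best = lattice[np.argmin((lattice - target[0]) ** 2)]
        assert x[0] == pytest.approx(best)

    def test_objective_never_increases(self, ranges):
        calls = []
        target = np.array([2.0, 2.0])
        base = self.quadratic(target)

        def recording(x):
            v = base(x)
            calls.append(v)
            return v

        _, fx, _ = hill_climb(np.array([0.5, 3.0]), recording, 0.05, ranges,
                              order_seed=5, names=self.names)
        accepted = [calls[0]]
        for v in calls[1:]:
            if v < accepted[-1]:
                accepted.append(v)
        assert fx == accepted[-1]
        assert fx <= calls[0]

    def test_same_seed_same_trajectory(self, ranges):
        res1 = hill_climb(np.array([0.5, 3.0]), self.quadratic(np.array([2, 2])),
                          0.05, ranges, order_seed=7, names=self.names)
        res2 = hill_climb(np.array([0.5, 3.0]), self.quadratic(np.array([2, 2])),
                          0.05, ranges, order_seed=7, names=self.names)
        assert np.allclose(res1[0], res2[0]) and res1[1] == res2[1]


class TestFitSubject:
    def test_self_consistency_recovery(self, default_spec, unit_dispersion, ranges):
        """Fitting noise-free expected PMs recovers the generating free
        parameters to within 2% of each range."""
        true = ModelParameters(alpha=1.93, beta=1.27, gamma=0.5, eps_pos=1.3,
                               eps_neg=1.12, sigma=0.7, c=1.95, s=4.133)
        obs = expected_pms_batch(true.to_array()[None, :])[0]
        cfg = FitConfig.from_preset("desk", seed=3)
        fr = fit_subject(obs, default_spec, unit_dispersion, cfg)
        assert fr.chi2 < 0.1
        for name in default_spec.free_names:
            err = abs(getattr(fr.best_params, name) - getattr(true, name))
            assert err <= 0.02 * ranges[name].width

    def test_chi2_not_worse_than_grid(self, default_spec, unit_dispersion):
        from memphen.fitting import _GridCache

        obs = np.array([8, 8, 7, 1, 7, 7, 6, 1], dtype=float)
        cfg = FitConfig.from_preset("desk", seed=1, n_starts=3)
        grid = _GridCache(default_spec, cfg)
        fr = fit_subject(obs, default_spec, unit_dispersion, cfg, grid=grid)
        grid_min = np.min(np.sum((grid.pms - obs) ** 2, axis=1))
        assert fr.chi2 <= grid_min + 1e-12
        assert fr.nu == 3
        assert fr.top_sets == tuple(sorted(fr.top_sets, key=lambda t: t[1]))

    def test_deterministic_rerun(self, default_spec, unit_dispersion):
        obs = np.array([8, 8, 7, 1, 7, 7, 6, 1], dtype=float)
        cfg = FitConfig.from_preset("desk", seed=2, n_starts=3)
        a = fit_subject(obs, default_spec, unit_dispersion, cfg)
        b = fit_subject(obs, default_spec, unit_dispersion, cfg)
        assert a.chi2 == b.chi2
        assert a.best_params == b.best_params


@pytest.fixture(scope="module")
def noise_free_cohort():
    from memphen.synthetic_data import CohortSpec, child_rng, generate_parameters

    cs = CohortSpec.table1(n_subjects=10, master_seed=7)
    dosage = child_rng(7, 0).choice([0.0, 1.0, 2.0], size=10,
                                    p=[0.455, 0.442, 0.103])
    truth = generate_parameters(cs, dosage, seed=7)
    theta = np.stack([p.to_array() for p in truth.parameters])
    return expected_pms_batch(theta)


@pytest.fixture(scope="module")
def estimate(noise_free_cohort):
    spec = ModelSpec(free_names=("alpha", "beta", "c", "eps_pos", "eps_neg"))
    cfg = FitConfig.from_preset("desk", seed=7, free_levels=3,
                                n_fixed_keep=2, n_starts=3)
    return estimate_fixed(noise_free_cohort, spec, cfg), cfg


class TestEstimateFixed:
    def test_fit_as_good_as_truth(self, noise_free_cohort, estimate):
        """The recovered fixed values fit the cohort at least as well as
        the true generating fixed values (the fixed-parameter objective is
        flat, so point recovery is not identifiable)."""
        est, cfg = estimate
        true_spec = ModelSpec(
            free_names=("alpha", "beta", "c", "eps_pos", "eps_neg"),
            fixed_values={"gamma": 0.5, "sigma": 0.7, "s": 4.133},
        )
        disp = PMDispersion.from_cohort(noise_free_cohort)
        fits_true = fit_cohort(noise_free_cohort, true_spec, disp, cfg)
        mean_true = float(np.mean([f.chi2 for f in fits_true]))
        assert est.mean_chi2 <= mean_true * 1.02 + 1e-6

    def test_stage_monotonicity(self, estimate):
        """Cohort-mean chi2 never increases from screening to final fits."""
        est, _ = estimate
        assert est.mean_chi2 <= est.screening["mean_chi2_grid"].min() + 1e-9

    def test_mean_is_arithmetic_mean(self, estimate):
        est, _ = estimate
        assert est.mean_chi2 == pytest.approx(
            np.mean([f.chi2 for f in est.fits])
        )

    def test_screening_invariant_under_subject_order(self, noise_free_cohort):
        spec = ModelSpec(
            free_names=("alpha", "beta", "c", "eps_pos", "eps_neg"),
            fixed_values={"gamma": 0.5, "sigma": 0.7, "s": 4.133},
        )
        cfg = FitConfig.from_preset("desk", seed=1, free_levels=3)
        disp = PMDispersion.from_cohort(noise_free_cohort)
        a = _grid_only_mean_chi2(noise_free_cohort, spec, disp, cfg)
        b = _grid_only_mean_chi2(noise_free_cohort[::-1], spec, disp, cfg)
        assert a == pytest.approx(b)


class TestModelSelection:
    def test_enumeration_size_and_partitions(self):
        specs = enumerate_model_specs()
        assert len(specs) == 56
        seen = set()
        for s in specs:
            assert len(s.free_names) == 5
            assert set(s.free_names) | set(s.fixed_names) == set(PARAM_NAMES)
            assert not set(s.free_names) & set(s.fixed_names)
            seen.add(frozenset(s.free_names))
        assert len(seen) == 56

    def test_mocked_evaluator_ranking(self):
        pm = np.tile(np.array([8, 8, 7, 1, 7, 7, 6, 1.0]), (10, 1))
        pm += np.random.default_rng(0).normal(0, 1, size=pm.shape)
        scores = {}

        def evaluator(spec):
            val = float(17 + 13 * hash(spec.free_names) % 97)
            scores[spec.free_names] = val
            return val

        table = select_model(pm, evaluator=evaluator)
        assert len(table) == 56
        best = min(scores, key=scores.get)
        assert tuple(table["free"].iloc[0]) == best
        assert table["mean_chi2"].is_monotonic_increasing
        assert list(table["refine"][:2]) == [True, True]

    def test_invalid_partitions_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(free_names=("alpha", "beta", "c", "eps_pos"))
        with pytest.raises(ValueError):
            ModelSpec(free_names=("alpha", "beta", "c", "eps_pos", "eps_neg"),
                      fixed_values={"alpha": 1.0})


class TestCombinationAverage:
    def test_full_subset_count(self):
        rng = np.random.default_rng(0)
        sets = [rng.uniform(0.5, 1.5, size=3) for _ in range(10)]
        target = np.array([1.0, 1.0, 1.0])
        best, score, table = combination_average(
            sets, lambda v: float(np.sum((v - target) ** 2))
        )
        assert len(table) == 1023
        assert score <= table["score"].min() + 1e-15
        assert score <= min(float(np.sum((s - target) ** 2)) for s in sets)

    def test_singleton(self):
        best, score, table = combination_average(
            [np.array([1.0, 2.0, 3.0])], lambda v: float(v.sum())
        )
        assert len(table) == 1
        assert np.allclose(best, [1, 2, 3])

    def test_identical_inputs_constant_score(self):
        sets = [np.array([1.0, 2.0, 3.0])] * 4
        _, _, table = combination_average(sets, lambda v: float(v.sum()))
        assert len(table) == 15
        assert np.allclose(table["score"], 6.0)


class TestBootstrap:
    def test_degenerate_resampling(self):
        sets = [np.tile(np.arange(8.0) + i, (10, 1)) for i in range(3)]
        samples = list(bootstrap_parameter_sets(sets, n_samples=5, seed=0))
        for s in samples:
            assert s.shape == (3, 8)
            assert np.allclose(s, samples[0])

    def test_seeded_stream_reproducible(self):
        rng = np.random.default_rng(1)
        sets = [rng.normal(size=(10, 8)) for _ in range(4)]
        a = list(bootstrap_parameter_sets(sets, n_samples=20, seed=3))
        b = list(bootstrap_parameter_sets(sets, n_samples=20, seed=3))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_subject_rejected(self):
        with pytest.raises(ValueError):
            list(bootstrap_parameter_sets([np.empty((0, 8))], n_samples=1))


class TestFittedValuesRespectRanges:
    def test_fits_stay_inside_ranges(self, small_cohort, default_spec, ranges):
        _, _, _, pm_table, _ = small_cohort
        cfg = FitConfig.from_preset("desk", seed=21, n_starts=3,
                                    free_levels=3)
        fits = fit_cohort(pm_table.to_numpy()[:8], default_spec, config=cfg)
        frame = fits_to_frame(fits)
        for name in PARAM_NAMES:
            iv = ranges[name]
            assert frame[name].between(iv.lo - 1e-9, iv.hi + 1e-9).all()
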