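"""NSGA-II machinery, objectives, and target fixtures."""

import numpy as np
import pytest

from autoshape.fitting import (
    GAConfig,
    TargetCurves,
    _dominates,
    crowding_distance,
    fast_non_dominated_sort,
    fit_nsga2,
    objectives,
    recovery_report,
)
from autoshape.protocols import AgentConfig, GroupSpec, Schedule, _run_group
from autoshape.targets import (
    SyntheticTargetSpec,
    make_shape_target,
    make_target,
    read_target_csv,
    write_target_csv,
)


def test_target_curve_validation():
    with pytest.raises(ValueError):
        TargetCurves((0.5, 0.5), (0.5,))
    with pytest.raises(ValueError):
        TargetCurves((1.5,), (0.5,))


class TestSortingMachinery:
    def test_non_dominated_sort_hand_example(self):
        F = np.array([[1, 1], [2, 2], [0.5, 3], [3, 0.5], [2, 1]])
        fronts = fast_non_dominated_sort(F)
        assert sorted(fronts[0]) == [0, 2, 3]
        assert sorted(fronts[1]) == [4]
        assert sorted(fronts[2]) == [1]

    def test_dominance_definition(self):
        assert _dominates(np.array([1, 1]), np.array([1, 2]))
        assert not _dominates(np.array([1, 2]), np.array([2, 1]))
        assert not _dominates(np.array([1, 1]), np.array([1, 1]))

    def test_crowding_boundary_points_infinite(self):
        F = np.array([[0, 3], [1, 2], [2, 1], [3, 0]], dtype=float)
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[3])
        assert np.isfinite(d[1]) and np.isfinite(d[2])


class TestObjectives:
    def test_non_negative_and_symmetric_zero(self):
        target = make_shape_target("ST")
        f = objectives(AgentConfig(), target, reps=2, seed=0)
        assert f[0] >= 0 and f[1] >= 0

    def test_self_consistency_small_at_truth(self):
        """A target generated by the candidate itself scores near zero."""
        spec = SyntheticTargetSpec(config=AgentConfig(omega=0.8), n_agents=200, seed=3)
        target = make_target(spec)
        lever, mag = objectives(AgentConfig(omega=0.8), target, reps=100, seed=9)
        assert lever < 0.005 and mag < 0.005
        # a wrong candidate scores clearly worse
        lever_bad, mag_bad = objectives(AgentConfig(omega=0.05), target, reps=100, seed=9)
        assert lever_bad > 10 * lever

    def test_curve_length_mismatch_raises(self):
        target = make_shape_target("ST", n_blocks=6)
        with pytest.raises(ValueError, match="mismatch"):
            objectives(AgentConfig(), target, schedule=Schedule(4, 25), reps=1, seed=0)


def test_fast_engine_statistically_matches_reference():
    """The compiled curve engine and the reference trial loop agree on
    group-mean engagement curves within Monte-Carlo tolerance."""
    from autoshape._fastsim import HAVE_NUMBA, simulate_group_curves

    if not HAVE_NUMBA:
        # reference path is then the only engine; nothing to cross-check
        return
    cfg = AgentConfig(omega=0.5)
    ref = _run_group(GroupSpec("x", 150, cfg), Schedule(), [5], collect_rpes=False)
    rl, _ = ref.engagement_curve("lever")
    rm, _ = ref.engagement_curve("magazine")
    fl, fm = simulate_group_curves(cfg, 150, 8, 25, [6])
    assert np.all(np.abs(rl - fl) < 0.05)
    assert np.all(np.abs(rm - fm) < 0.05)


class TestFitNSGA2:
    def test_one_generation_structure(self):
        target = make_shape_target("ST")
        ga = GAConfig(population=4, generations=1, reps=1, seed=0,
                      draws_per_generation=1)
        fit = fit_nsga2(target, ga, param_names=("omega",))
        assert fit.front_params.shape[1] == 1
        assert len(fit.front_objectives) == len(fit.front_params)
        assert 0.0 <= fit.representative["omega"] <= 1.0

    def test_front_is_mutually_non_dominated(self):
        target = make_shape_target("GT")
        ga = GAConfig(population=8, generations=3, reps=2, seed=1,
                      draws_per_generation=1)
        fit = fit_nsga2(target, ga, param_names=("omega", "beta"))
        F = fit.front_objectives
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j:
                    assert not _dominates(F[i], F[j])

    def test_deterministic_given_seed(self):
        target = make_shape_target("ST")
        ga = GAConfig(population=4, generations=2, reps=1, seed=5,
                      draws_per_generation=1)
        f1 = fit_nsga2(target, ga, param_names=("omega",))
        f2 = fit_nsga2(target, ga, param_names=("omega",))
        assert np.array_equal(f1.front_params, f2.front_params)
        assert f1.representative == f2.representative

    def test_shape_targets_order_recovered_omega(self):
        """A goal-tracking-shaped target is explained by a lower feature
        weight than a sign-tracking-shaped one."""
        ga = GAConfig(population=12, generations=8, reps=3, seed=0,
                      draws_per_generation=1)
        st = fit_nsga2(make_shape_target("ST"), ga, param_names=("omega",))
        gt = fit_nsga2(make_shape_target("GT"), ga, param_names=("omega",))
        assert gt.representative["omega"] < st.representative["omega"]

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            fit_nsga2(make_shape_target("ST"), GAConfig(population=2, generations=1),
                      param_names=("nonexistent",))

    def test_population_must_be_even(self):
        with pytest.raises(ValueError):
            GAConfig(population=5)


def test_recovery_report_rows_and_bias():
    target = make_shape_target("ST")
    ga = GAConfig(population=4, generations=1, reps=1, seed=0, draws_per_generation=1)
    fit = fit_nsga2(target, ga, param_names=("omega", "u"))
    rows = recovery_report({"omega": 0.8}, fit)
    assert len(rows) == 2
    om = next(r for r in rows if r["parameter"] == "omega")
    assert om["bias"] == pytest.approx(om["estimate"] - 0.8)
    assert 0.0 <= om["estimate"] <= 1.0


class TestTargets:
    def test_reproducible(self):
        spec = SyntheticTargetSpec(n_agents=5, noise_sd=0.05, seed=4)
        assert make_target(spec) == make_target(spec)

    def test_zero_noise_equals_simulation(self):
        spec = SyntheticTargetSpec(n_agents=5, seed=4)
        noisy = SyntheticTargetSpec(n_agents=5, noise_sd=0.1, seed=4)
        assert make_target(spec) != make_target(noisy)
        assert all(0 <= x <= 1 for x in make_target(noisy).lever)

    def test_st_spec_target_ends_lever_dominant(self):
        t = make_target(SyntheticTargetSpec(config=AgentConfig(omega=0.8),
                                            n_agents=14, seed=0))
        assert t.lever[-1] > t.magazine[-1]

    def test_shape_targets_monotone_and_mirrored(self):
        st = make_shape_target("ST", n_blocks=5)
        gt = make_shape_target("GT", n_blocks=5)
        assert list(st.lever) == sorted(st.lever)
        assert list(st.magazine) == sorted(st.magazine, reverse=True)
        assert st.lever == gt.magazine and st.magazine == gt.lever
        assert all(0 <= x <= 1 for x in (*st.lever, *st.magazine))

    def test_csv_roundtrip(self, tmp_path):
        t = make_shape_target("ST")
        path = tmp_path / "target.csv"
        write_target_csv(t, path)
        assert read_target_csv(path) == t
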