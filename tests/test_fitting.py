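import numpy as np
import pytest

import floatnr as F
from floatnr.fitting import FitProblem, ReflectivityDataset, fit_global, fit_local

from conftest import simulate_joint


class TestDataset:
    def test_validation(self, d2o):
        q = np.array([0.01, 0.02, 0.03])
        with pytest.raises(ValueError, match="equal lengths"):
            ReflectivityDataset(q, q[:2], q, contrast=d2o)
        with pytest.raises(ValueError, match="strictly positive"):
            ReflectivityDataset(q, q, np.array([1e-3, 0.0, 1e-3]), contrast=d2o)
        with pytest.raises(ValueError, match="ascending"):
            ReflectivityDataset(q[::-1], q, q, contrast=d2o)
        with pytest.raises(ValueError, match="phase"):
            ReflectivityDataset(q, q, q, contrast=d2o, phase="wet")

    def test_default_name_and_dq(self, d2o):
        q = np.array([0.01, 0.02])
        ds = ReflectivityDataset(q, q, q, contrast=d2o, condition="Ca",
                                 dq=0.035 * q)
        assert ds.name == "Ca:D2O"
        assert ds.dq_over_q() == pytest.approx(0.035)


class TestChiSquared:
    def test_definition_single_point(self, ground_truth, d2o):
        # one point whose residual is 2 sigma contributes exactly 4
        q = np.array([0.05])
        grid = F.QGrid(q, 0.0)
        r_model = F.model_reflectivity(
            ground_truth.underlayers, None, d2o, grid, background=1e-6
        )
        ds = ReflectivityDataset(
            q, r_model + 2e-8, np.array([1e-8]), contrast=d2o, phase="bare",
            dq=np.zeros(1),
        )
        prob = FitProblem(ground_truth.underlayers, [ds])
        assert prob.chi_squared() == pytest.approx(4.0, rel=1e-6)

    def test_zero_for_self_generated_noise_free_data(
        self, ground_truth, small_instrument
    ):
        ds = simulate_joint(ground_truth, small_instrument, 3,
                            counting_time=np.inf)
        prob = FitProblem(
            ground_truth.underlayers, ds,
            membranes={"Ca": ground_truth.membranes["Ca"]},
        )
        assert prob.chi_squared() < 1e-12

    def test_invariant_to_dataset_order(self, ground_truth, small_instrument):
        ds = simulate_joint(ground_truth, small_instrument, 4)
        a = FitProblem(ground_truth.underlayers, ds,
                       membranes={"Ca": ground_truth.membranes["Ca"]})
        b = FitProblem(ground_truth.underlayers, ds[::-1],
                       membranes={"Ca": ground_truth.membranes["Ca"]})
        assert a.chi_squared() == pytest.approx(b.chi_squared(), rel=1e-12)

    def test_warns_without_bare_datasets(self, ground_truth, small_instrument):
        ds = simulate_joint(ground_truth, small_instrument, 5, bare=False,
                            contrasts=("D2O",))
        with pytest.warns(UserWarning, match="bare"):
            FitProblem(ground_truth.underlayers, ds,
                       membranes={"Ca": ground_truth.membranes["Ca"]})

    def test_membrane_dataset_requires_model(self, ground_truth,
                                             small_instrument):
        ds = simulate_joint(ground_truth, small_instrument, 5, bare=False,
                            contrasts=("D2O",))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="membrane"):
                FitProblem(ground_truth.underlayers, ds)


class TestSharedParameters:
    def test_underlayers_shared_across_all_datasets(self, ground_truth,
                                                    small_instrument):
        ds = simulate_joint(ground_truth, small_instrument, 6)
        prob = FitProblem(ground_truth.underlayers, ds,
                          membranes={"Ca": ground_truth.membranes["Ca"]})
        names = [p.name for p in prob.parameters()]
        # one shared copy of each under-layer parameter despite 6 datasets
        assert names.count("sam_coverage") == 1
        assert names.count("gold_thickness") == 1
        # per-dataset nuisance parameters exist for each dataset
        assert sum(n.startswith("scale[") for n in names) == 6

    def test_moving_shared_parameter_changes_every_curve(
        self, ground_truth, small_instrument
    ):
        ds = simulate_joint(ground_truth, small_instrument, 7)
        prob = FitProblem(ground_truth.underlayers, ds,
                          membranes={"Ca": ground_truth.membranes["Ca"]})
        before = [prob.model_for(e).copy() for e in prob.entries]
        prob.find_parameter("gold_thickness").value = 120.0
        after = [prob.model_for(e) for e in prob.entries]
        for b, a in zip(before, after):
            assert not np.allclose(b, a)


class TestFitting:
    def test_all_fixed_global_fit_is_noop(self, ground_truth,
                                          small_instrument):
        ds = simulate_joint(ground_truth, small_instrument, 8,
                            conditions=(), bare=True)
        prob = FitProblem(ground_truth.underlayers, ds)
        chi0 = prob.chi_squared()
        res = fit_global(prob, seed=1)
        assert res.fun == pytest.approx(chi0)
        assert res.nfev == 0

    def test_unbounded_varying_parameter_rejected(self, ground_truth,
                                                  small_instrument):
        ds = simulate_joint(ground_truth, small_instrument, 8,
                            conditions=(), bare=True)
        prob = FitProblem(ground_truth.underlayers, ds)
        p = prob.find_parameter("gold_thickness")
        p.vary = True
        p.bounds = (0, np.inf)
        with pytest.raises(ValueError, match="bounded"):
            fit_global(prob, seed=1)

    def test_single_parameter_recovery_matches_grid_scan(
        self, ground_truth, small_instrument
    ):
        # noise-free single-contrast problem, interlayer free: the global
        # fit must land on the grid-scan optimum (the generating value)
        ds = simulate_joint(ground_truth, small_instrument, 9, bare=False,
                            contrasts=("D2O",), counting_time=np.inf)
        fit_gt = F.default_ground_truth()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prob = FitProblem(fit_gt.underlayers, ds,
                              membranes={"Ca": fit_gt.membranes["Ca"]})
        p = prob.find_parameter("interlayer_thickness")
        p.vary = True
        p.bounds = (5, 20)

        grid = np.linspace(5, 20, 151)
        chis = []
        for v in grid:
            p.value = v
            chis.append(prob.chi_squared())
        grid_best = grid[int(np.argmin(chis))]
        assert grid_best == pytest.approx(11.0, abs=0.1)

        fit_global(prob, seed=2, maxiter=30)
        fit_local(prob)
        assert p.value == pytest.approx(11.0, abs=0.1)

    def test_local_fit_monotone_and_stationary_at_truth(
        self, ground_truth, small_instrument
    ):
        ds = simulate_joint(ground_truth, small_instrument, 10,
                            conditions=(), bare=True,
                            counting_time=np.inf)
        prob = FitProblem(ground_truth.underlayers, ds)
        for name in ("sam_thickness", "sam_coverage"):
            prob.find_parameter(name).vary = True
        start = prob.varying_values()
        chi0 = prob.chi_squared()
        fit_local(prob)
        assert prob.chi_squared() <= chi0 + 1e-12
        assert np.allclose(prob.varying_values(), start, atol=1e-6)

    def test_local_fit_rejects_out_of_bounds_start(self, ground_truth,
                                                   small_instrument):
        ds = simulate_joint(ground_truth, small_instrument, 10,
                            conditions=(), bare=True)
        prob = FitProblem(ground_truth.underlayers, ds)
        prob.find_parameter("sam_thickness").vary = True
        with pytest.raises(ValueError, match="bounds"):
            fit_local(prob, start=np.array([1000.0]))

    def test_noise_free_three_parameter_fit_reaches_machine_chi2(self):
        # frozen scale/background, noise-free data: global+local must find
        # chi2 < 1e-6 x N on a 3-parameter bare-surface problem
        truth = F.default_ground_truth()
        inst = F.InstrumentSpec("INTER-lite", (1.0, 16.0), (0.7, 2.3),
                                n_bins=60)
        ds = simulate_joint(truth, inst, 11, conditions=(), bare=True,
                            counting_time=np.inf)
        fit_gt = F.default_ground_truth()
        prob = FitProblem(fit_gt.underlayers, ds)
        for name, bounds in [("sam_thickness", (15, 35)),
                             ("sam_coverage", (0.6, 1.0)),
                             ("gold_thickness", (60, 140))]:
            p = prob.find_parameter(name)
            p.vary = True
            p.bounds = bounds
        fit_global(prob, seed=3, popsize=10, maxiter=40)
        fit_local(prob)
        assert prob.chi_squared() < 1e-6 * prob.n_points
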