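import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from floatnr.kernel import (
    QGrid,
    Slab,
    _abeles_numpy,
    _stack_arrays,
    abeles_reflectivity,
    apply_scale_background,
    qz_from_angle,
    smear_fixed_dlogq,
    smear_gaussian,
)

SI, D2O = 2.07, 6.36
QC_SI_D2O = np.sqrt(16 * np.pi * (D2O - SI) * 1e-6)  # critical edge


def fresnel_single_interface(q, rho_front, rho_back):
    """Independent closed-form |r|² for one sharp interface."""
    k0 = q / 2.0
    k1 = np.sqrt((q / 2.0) ** 2 - 4e-6 * np.pi * (rho_back - rho_front) + 0j)
    return np.abs((k0 - k1) / (k0 + k1)) ** 2


class TestQz:
    @pytest.mark.parametrize(
        "theta, lam, expected",
        [(0.7, 16.0, 0.009596), (1.5, 0.5, 0.6580)],
    )
    def test_formula(self, theta, lam, expected):
        assert qz_from_angle(theta, lam) == pytest.approx(expected, rel=1e-3)

    def test_zero_angle_limit(self):
        assert qz_from_angle(0.0, 4.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            qz_from_angle(0.7, -1.0)
        with pytest.raises(ValueError):
            qz_from_angle(95.0, 4.0)


class TestAbeles:
    def test_uniform_medium_reflects_nothing(self):
        slabs = [Slab(0, 3.0), Slab(50, 3.0), Slab(0, 3.0)]
        r = abeles_reflectivity(slabs, np.array([0.01, 0.05, 0.2]))
        assert np.allclose(r, 0.0)

    def test_total_reflection_below_critical_edge(self):
        slabs = [Slab(0, SI), Slab(0, D2O)]
        q = np.linspace(0.005, QC_SI_D2O * 0.999, 20)
        r = abeles_reflectivity(slabs, q)
        assert np.allclose(r, 1.0, atol=1e-12)

    @pytest.mark.parametrize("q", [2 * QC_SI_D2O, 0.1, 0.3])
    def test_fresnel_closed_form(self, q):
        slabs = [Slab(0, SI), Slab(0, D2O)]
        r = abeles_reflectivity(slabs, np.array([q]))
        assert r[0] == pytest.approx(fresnel_single_interface(q, SI, D2O), rel=1e-10)

    def test_needs_two_slabs(self):
        with pytest.raises(ValueError):
            abeles_reflectivity([Slab(0, SI)], np.array([0.1]))

    def test_zero_thickness_slab_is_invisible(self):
        q = np.geomspace(0.01, 0.3, 50)
        base = [Slab(0, SI), Slab(100, 4.5, 3), Slab(0, D2O)]
        padded = [Slab(0, SI), Slab(0.0, 8.0), Slab(100, 4.5, 3), Slab(0, D2O)]
        assert np.allclose(
            abeles_reflectivity(base, q), abeles_reflectivity(padded, q),
            rtol=1e-12,
        )

    def test_reciprocity_of_reversed_stack(self):
        # reversing stack and beam direction preserves |r|^2 when compared
        # at the corresponding in-medium wavevectors: the nominal Q is
        # defined in the incident medium, so (Q'/2)² = (Q/2)² − 4πΔρ maps
        # the reversed measurement onto the forward one
        q = np.geomspace(0.05, 0.3, 40)
        fwd = [Slab(0, SI), Slab(80, 8.5, 0), Slab(30, 1.0, 0), Slab(0, D2O)]
        rev = [Slab(0, D2O), Slab(30, 1.0, 0), Slab(80, 8.5, 0), Slab(0, SI)]
        q_rev = 2 * np.sqrt((q / 2) ** 2 - 4e-6 * np.pi * (D2O - SI))
        assert np.allclose(
            abeles_reflectivity(fwd, q), abeles_reflectivity(rev, q_rev),
            rtol=1e-8,
        )

    def test_reflectivity_decays_at_high_q(self):
        slabs = [Slab(0, SI, 3), Slab(100, 4.5, 3), Slab(0, D2O)]
        r = abeles_reflectivity(slabs, np.array([0.05, 0.3, 1.0, 3.0]))
        assert np.all(np.diff(r) < 0)
        assert r[-1] < 1e-12

    @given(
        st.lists(
            st.tuples(st.floats(5, 150), st.floats(-0.5, 8.5), st.floats(0, 3)),
            min_size=0, max_size=4,
        )
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_bounded_between_zero_and_one(self, layers):
        slabs = (
            [Slab(0, SI, 2)]
            + [Slab(t, s, r) for t, s, r in layers]
            + [Slab(0, D2O)]
        )
        r = abeles_reflectivity(slabs, np.geomspace(0.005, 0.4, 60))
        assert np.all(r >= 0) and np.all(r <= 1.0)

    def test_numba_and_numpy_paths_agree(self):
        slabs = [Slab(0, SI, 2), Slab(80, 8.5, 3), Slab(25, 0.9, 3), Slab(0, D2O)]
        q = np.geomspace(0.009, 0.3, 80)
        d, rho, sigma = _stack_arrays(slabs)
        from floatnr.kernel import _abeles

        assert np.allclose(
            _abeles(q, d, rho, sigma**2),
            _abeles_numpy(q, d, rho, sigma**2),
            rtol=1e-12,
        )


class TestRoughnessModels:
    @pytest.mark.parametrize(
        "slabs",
        [
            [Slab(0, SI, 3), Slab(120, 3.47, 3), Slab(0, D2O)],
            [Slab(0, SI, 2), Slab(80, 8.5, 3), Slab(100, 4.5, 3),
             Slab(25, 1.0, 3), Slab(0, D2O)],
        ],
    )
    def test_nevot_croce_matches_microslice_at_small_roughness(self, slabs):
        q = np.geomspace(0.009, 0.3, 120)
        nc = abeles_reflectivity(slabs, q, "nevot_croce")
        ms = abeles_reflectivity(slabs, q, "microslice")
        assert np.max(np.abs(nc / ms - 1)) < 1e-3

    def test_microslice_converges_with_slice_width(self):
        slabs = [Slab(0, SI, 3), Slab(120, 3.47, 3), Slab(0, D2O)]
        q = np.geomspace(0.009, 0.3, 60)
        coarse = abeles_reflectivity(slabs, q, "microslice", dz=1.0)
        fine = abeles_reflectivity(slabs, q, "microslice", dz=0.125)
        assert np.max(np.abs(coarse / fine - 1)) < 2e-4

    def test_hybrid_matches_full_microslice_in_sliced_region(self):
        # large roughness relative to thickness forces slicing
        slabs = [Slab(0, SI, 2), Slab(80, 8.5, 3), Slab(100, 4.5, 3),
                 Slab(25, 1.0, 9), Slab(11, D2O, 7), Slab(30, 0.2, 7),
                 Slab(0, D2O)]
        q = np.geomspace(0.009, 0.3, 100)
        hy = abeles_reflectivity(slabs, q, "hybrid")
        ms = abeles_reflectivity(slabs, q, "microslice")
        assert np.max(np.abs(hy / ms - 1)) < 5e-3

    def test_auto_uses_plain_nc_when_valid(self):
        slabs = [Slab(0, SI, 2), Slab(120, 3.47, 3), Slab(0, D2O)]
        q = np.geomspace(0.01, 0.2, 40)
        assert np.array_equal(
            abeles_reflectivity(slabs, q, "auto"),
            abeles_reflectivity(slabs, q, "nevot_croce"),
        )

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            abeles_reflectivity(
                [Slab(0, SI), Slab(0, D2O)], np.array([0.1]), "bogus"
            )


class TestSmearing:
    def brute_force(self, fn, q, dq_over_q, width=5.0, n=801):
        out = np.empty_like(q)
        for i, qi in enumerate(q):
            s = dq_over_q * qi / 2.355
            x = np.linspace(qi - width * s, qi + width * s, n)
            w = np.exp(-0.5 * ((x - qi) / s) ** 2)
            w /= w.sum()
            out[i] = np.sum(w * fn(np.maximum(x, 1e-8)))
        return out

    def test_zero_resolution_is_identity(self):
        q = QGrid(np.geomspace(0.01, 0.2, 30), 0.0)
        fn = lambda x: np.exp(-x)
        assert np.array_equal(smear_gaussian(fn, q), fn(q.q_values))
        assert np.array_equal(smear_fixed_dlogq(fn, q), fn(q.q_values))

    def test_constant_curve_unchanged(self):
        q = QGrid(np.geomspace(0.01, 0.2, 30), 0.035)
        smeared = smear_gaussian(lambda x: np.full_like(x, 0.25), q)
        assert np.allclose(smeared, 0.25, rtol=1e-12)

    def test_kiessig_fringes_damped_toward_brute_force_oracle(self):
        # 500 Å film: resolution smearing must damp fringe contrast
        slabs = [Slab(0, SI), Slab(500, 4.0, 0), Slab(0, D2O)]
        fn = lambda x: abeles_reflectivity(slabs, x)
        q = QGrid(np.geomspace(0.012, 0.1, 80), 0.035)
        smeared = smear_gaussian(fn, q)
        oracle = self.brute_force(fn, q.q_values, 0.035)
        assert np.max(np.abs(smeared / oracle - 1)) < 2e-2
        # fringe amplitude is reduced relative to the unsmeared curve
        raw = fn(q.q_values)
        assert np.std(np.log(smeared[20:])) < np.std(np.log(raw[20:]))

    def test_fast_log_grid_path_matches_brute_force(self):
        slabs = [Slab(0, SI, 3), Slab(120, 3.47, 3), Slab(0, D2O)]
        fn = lambda x: abeles_reflectivity(slabs, x)
        q = QGrid(np.geomspace(0.012, 0.25, 80), 0.035)
        fast = smear_fixed_dlogq(fn, q)
        oracle = self.brute_force(fn, q.q_values, 0.035)
        assert np.max(np.abs(fast / oracle - 1)) < 2e-2


class TestScaleBackground:
    def test_identity_and_offset(self):
        r = np.array([1.0, 0.0, 1e-4])
        assert np.array_equal(apply_scale_background(r, 1.0, 0.0), r)
        assert apply_scale_background(np.array([0.0]), 1.0, 1e-6)[0] == 1e-6
        assert apply_scale_background(np.array([1.0]), 0.95, 0.0)[0] == 0.95

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            apply_scale_background(np.array([1.0]), 0.0, 0.0)
        with pytest.raises(ValueError):
            apply_scale_background(np.array([1.0]), 1.0, -1e-9)


class TestQGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            QGrid(np.array([0.1, 0.05]))
        with pytest.raises(ValueError):
            QGrid(np.array([-0.1, 0.05]))
        with pytest.raises(ValueError):
            QGrid(np.array([0.05, 0.1]), dq_over_q=-0.1)

    def test_slab_validation(self):
        with pytest.raises(ValueError):
            Slab(-1.0, 2.0)
        with pytest.raises(ValueError):
            Slab(1.0, 2.0, roughness=-0.5)
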