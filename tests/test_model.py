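"""Unit and property tests for the algebraic laws of the bone model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteofatigue import (
    BoneState,
    LoadingCondition,
    ModelParameters,
    damage_formation_rate,
    damage_per_cycle,
    damage_repair_rate,
    fatigue_life,
    formation_activity,
    model_rhs,
    preset,
    resorption_activity,
    specific_surface,
    strain_energy_density,
    tissue_stiffness,
)
from osteofatigue.params import load_parameters, save_parameters


class TestSpecificSurface:
    @pytest.mark.parametrize(
        "fBM, expected",
        [(1.0, 0.0), (0.9, 3.6185), (0.5, 8.1561)],
    )
    def test_closed_form(self, fitted, fBM, expected):
        assert specific_surface(fBM, fitted) == pytest.approx(expected, abs=2e-4)

    def test_positive_on_open_interval(self, fitted):
        for f in np.linspace(0.01, 0.99, 50):
            assert specific_surface(f, fitted) > 0

    def test_domain_error(self, fitted):
        with pytest.raises(ValueError):
            specific_surface(1.2, fitted)
        with pytest.raises(ValueError):
            specific_surface(-0.1, fitted)


class TestTissueStiffness:
    def test_reference_stiffness(self, fitted):
        # trained bone (fBM = 0.9) at a 0.36 1/s test strain rate
        assert tissue_stiffness(0.9, 0.36, fitted) == pytest.approx(1714.1, abs=0.1)

    def test_unit_arguments_give_E0(self, fitted):
        assert tissue_stiffness(1.0, 1.0, fitted) == pytest.approx(fitted.E0)

    def test_training_strain_rate(self, fitted):
        assert tissue_stiffness(0.9, 0.2974, fitted) == pytest.approx(1694.7, rel=1e-3)

    def test_monotone_in_both_arguments(self, fitted):
        E = [tissue_stiffness(f, 0.3, fitted) for f in (0.5, 0.7, 0.9)]
        assert E[0] < E[1] < E[2]
        E = [tissue_stiffness(0.9, s, fitted) for s in (0.05, 0.2, 0.4)]
        assert E[0] < E[1] < E[2]

    def test_rejects_nonpositive_strain_rate(self, fitted):
        with pytest.raises(ValueError):
            tissue_stiffness(0.9, 0.0, fitted)


class TestStrainEnergyDensity:
    @pytest.mark.parametrize(
        "sigma, E, expected",
        [(90.0, 1714.1, 2.36), (0.0, 1000.0, 0.0), (30.0, 1451.6, 0.31)],
    )
    def test_values(self, sigma, E, expected):
        assert strain_energy_density(sigma, E) == pytest.approx(expected, abs=5e-3)

    def test_rejects_nonpositive_stiffness(self):
        with pytest.raises(ValueError):
            strain_energy_density(90.0, 0.0)


class TestActivities:
    def test_formation_limits(self, fitted):
        assert formation_activity(0.0, fitted) == pytest.approx(fitted.AOBL_min)
        half = (fitted.AOBL_min + fitted.AOBL_max) / 2
        assert formation_activity(fitted.deltaB, fitted) == pytest.approx(half)

    def test_formation_at_racing_signal(self, fitted):
        assert formation_activity(2.36, fitted) == pytest.approx(2.3386e-3, rel=1e-3)

    def test_resorption_limits(self, fitted):
        assert resorption_activity(0.0, fitted) == pytest.approx(fitted.AOCL_max)
        half = (fitted.AOCL_min + fitted.AOCL_max) / 2
        assert resorption_activity(fitted.deltaC, fitted) == pytest.approx(half)

    def test_rest_training_resorption_ratio(self, initial_preset):
        # resting bone remodels about four times faster than bone in full
        # training, the tuning anchor of the resorption Hill curve
        ratio = resorption_activity(0.31, initial_preset) / resorption_activity(
            2.36, initial_preset
        )
        assert ratio == pytest.approx(4.014, abs=0.01)

    def test_monotonicity_and_bounds(self, fitted):
        grid = np.linspace(0.0, 20.0, 200)
        obl = np.array([formation_activity(x, fitted) for x in grid])
        ocl = np.array([resorption_activity(x, fitted) for x in grid])
        assert np.all(np.diff(obl) >= 0)
        assert np.all(np.diff(ocl) <= 0)
        assert np.all((obl >= fitted.AOBL_min) & (obl <= fitted.AOBL_max))
        assert np.all((ocl >= fitted.AOCL_min) & (ocl <= fitted.AOCL_max))

    def test_fractional_sigmoidicity_defined_at_zero(self, fitted):
        params = fitted.replace(gammaB=0.5)
        assert formation_activity(0.0, params) == pytest.approx(params.AOBL_min)


class TestFatigueLife:
    def test_reference_point(self, fitted):
        assert fatigue_life(fitted.sigma0, fitted.Enom, fitted) == pytest.approx(1.0)
        assert fatigue_life(
            fitted.sigma0 - fitted.sigma1, fitted.Enom, fitted
        ) == pytest.approx(10.0)

    def test_training_stress(self, fitted):
        assert fatigue_life(90.0, 1694.6, fitted) == pytest.approx(2952.6, rel=1e-3)
        assert damage_per_cycle(90.0, 1694.6, fitted) == pytest.approx(3.387e-4, rel=1e-3)

    def test_strictly_decreasing_in_stress(self, fitted):
        lives = [fatigue_life(s, fitted.Enom, fitted) for s in (60, 80, 100, 120)]
        assert all(a > b for a, b in zip(lives, lives[1:]))

    @settings(derandomize=True, max_examples=50)
    @given(
        sigma=st.floats(0.0, 150.0),
        E=st.floats(100.0, 4000.0),
    )
    def test_reciprocal_identity(self, sigma, E):
        p = preset("fitted")
        product = damage_per_cycle(sigma, E, p) * fatigue_life(sigma, E, p)
        assert product == pytest.approx(1.0, rel=1e-12)

    def test_tension_rejected(self):
        with pytest.raises(ValueError):
            LoadingCondition(sigma=-10.0, strain_rate=0.3)


class TestDamageRates:
    @pytest.mark.parametrize(
        "vD, vn, expected", [(3.387e-4, 43.7, 0.0148), (1.0, 0.0, 0.0), (1.0, 1.0, 1.0)]
    )
    def test_formation(self, vD, vn, expected):
        assert damage_formation_rate(vD, vn) == pytest.approx(expected, rel=1e-2)

    def test_repair_zero_without_damage(self, fitted):
        state = BoneState(fBM=0.9, D=0.0)
        assert damage_repair_rate(0.002, 0.001, 3.6, state, fitted) == 0.0

    def test_untargeted_resorption_repairs_nothing(self, fitted):
        # Fs = 1 and no formation: resorption alone cannot remove damage
        params = fitted.replace(Fs=1.0)
        state = BoneState(fBM=0.9, D=0.5)
        assert damage_repair_rate(0.0, 0.01, 3.6, state, params) == 0.0

    def test_closed_form(self, fitted):
        state = BoneState(fBM=0.9, D=0.5)
        rate = damage_repair_rate(0.002350, 0.001384, 3.6185, state, fitted)
        assert rate == pytest.approx(3.0121e-3, rel=1e-3)

    def test_linear_in_damage(self, fitted):
        r1 = damage_repair_rate(0.002, 0.0015, 3.6, BoneState(0.9, 0.25), fitted)
        r2 = damage_repair_rate(0.002, 0.0015, 3.6, BoneState(0.9, 0.5), fitted)
        r4 = damage_repair_rate(0.002, 0.0015, 3.6, BoneState(0.9, 1.0), fitted)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)
        assert r4 == pytest.approx(4 * r1, rel=1e-12)


class TestModelRhs:
    def test_composite_high_workload(self, fitted):
        bundle = model_rhs(
            0.0,
            BoneState(fBM=0.9, D=0.0),
            LoadingCondition(sigma=90.0, strain_rate=0.2974, vn=43.7),
            fitted,
        )
        assert bundle.dD_dt == pytest.approx(0.014801, rel=2e-3)
        assert bundle.dfBM_dt == pytest.approx(6.64e-4, rel=5e-3)
        assert bundle.Dr == 0.0

    def test_full_bone_has_no_remodelling(self, fitted):
        bundle = model_rhs(
            0.0,
            BoneState(fBM=1.0, D=0.5),
            LoadingCondition(sigma=60.0, strain_rate=0.3, vn=40.0),
            fitted,
        )
        assert bundle.Sv == 0.0
        assert bundle.dfBM_dt == 0.0
        assert bundle.Dr == 0.0

    def test_balance_point_is_stationary(self, fitted):
        from scipy.optimize import brentq

        psi_star = brentq(
            lambda x: formation_activity(x, fitted) - resorption_activity(x, fitted),
            1e-6, 20.0,
        )
        f = 0.9
        E = tissue_stiffness(f, 0.2974, fitted)
        sigma = math.sqrt(2 * E * psi_star)
        bundle = model_rhs(
            0.0, BoneState(f, 0.0),
            LoadingCondition(sigma=sigma, strain_rate=0.2974, vn=0.0), fitted,
        )
        assert bundle.dfBM_dt == pytest.approx(0.0, abs=1e-12)


class TestParameters:
    def test_fitted_preset_defaults(self, fitted):
        assert (fitted.AOBL_max, fitted.AOCL_max, fitted.sigma0) == (
            0.00603, 0.00358, 139.0,
        )

    def test_initial_preset(self, initial_preset):
        assert (initial_preset.AOBL_max, initial_preset.AOCL_max,
                initial_preset.sigma0) == (0.0127, 0.011, 134.2)

    @pytest.mark.parametrize(
        "bad",
        [
            {"alpha": 0.0},
            {"alpha": 1.5},
            {"AOBL_max": 0.0001},  # below AOBL_min
            {"Fs": 0.5},
            {"sigma1": -1.0},
        ],
    )
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            BoneState(fBM=0.0)
        with pytest.raises(ValueError):
            BoneState(fBM=0.5, D=1.5)

    def test_config_round_trip(self, fitted, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(fitted.replace(sigma0=140.5), path)
        loaded = load_parameters(path)
        assert loaded.sigma0 == 140.5
        assert loaded == fitted.replace(sigma0=140.5)

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "params.yaml"
        path.write_text("sigma0: 139.0\nnot_a_parameter: 1\n")
        with pytest.raises(KeyError):
            load_parameters(path)
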