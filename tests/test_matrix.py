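"""Power-law interaction matrix: fluxes, calibration, integration, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neuromobile as nm
from neuromobile.matrix import DEFAULT_KINETIC_ORDERS
from neuromobile.transmitters import TRANSMITTERS, N_TRANSMITTERS

ONES = nm.TransmitterProfile(np.ones(6))


class TestProductionFlux:
    def test_baseline_dopamine_flux_balances_printed_degradation(self, model):
        # at steady state production equals k_DA * 100 = 790.1101
        flux = nm.production_flux(model.baseline, model.orders, "DA")
        assert flux == pytest.approx(790.1101, abs=0.1)

    @pytest.mark.parametrize("target", TRANSMITTERS)
    def test_unit_profile_gives_unit_flux(self, target):
        assert nm.production_flux(ONES, DEFAULT_KINETIC_ORDERS, target) == pytest.approx(1.0)

    def test_zero_orders_give_empty_product(self, model):
        zero = np.zeros((6, 6))
        assert nm.production_flux(model.baseline, zero, "Glu") == 1.0

    def test_nonpositive_intensity_rejected_naming_transmitter(self):
        with pytest.raises(ValueError, match="NA"):
            nm.TransmitterProfile([100, 100, 0, 100, 200, 150])
        with pytest.raises(ValueError, match="Glu"):
            nm.TransmitterProfile([100, 100, 100, 100, -5, 150])


class TestDerivatives:
    def test_baseline_is_steady_state(self, model):
        dx = nm.derivatives(model.baseline, model)
        assert np.all(np.abs(dx) < 1e-6 * model.baseline.values)

    def test_doubled_gaba_production_adds_one_production_flux(self, model):
        mods = nm.ModifierSet.from_dict(production={"GABA": 2.0})
        dx = nm.derivatives(model.baseline, model, mods)
        i = TRANSMITTERS.index("GABA")
        k_gaba = model.rates[i]
        assert dx[i] == pytest.approx(k_gaba * 150.0, rel=1e-9)
        others = np.delete(dx, i)
        assert np.all(np.abs(others) < 1e-6)

    def test_doubled_glu_degradation_removes_one_degradation_flux(self, model):
        mods = nm.ModifierSet.from_dict(degradation={"Glu": 2.0})
        dx = nm.derivatives(model.baseline, model, mods)
        i = TRANSMITTERS.index("Glu")
        assert dx[i] == pytest.approx(-model.rates[i] * 200.0, rel=1e-9)

    def test_nonpositive_modifier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            nm.ModifierSet.from_dict(production={"DA": 0.0})


class TestCalibration:
    @pytest.mark.parametrize(
        "transmitter,printed", sorted(nm.PRINTED_DEGRADATION_RATES.items())
    )
    def test_reproduces_printed_rate_constants(self, transmitter, printed):
        rates = nm.calibrate_degradation(nm.DEFAULT_BASELINE, DEFAULT_KINETIC_ORDERS)
        k = rates[TRANSMITTERS.index(transmitter)]
        assert k == pytest.approx(printed, rel=1e-4)

    def test_unit_baseline_zero_orders_gives_unit_rates(self):
        rates = nm.calibrate_degradation(ONES, np.zeros((6, 6)))
        assert np.allclose(rates, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        logs=st.lists(st.floats(-2, 2), min_size=6, max_size=6),
        orders=st.lists(
            st.floats(-0.5, 0.5), min_size=36, max_size=36
        ),
    )
    def test_calibration_roundtrip_zeroes_derivatives(self, logs, orders):
        """Calibrated rates make any positive baseline a fixed point of any orders."""
        baseline = nm.TransmitterProfile(np.exp(np.array(logs)))
        g = np.array(orders).reshape(6, 6)
        np.fill_diagonal(g, 0.0)
        model = nm.MatrixModel.from_baseline(baseline, g)
        dx = nm.derivatives(baseline, model)
        assert np.all(np.abs(dx) < 1e-9 * np.maximum(baseline.values, 1.0))


class TestIntegrate:
    def test_unit_schedule_stays_at_baseline(self, model):
        schedule = nm.ModifierSchedule.unit(0.0, 100.0)
        traj = nm.integrate(model, schedule)
        rel = np.abs(traj.values / model.baseline.values - 1.0)
        assert np.max(rel) < 1e-3

    def test_acute_phase_raises_gaba_and_lowers_glu(self, alcohol_result):
        profile = alcohol_result.phase_end_profile("acute")
        baseline = alcohol_result.model.baseline
        assert profile["GABA"] > baseline["GABA"]
        assert profile["Glu"] < baseline["Glu"]

    def test_tolerance_refinement_leaves_trajectory_unchanged(self, model, tree):
        schedule = nm.build_alcohol_timeline()
        coarse = nm.integrate(model, schedule, grid_dt=0.5)
        fine = nm.integrate(model, schedule, grid_dt=0.5, rtol=1e-10, atol=1e-12)
        rel = np.abs(fine.values / coarse.values - 1.0)
        assert np.max(rel) < 1e-4

    def test_positivity_preserved_under_strong_perturbation(self, model):
        schedule = nm.build_alcohol_timeline(alpha=1.5, gamma=1.5)
        traj = nm.integrate(model, schedule)
        assert np.all(traj.values > 0)

    def test_grid_contains_phase_boundaries(self, alcohol_result):
        times = alcohol_result.trajectory.times
        for t in alcohol_result.schedule.boundaries().values():
            assert np.any(np.isclose(times, t, atol=1e-12))


class TestSteadyState:
    def test_unit_modifiers_return_baseline(self, model):
        ss = nm.find_steady_state(model)
        assert np.allclose(ss.values, model.baseline.values, rtol=1e-8)

    def test_equal_production_and_degradation_folds_cancel(self, model):
        mods = nm.ModifierSet.from_dict(
            production={"GABA": 1.7}, degradation={"GABA": 1.7}
        )
        ss = nm.find_steady_state(model, mods)
        assert np.allclose(ss.values, model.baseline.values, rtol=1e-8)

    def test_matches_long_time_integration(self, model):
        """Root-finding agrees with integrating to ten times the slowest timescale."""
        mods = nm.ModifierSet.from_dict(
            production={"GABA": 1.3, "Glu": 1 / 1.3}, degradation={"NA": 1.1}
        )
        ss = nm.find_steady_state(model, mods)
        horizon = 10.0 / model.rates.min()
        schedule = nm.ModifierSchedule((nm.Phase("hold", 0.0, horizon, mods),))
        traj = nm.integrate(model, schedule, grid_dt=horizon / 200, rtol=1e-10, atol=1e-12)
        assert np.allclose(traj.values[-1], ss.values, rtol=1e-6)

    def test_residual_below_tolerance(self, model):
        mods = nm.ModifierSet.from_dict(production={"DA": 1.4})
        ss = nm.find_steady_state(model, mods)
        dx = nm.derivatives(ss, model, mods)
        assert np.max(np.abs(dx) / ss.values) < 1e-9


def test_production_jacobian_has_kinetic_order_sign_pattern(model):
    """Activation/inhibition structure of the network survives into the dynamics."""
    x0 = model.baseline.values
    eps = 1e-6
    for j in range(N_TRANSMITTERS):
        bumped = x0.copy()
        bumped[j] *= 1 + eps
        f0 = np.array([
            nm.production_flux(model.baseline, model.orders, t) for t in TRANSMITTERS
        ])
        f1 = np.array([
            nm.production_flux(nm.TransmitterProfile(bumped), model.orders, t)
            for t in TRANSMITTERS
        ])
        jac_col = (f1 - f0) / (x0[j] * eps)
        assert np.all(np.sign(np.round(jac_col, 12)) == np.sign(model.orders[:, j]))


def test_model_rejects_uncalibrated_rates():
    with pytest.raises(ValueError, match="steady state"):
        nm.MatrixModel(
            orders=DEFAULT_KINETIC_ORDERS,
            rates=np.ones(6),
            baseline=nm.DEFAULT_BASELINE,
        )
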