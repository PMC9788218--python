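"""Tumor-response models: kill dynamics, volume delay, impaired regrowth."""

import numpy as np
import pytest

from trtsim import (
    DoseInput,
    InvalidInputError,
    TumorParams,
    ellipsoid_volume,
    lambda_mod,
    run_scenarios,
    simulate_cells_basic,
    simulate_full,
)


class TestLambdaMod:
    @pytest.mark.parametrize(
        "dose,expected",
        [(0.0, 0.14), (1.0, 0.07), (9.7, 0.14 / (1 + 9.7**0.25))],
    )
    def test_values(self, dose, expected):
        assert lambda_mod(0.14, dose) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_dose(self):
        doses = np.linspace(0.0, 30.0, 100)
        assert np.all(np.diff(lambda_mod(0.14, doses)) < 0.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(InvalidInputError):
            lambda_mod(0.14, -1.0)


class TestBasicKillModel:
    def test_unirradiated_exponential_growth(self, params_exponential):
        """With no dose and no saturation the cell count grows as e^{λt}."""
        t = np.linspace(0.0, 10.0, 51)
        N = simulate_cells_basic(params_exponential, DoseInput.zero(), t)
        expected = params_exponential.N0 * np.exp(0.14 * t)
        assert np.max(np.abs(N / expected - 1.0)) < 1e-7

    @pytest.mark.parametrize("total", [1.0, 5.0, 9.7, 20.0])
    def test_impulse_survival_converges_to_exponential_kill(
        self, params_exponential, total
    ):
        """Narrowing pulses of fixed total dose D drive the post-pulse
        survival to the closed form e^{-bD}."""
        expected = np.exp(-params_exponential.b * total)
        errs = []
        for width in (1e-1, 1e-2, 1e-3):
            t = np.array([0.0, width, 1.0])
            N = simulate_cells_basic(
                params_exponential, DoseInput.pulse(total, width), t
            )
            errs.append(abs(N[1] / params_exponential.N0 / expected - 1.0))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_kill_integral_invariance(self, params_exponential):
        """Halving the kill coefficient while doubling the dose leaves the
        kill integral b*D, hence the impulse survival, unchanged."""
        w = 1e-3
        t = np.array([0.0, w, 1.0])
        half_b = TumorParams(b=0.15, Nm=np.inf)
        n_half = simulate_cells_basic(half_b, DoseInput.pulse(19.4, w), t)
        n_full = simulate_cells_basic(params_exponential,
                                      DoseInput.pulse(9.7, w), t)
        assert n_half[1] == pytest.approx(n_full[1], rel=1e-6)

    def test_regrowth_slope_returns_to_control_rate(
        self, params_exponential, dose_1mbq
    ):
        """After the dose is spent the log-slope equals λ again (N << Nm):
        surviving cells resume proliferation at the control rate."""
        t = np.linspace(0.0, 20.0, 201)
        N = simulate_cells_basic(params_exponential, dose_1mbq, t)
        late = t >= 10.0
        slope = np.polyfit(t[late], np.log(N[late]), 1)[0]
        assert slope == pytest.approx(0.14, rel=0.01)

    def test_grid_must_start_at_zero(self, params):
        with pytest.raises(InvalidInputError):
            simulate_cells_basic(params, DoseInput.zero(), [1.0, 2.0])


class TestFullModel:
    def test_control_limit_is_exponential(self, params_exponential):
        t = np.linspace(0.0, 10.0, 101)
        traj = simulate_full(params_exponential, DoseInput.zero(), t)
        expected = params_exponential.V0 * np.exp(0.14 * t)
        assert np.max(np.abs(traj.V / expected - 1.0)) < 1e-6
        assert np.all(traj.N_D == 0.0)

    def test_initial_condition(self, params, dose_1mbq):
        traj = simulate_full(params, dose_1mbq, np.linspace(0.0, 5.0, 11))
        assert traj.V[0] == pytest.approx(params.V0)
        assert traj.V_D[0] == 0.0

    def test_volume_is_sum_of_live_and_damaged(self, params, dose_1mbq):
        traj = simulate_full(params, dose_1mbq, np.linspace(0.0, 40.0, 81))
        np.testing.assert_allclose(traj.V, traj.V_L + traj.V_D, rtol=1e-12)
        for comp in (traj.N, traj.N_D, traj.V_L, traj.V_D):
            assert np.all(comp >= 0.0)

    def test_flags_off_reduce_to_basic_model(self, params, dose_1mbq):
        t = np.linspace(0.0, 30.0, 61)
        traj = simulate_full(params, dose_1mbq, t, use_lambda_mod=False,
                             use_delay=False)
        N = simulate_cells_basic(params, dose_1mbq, t)
        np.testing.assert_allclose(traj.V, params.v * N, rtol=1e-6)

    def test_longtime_slope_is_dose_impaired_rate(
        self, params_exponential, dose_1mbq
    ):
        """Once the dose is complete, the live-volume log-slope settles at
        λ_mod evaluated at the final cumulative dose (~9.7 Gy)."""
        t = np.linspace(0.0, 60.0, 241)
        traj = simulate_full(params_exponential, dose_1mbq, t)
        late = t >= 50.0
        slope = np.polyfit(t[late], np.log(traj.V_L[late]), 1)[0]
        assert slope == pytest.approx(lambda_mod(0.14, dose_1mbq.total),
                                      rel=0.005)

    def test_larger_total_dose_slows_regrowth(self, params_exponential,
                                              rates, conv):
        t = np.linspace(0.0, 60.0, 121)
        slopes = []
        for q in (0.1, 0.4, 1.0):
            tab = run_scenarios([q], rates, conv, params_exponential, 60.0)
            late = tab[tab.t_day >= 50.0]
            slopes.append(np.polyfit(late.t_day, np.log(late.V_L), 1)[0])
        assert slopes[0] > slopes[1] > slopes[2]

    def test_continuous_clearance_approximates_literal_delay(
        self, params, dose_1mbq
    ):
        """The continuous damaged-volume balance dV_D/dt = v b d N - c V_D
        must track the literal delayed form closely, since irradiation
        (<1 day) is much faster than clearance (1/c = 10 days)."""
        t = np.linspace(0.0, 40.0, 81)
        literal = simulate_full(params, dose_1mbq, t)
        cont = simulate_full(params, dose_1mbq, t, continuous_clearance=True)
        late = t >= 2.0
        assert np.max(np.abs(cont.V[late] / literal.V[late] - 1.0)) < 0.05


class TestScenarios:
    def test_control_scenario_reproduces_logistic_growth(self, rates, conv,
                                                         params):
        tab = run_scenarios([0.0], rates, conv, params, 40.0)
        # logistic closed form: V(t) = Vm / (1 + (Vm/V0 - 1) e^{-λt})
        t = tab.t_day.to_numpy()
        expected = params.Vm / (
            1.0 + (params.Vm / params.V0 - 1.0) * np.exp(-params.lam * t)
        )
        assert np.max(np.abs(tab.V.to_numpy() / expected - 1.0)) < 1e-6

    def test_final_volume_monotone_in_activity(self, rates, conv, params):
        tab = run_scenarios([0.0, 0.02, 0.1, 0.4, 1.0, 2.0], rates, conv,
                            params, 40.0)
        day40 = tab[tab.t_day == 40.0].sort_values("activity_mbq")
        assert np.all(np.diff(day40.V.to_numpy()) < 0.0)

    def test_nadir_is_later_at_higher_activity(self, rates, conv, params):
        tab = run_scenarios([0.1, 1.0], rates, conv, params, 40.0)
        nadir = {
            q: sub.t_day.to_numpy()[np.argmin(sub.V.to_numpy())]
            for q, sub in tab.groupby("activity_mbq")
        }
        assert nadir[1.0] > nadir[0.1]

    def test_negative_activity_rejected(self, rates, conv, params):
        with pytest.raises(InvalidInputError):
            run_scenarios([-0.1], rates, conv, params, 10.0)


class TestEllipsoidVolume:
    def test_sphere_limit(self):
        assert ellipsoid_volume(10.0, 10.0) == pytest.approx(
            np.pi * 10.0**3 / 6.0
        )

    def test_cubic_scaling(self):
        assert ellipsoid_volume(14.0, 8.0) == pytest.approx(
            8.0 * ellipsoid_volume(7.0, 4.0)
        )

    @pytest.mark.parametrize("length,width", [(5.0, 10.0), (10.0, 0.0),
                                              (0.0, 0.0)])
    def test_invalid_axes_rejected(self, length, width):
        with pytest.raises(InvalidInputError):
            ellipsoid_volume(length, width)


def test_dose_input_unit_round_trip(dose_1mbq, rates, conv):
    """The per-day dose input must integrate to the same total dose the
    dosimetry layer reports in Gy, regardless of the hour/day unit path."""
    from trtsim import total_dose

    t = np.linspace(0.0, 10.0, 20001)
    integral = np.trapezoid(dose_1mbq.rate(t), t)
    assert integral == pytest.approx(total_dose(rates, 1.0, conv), rel=1e-3)
    assert dose_1mbq.total == pytest.approx(total_dose(rates, 1.0, conv),
                                            rel=1e-3)
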