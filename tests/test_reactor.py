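"""Reactor mass balances: derivatives, schedules, events, derived quantities."""

import numpy as np
import pytest

from lacferm.kinetics import GrowthParams, OrganismParams, qu25_table1
from lacferm.reactor import (
    ConcentrationEvent,
    FeedSpec,
    OperatingPhase,
    ReactorState,
    concentration_event,
    consumed_ratio,
    detect_steady_state,
    productivity,
    simulate_schedule,
    simulate_to_steady_state,
    state_derivatives,
)
from lacferm.steady_state import SteadyStateQuery, effluent_substrate, steady_biomass
from lacferm.stoich import YieldSet


def _glucose_params_rounded_yields(K_D=0.02):
    """Glucose kinetics with the tabulated (rounded) mass yields 0.038/0.950."""
    return OrganismParams(
        per_sugar={"glucose": GrowthParams(mu_max=1.20, Ks=55.6, Kis=108.3, Kip=1.8)},
        yields={"glucose": YieldSet(0.06053, 0.038, 0.950)},
        K_D=K_D,
    )


BATCH = OperatingPhase(mode="batch", duration=10.0)


class TestStateDerivatives:
    def test_batch_glucose_worked_example(self):
        params = _glucose_params_rounded_yields()
        state = ReactorState(S_glu=50.0, X=1.0)
        ds = state_derivatives(state, BATCH, params)
        assert ds[0] == pytest.approx(-12.270, abs=1e-3)  # dS_glu/dt
        assert ds[3] == pytest.approx(0.44626, abs=1e-5)  # dX/dt
        assert ds[4] == pytest.approx(11.657, abs=1e-3)  # dS_la/dt

    def test_washout_fixed_point(self):
        params = qu25_table1(sugars=("glucose",))
        phase = OperatingPhase(
            mode="cfstr", duration=5.0, D=0.3, feed=FeedSpec(S_glu=100.0)
        )
        ds = state_derivatives(ReactorState(S_glu=100.0), phase, params)
        assert ds[3] == 0.0  # X = X_in = 0 stays zero
        np.testing.assert_allclose(ds, [0.0, 0.0, 0.0, 0.0, 0.0])

    def test_sugar_without_params_raises(self):
        params = qu25_table1(sugars=("glucose",))
        with pytest.raises(ValueError, match="cellobiose"):
            state_derivatives(ReactorState(S_cel=10.0), BATCH, params)


class TestSimulateSchedule:
    def test_all_zero_init_stays_zero(self, qu25):
        res = simulate_schedule([BATCH], ReactorState(), qu25)
        assert np.all(res.states == 0.0)

    def test_batch_exhaustion_matches_yield_arithmetic(self):
        params = qu25_table1(sugars=("glucose",), K_D=0.0)
        res = simulate_schedule(
            [OperatingPhase(mode="batch", duration=200.0)],
            ReactorState(S_glu=10.0, X=0.5),
            params,
        )
        f = res.final_state
        yx = params.yields["glucose"]
        assert f.S_glu < 1e-4
        assert f.X == pytest.approx(0.5 + yx.cell_mass_yield * 10.0, abs=1e-4)
        assert f.S_la == pytest.approx(yx.lactate_mass_yield * 10.0, abs=1e-3)
        # headline numbers at the tabulated precision
        assert f.X == pytest.approx(0.88, abs=0.005)
        assert f.S_la == pytest.approx(9.5, abs=0.01)

    def test_batch_conservation_identities_at_all_times(self):
        """With K_D = 0, biomass and lactate track consumed sugar exactly."""
        params = qu25_table1(K_D=0.0)
        init = ReactorState(S_glu=20.0, S_cel=30.0, S_xyl=15.0, X=0.2)
        res = simulate_schedule(
            [OperatingPhase(mode="batch", duration=30.0)], init, params
        )
        consumed = {
            s: init.as_array()[i] - res.states[:, i]
            for i, s in enumerate(("glucose", "cellobiose", "xylose"))
        }
        x_pred = init.X + sum(
            params.yields[s].cell_mass_yield * consumed[s] for s in consumed
        )
        la_pred = sum(
            params.yields[s].lactate_mass_yield * consumed[s] for s in consumed
        )
        np.testing.assert_allclose(res.states[:, 3], x_pred, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(res.states[:, 4], la_pred, rtol=1e-6, atol=1e-8)

    def test_trajectory_nonnegative_and_time_increasing(self, qu25):
        res = simulate_schedule(
            [
                OperatingPhase(mode="batch", duration=12.0),
                OperatingPhase(
                    mode="cfstr",
                    duration=30.0,
                    D=0.2,
                    feed=FeedSpec(S_cel=50.0, S_xyl=30.0),
                ),
            ],
            ReactorState(S_cel=50.0, S_xyl=30.0, X=0.1),
            qu25,
        )
        assert np.all(res.states >= 0.0)
        assert np.all(np.diff(res.time) > 0)
        assert res.time[-1] == pytest.approx(42.0)

    def test_washout_above_critical_dilution(self):
        params = qu25_table1(sugars=("glucose",), K_D=0.02)
        phase = OperatingPhase(
            mode="cfstr", duration=80.0, D=1.3, feed=FeedSpec(S_glu=50.0)
        )  # D > mu_max - K_D = 1.18
        res = simulate_schedule([phase], ReactorState(S_glu=50.0, X=2.0), params)
        assert res.final_state.X < 1e-6
        assert res.final_state.S_glu == pytest.approx(50.0, rel=1e-3)

    def test_cfstr_long_run_matches_closed_form(self):
        """Inhibition-free chemostat converges to the analytic steady state."""
        growth = GrowthParams(mu_max=1.20, Ks=55.6)
        params = OrganismParams(
            per_sugar={"glucose": growth},
            yields=qu25_table1().yields,
            K_D=0.02,
        )
        D = 0.25
        phase = OperatingPhase(
            mode="cfstr", duration=10.0, D=D, feed=FeedSpec(S_glu=100.0)
        )
        state = simulate_to_steady_state(
            phase, ReactorState(S_glu=100.0, X=0.5), params, rel_tol=1e-11
        )
        q = SteadyStateQuery(
            growth=growth,
            K_D=0.02,
            CRT=1 / D,
            HRT=1 / D,
            S_in=100.0,
            cell_mass_yield=params.yields["glucose"].cell_mass_yield,
        )
        assert state.S_glu == pytest.approx(effluent_substrate(q), rel=1e-6)
        assert state.X == pytest.approx(steady_biomass(q), rel=1e-6)

    def test_cell_recycle_beats_cfstr_at_equal_dilution(self, qu25):
        """Retention raises steady biomass and lowers residual sugar."""
        params = qu25_table1(K_D=0.02)
        feed = FeedSpec(S_cel=50.0, S_xyl=30.0)
        init = ReactorState(S_cel=50.0, S_xyl=30.0, X=0.5)
        for D in (0.1, 0.2):
            cfstr = simulate_to_steady_state(
                OperatingPhase(mode="cfstr", duration=1.0, D=D, feed=feed),
                init,
                params,
                rel_tol=1e-9,
            )
            cfcr = simulate_to_steady_state(
                OperatingPhase(
                    mode="cfcr", duration=1.0, D=D, cell_passes_membrane=0.0, feed=feed
                ),
                init,
                params,
                rel_tol=1e-9,
                max_time=4000.0,
            )
            assert cfcr.X > cfstr.X
            assert cfcr.S_cel + cfcr.S_xyl < cfstr.S_cel + cfstr.S_xyl


class TestEventsAndDerived:
    def test_concentration_event_scales_cells_only(self):
        s = ReactorState(S_cel=12.0, S_xyl=3.0, X=2.0, S_la=30.0)
        out = concentration_event(s, 10.0)
        assert out.X == 20.0
        assert (out.S_cel, out.S_xyl, out.S_la) == (12.0, 3.0, 30.0)
        assert concentration_event(s, 1.0) == s
        assert concentration_event(ReactorState(X=2.18), 10.0).X == pytest.approx(21.8)
        with pytest.raises(ValueError):
            concentration_event(s, 0.5)

    @pytest.mark.parametrize(
        "s_la, d, expected",
        [(23.4, 0.25, 5.85), (65.15, 0.2, 13.03), (0.0, 0.3, 0.0)],
    )
    def test_productivity(self, s_la, d, expected):
        assert productivity(s_la, d) == pytest.approx(expected, abs=5e-3)

    def test_consumed_ratio(self):
        assert consumed_ratio(2.64, 27.5) == pytest.approx(0.096, abs=5e-4)
        assert consumed_ratio(0.0, 10.0) == 0.0
        assert consumed_ratio(11.7, 21.8) == pytest.approx(0.537, abs=5e-4)
        with pytest.raises(ZeroDivisionError):
            consumed_ratio(1.0, 0.0)


class TestDetectSteadyState:
    def _const_result(self, qu25):
        return simulate_schedule([BATCH], ReactorState(), qu25)

    def test_constant_trajectory_detected_immediately(self, qu25):
        res = self._const_result(qu25)
        det = detect_steady_state(res, window=2.0, rel_tol=1e-6)
        assert det is not None
        assert det[0] == res.time[0]

    def test_growing_culture_never_steady(self):
        params = qu25_table1(sugars=("cellobiose",))
        res = simulate_schedule(
            [OperatingPhase(mode="batch", duration=6.0)],
            ReactorState(S_cel=100.0, X=0.05),
            params,
        )
        assert detect_steady_state(res, window=3.0, rel_tol=1e-4) is None

    def test_cfstr_detection_matches_closed_form(self):
        growth = GrowthParams(mu_max=1.20, Ks=55.6)
        params = OrganismParams(
            per_sugar={"glucose": growth}, yields=qu25_table1().yields, K_D=0.02
        )
        D = 0.25
        res = simulate_schedule(
            [OperatingPhase(mode="cfstr", duration=400.0, D=D, feed=FeedSpec(S_glu=100.0))],
            ReactorState(S_glu=100.0, X=0.5),
            params,
        )
        det = detect_steady_state(res, window=20.0, rel_tol=1e-4)
        assert det is not None
        _, state = det
        q = SteadyStateQuery(
            growth=growth, K_D=0.02, CRT=1 / D, HRT=1 / D, S_in=100.0,
            cell_mass_yield=params.yields["glucose"].cell_mass_yield,
        )
        assert state.S_glu == pytest.approx(effluent_substrate(q), rel=1e-3)
        assert state.X == pytest.approx(steady_biomass(q), rel=1e-3)


class TestPhaseValidation:
    def test_batch_requires_zero_dilution(self):
        with pytest.raises(ValueError, match="D must be 0 iff"):
            OperatingPhase(mode="batch", duration=5.0, D=0.1)
        with pytest.raises(ValueError, match="D must be 0 iff"):
            OperatingPhase(mode="cfstr", duration=5.0, D=0.0)

    def test_cfstr_requires_full_cell_passage(self):
        with pytest.raises(ValueError, match="cell_passes_membrane"):
            OperatingPhase(mode="cfstr", duration=5.0, D=0.1, cell_passes_membrane=0.5)

    def test_mode_defaults(self):
        assert OperatingPhase(mode="cfstr", duration=1.0, D=0.1).cell_passes_membrane == 1.0
        assert OperatingPhase(mode="cfcr", duration=1.0, D=0.1).cell_passes_membrane == 0.0

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            ReactorState(S_glu=-1.0)
        with pytest.raises(ValueError):
            FeedSpec(S_cel=-2.0)
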