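"""Kinetic model construction: closure, steady states, labelling curves."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.integrate import solve_ivp

from memokin.datamodel import ExperimentDesign
from memokin.models import (
    ClosureError,
    KineticParameters,
    LabellingSolver,
    ModelTopology,
    _AffinePropagator,
    _build_system,
    close_parameters,
    ki67_equilibrium_fraction,
    solve_labelling,
    stationarity_residual,
    steady_state,
)

TWO_POOL = [ModelTopology.BRANCHED, ModelTopology.LINEAR, ModelTopology.BURST]


def _homog(eps=0.8, beta=0.3226, alpha=0.045, f=0.005):
    return KineticParameters(
        epsilon=eps, beta=beta, alpha_fast=alpha, alpha_slow=0.0,
        f=f, N_fast=1.0, N_slow=0.0,
    )


class TestClosure:
    def test_homogeneous_balance(self):
        # single pool: influx + division balances loss, delta = f + alpha
        c = close_parameters(_homog(), ModelTopology.BRANCHED)
        assert c.delta_fast == pytest.approx(0.05, abs=1e-12)

    def test_all_zero_rates(self):
        p = KineticParameters(
            epsilon=0.5, beta=0.3, alpha_fast=0.0, alpha_slow=0.0,
            f=0.0, N_fast=1.0, N_slow=1.0,
        )
        c = close_parameters(p, ModelTopology.BRANCHED)
        assert c.delta_fast == 0.0 and c.delta_slow == 0.0

    def test_branched_zero_net_growth_by_integration(self):
        # independent oracle: integrate the pool-size ODE for 100 days
        p = KineticParameters(
            epsilon=0.6, beta=0.3226, alpha_fast=0.2, alpha_slow=0.005,
            f=0.01, N_fast=0.2, N_slow=0.8, phi_fast_fraction=0.8,
        )
        c = close_parameters(p, ModelTopology.BRANCHED)
        phi = c.phi

        def rhs(t, N):
            return [
                phi * c.phi_fast_fraction + (c.alpha_fast - c.delta_fast) * N[0],
                phi * (1 - c.phi_fast_fraction) + (c.alpha_slow - c.delta_slow) * N[1],
            ]

        sol = solve_ivp(rhs, (0, 100), [c.N_fast, c.N_slow], rtol=1e-10, atol=1e-14)
        drift = np.abs(sol.y[:, -1] - [c.N_fast, c.N_slow]) / [c.N_fast, c.N_slow]
        assert np.max(drift) < 1e-6

    def test_infeasible_parameters_raise(self):
        # inflow into an empty pool cannot be balanced
        p = KineticParameters(
            epsilon=0.5, beta=0.3, alpha_fast=0.1, alpha_slow=0.0,
            f=0.01, N_fast=0.0, N_slow=1.0, phi_fast_fraction=0.5,
        )
        with pytest.raises(ClosureError):
            close_parameters(p, ModelTopology.BRANCHED)

    def test_temporal_closes_both_losses(self):
        p = KineticParameters(
            epsilon=0.6, beta=0.3226, alpha_fast=0.08, alpha_slow=0.0,
            f=0.01, N_fast=0.2, N_slow=0.8,
        )
        c = close_parameters(p, ModelTopology.TEMPORAL)
        assert np.max(np.abs(stationarity_residual(c, ModelTopology.TEMPORAL))) < 1e-12


class TestStationarityResidual:
    def test_closed_homogeneous_residual_zero(self):
        p = _homog()
        c = close_parameters(p, ModelTopology.BRANCHED)
        assert np.max(np.abs(stationarity_residual(c, ModelTopology.BRANCHED))) < 1e-12

    def test_growth_without_loss(self):
        import dataclasses

        p = dataclasses.replace(_homog(), delta_fast=0.0, delta_slow=0.0)
        res = stationarity_residual(p, ModelTopology.BRANCHED)
        # per-capita growth = f + alpha when nothing is lost
        assert res[0] == pytest.approx(0.005 + 0.045, abs=1e-12)

    @given(
        alpha_fast=st.floats(0.01, 0.5),
        alpha_slow=st.floats(0.0, 0.02),
        f=st.floats(0.0, 0.05),
        nf=st.floats(0.05, 0.95),
        pff=st.floats(0.0, 1.0),
        topo=st.sampled_from(TWO_POOL),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_closure_residual_below_1e9(self, alpha_fast, alpha_slow, f, nf, pff, topo):
        p = KineticParameters(
            epsilon=0.6, beta=0.3226, alpha_fast=alpha_fast, alpha_slow=alpha_slow,
            f=f, N_fast=nf, N_slow=1 - nf, phi_fast_fraction=pff,
            gamma=0.02 if topo is ModelTopology.LINEAR else 0.0,
            activation=0.02 if topo is ModelTopology.BURST else 0.0,
            reversion=0.05 if topo is ModelTopology.BURST else 0.0,
        )
        try:
            c = close_parameters(p, topo)
        except ClosureError:
            assume(False)
        assert np.max(np.abs(stationarity_residual(c, topo))) < 1e-9


class TestSteadyState:
    def test_no_division_no_influx_means_no_ki67(self):
        p = KineticParameters(
            epsilon=0.5, beta=0.3, alpha_fast=0.0, alpha_slow=0.0,
            f=0.0, N_fast=1.0, N_slow=0.0,
        )
        c = close_parameters(p, ModelTopology.BRANCHED)
        ss = steady_state(c, ModelTopology.BRANCHED)
        assert ss.frac_ki67hi == pytest.approx(0.0, abs=1e-12)
        assert ss.frac_brdu == 0.0

    def test_beta_zero_all_ki67_high(self):
        p = KineticParameters(
            epsilon=0.5, beta=0.0, alpha_fast=0.045, alpha_slow=0.0,
            f=0.005, N_fast=1.0, N_slow=0.0,
        )
        c = close_parameters(p, ModelTopology.BRANCHED)
        ss = steady_state(c, ModelTopology.BRANCHED)
        assert ss.frac_ki67hi == pytest.approx(1.0, abs=1e-9)

    def test_nonstationary_parameters_refused(self):
        import dataclasses

        p = dataclasses.replace(_homog(), delta_fast=0.2, delta_slow=0.0)
        with pytest.raises(ValueError, match="close_parameters"):
            steady_state(p, ModelTopology.BRANCHED)


class TestKi67Equilibrium:
    def test_zero_sources(self):
        assert ki67_equilibrium_fraction(0.0, 0.0, 0.3, 0.1) == 0.0

    def test_beta_zero_stationary_gives_one(self):
        # f + alpha = delta makes (f + 2a)/(a + 0 + d) = 1
        assert ki67_equilibrium_fraction(0.01, 0.02, 0.0, 0.03) == pytest.approx(1.0)

    def test_formula_matches_long_time_integration(self):
        # integrate the BrdU-free system from a perturbed initial state
        f, alpha, beta = 0.01, 0.02, 0.3226
        p = close_parameters(
            KineticParameters(
                epsilon=0.0, beta=beta, alpha_fast=alpha, alpha_slow=0.0,
                f=f, N_fast=1.0, N_slow=0.0,
            ),
            ModelTopology.BRANCHED,
        )
        A, b = _build_system(p, ModelTopology.BRANCHED, n_stages=1, pulse=False)

        def rhs(t, x):
            return A @ x + b

        x0 = np.zeros(A.shape[0])
        x0[2] = 1.0  # everything Ki67-low, BrdU-negative
        sol = solve_ivp(rhs, (0, 500), x0, rtol=1e-10, atol=1e-14)
        xT = sol.y[:, -1]
        k_num = (xT[0] + xT[1]) / xT.sum()
        assert k_num == pytest.approx(
            ki67_equilibrium_fraction(f, alpha, beta, p.delta_fast), abs=1e-6
        )
        assert ki67_equilibrium_fraction(f, alpha, beta, p.delta_fast) == pytest.approx(
            0.1342, abs=5e-5
        )

    def test_degenerate_denominator(self):
        with pytest.raises(ZeroDivisionError):
            ki67_equilibrium_fraction(0.0, 0.0, 0.0, 0.0)


class TestSolveLabelling:
    def test_epsilon_zero_no_label(self, design):
        p = close_parameters(_homog(eps=0.0), ModelTopology.BRANCHED)
        df = solve_labelling(p, ModelTopology.BRANCHED, design, [0, 7, 21, 30])
        assert np.allclose(df.frac_brdu, 0.0, atol=1e-12)
        ss = steady_state(p, ModelTopology.BRANCHED)
        assert np.allclose(df.frac_ki67hi, ss.frac_ki67hi, atol=1e-9)

    def test_t_zero_is_steady_state(self, design, stratum_params):
        df = solve_labelling(stratum_params, ModelTopology.BRANCHED, design, [0.0])
        ss = steady_state(stratum_params, ModelTopology.BRANCHED)
        assert df.frac_brdu.iloc[0] == 0.0
        assert df.frac_ki67hi.iloc[0] == pytest.approx(ss.frac_ki67hi, abs=1e-9)

    def test_continuity_at_pulse_end(self, design, stratum_params):
        eps_t = 1e-6
        df = solve_labelling(
            stratum_params, ModelTopology.BRANCHED, design,
            [design.pulse_end - eps_t, design.pulse_end + eps_t],
        )
        assert df.frac_brdu.iloc[0] == pytest.approx(df.frac_brdu.iloc[1], abs=1e-4)

    @pytest.mark.parametrize("topo", TWO_POOL + [ModelTopology.TEMPORAL])
    def test_pulse_monotonicity_and_bounds(self, topo, design, branched_truth):
        from memokin.synthetic import default_ground_truth

        truth = default_ground_truth(topo)
        p = truth.params[next(iter(truth.params))]
        ts = np.linspace(0, design.chase_end, 70)
        df = solve_labelling(p, topo, design, ts)
        vals = df[["frac_brdu", "frac_brdu_in_ki67hi", "frac_brdu_in_ki67lo", "frac_ki67hi"]].to_numpy()
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0)
        pulse = df[df.time <= design.pulse_end].frac_brdu.to_numpy()
        assert np.all(np.diff(pulse) >= -1e-10)
        if p.epsilon < 1.0:
            assert df.frac_brdu_in_ki67hi.max() < 1.0

    def test_total_matches_exponential_closed_form(self):
        # division-only growth: N(t) = N0 * exp((alpha - delta) t)
        p = KineticParameters(
            epsilon=0.5, beta=0.3226, alpha_fast=0.08, alpha_slow=0.0,
            f=0.0, N_fast=1.0, N_slow=0.0, delta_fast=0.03, delta_slow=0.0,
        )
        A, b = _build_system(p, ModelTopology.BRANCHED, n_stages=1, pulse=True)
        prop = _AffinePropagator(A, b)
        x0 = np.zeros(A.shape[0])
        x0[0] = 1.0
        ts = np.array([0.0, 5.0, 15.0, 30.0])
        out = prop.propagate(x0, ts)
        totals = out.sum(axis=1)
        assert np.allclose(totals, np.exp((0.08 - 0.03) * ts), atol=1e-8)

    def test_erlang_stages_sharpen_ki67lo_delay(self, design, stratum_params):
        # staged Ki67 delays the first BrdU+ Ki67-low cells by ~T
        T = 1.0 / stratum_params.beta
        t_probe = [0.5 * T, 2.0 * T]
        single = solve_labelling(stratum_params, ModelTopology.BRANCHED, design, t_probe)
        staged = solve_labelling(
            stratum_params, ModelTopology.BRANCHED, design, t_probe, n_stages=8
        )
        early_1, early_8 = single.frac_brdu_in_ki67lo[0], staged.frac_brdu_in_ki67lo[0]
        assert early_8 < 0.15 * early_1  # hard suppression before the delay
        assert staged.frac_brdu_in_ki67lo[1] > 10 * early_8  # label arrives after ~T
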