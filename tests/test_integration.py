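"""Day integration, dilution bookkeeping and the batch protocol runner."""

import numpy as np
import pytest

from idcsim import (BatchProtocol, CocultureState, E_CROSS, MediaConfig,
                    ModelParams, S_CROSS, S_WT, apply_dilution, initial_state,
                    integrate_day, reduced_two_species_derivatives,
                    run_batch_protocol)
from idcsim.errors import InvalidParameterError
from idcsim.params import PopulationKinetics

QUIET = PopulationKinetics(mu=0.0, death=0.0, u_aa=0.0, u_glc=0.0)
ALL_OFF = ModelParams(bacterium=QUIET, yeast=QUIET, transconjugant=QUIET,
                      sigma_L=0.0, sigma_L_basal=0.0, sigma_W=0.0,
                      k_a=0.0, k_d=0.0, gamma=0.0, gamma_c=0.0)


def test_all_rates_zero_state_constant():
    media = MediaConfig()
    st = initial_state(media, 1e6, 1e6)
    _, ys, _ = integrate_day(st, ALL_OFF, E_CROSS, S_CROSS, media, 24.0)
    assert np.allclose(ys, ys[0], rtol=0, atol=1e-9)


def test_exponential_closed_form():
    """A single prototrophic population with excess nutrients and no death
    matches X0 * exp(mu' t) to 1e-6 relative, mu' the saturated rate."""
    media = MediaConfig()
    yeast = PopulationKinetics(mu=0.3, death=0.0, u_aa=0.0, u_glc=0.0)
    p = ALL_OFF.evolve(yeast=yeast, transconjugant=yeast)
    st = initial_state(media, 0.0, 1e4)
    grid, ys, _ = integrate_day(st, p, E_CROSS, S_WT, media, 24.0)
    g = media.glucose_gL
    mu_eff = 0.3 * g / (yeast.K_glc + g)
    expected = 1e4 * np.exp(mu_eff * grid)
    np.testing.assert_allclose(ys[:, 2], expected, rtol=1e-6)


def test_glucose_mass_balance():
    """Growth-coupled consumption: glucose drawdown equals the per-cell
    requisition times the new cells, to 1e-6 relative."""
    media = MediaConfig(glucose_gL=2.0)
    yeast = PopulationKinetics(mu=0.3, death=0.0, u_aa=0.0, u_glc=6e-7)
    p = ALL_OFF.evolve(yeast=yeast, transconjugant=yeast)
    st = initial_state(media, 0.0, 1e5)
    _, ys, _ = integrate_day(st, p, E_CROSS, S_WT, media, 48.0,
                             sampling_interval_h=0.5)
    new_cells = ys[-1, 2] - ys[0, 2]
    consumed = ys[0, 10] - ys[-1, 10]
    assert consumed == pytest.approx(6e-7 * new_cells, rel=1e-6)


def test_reduced_two_species_matches_full_model():
    """With clumping and transfer off and T0 = 0, the two-ODE reduction
    reproduces the full model over 6 dilution-punctuated days at 1e-8."""
    from scipy.integrate import solve_ivp

    media = MediaConfig(f_L=0.15, f_W=0.15)
    p = ModelParams(k_a=0.0, gamma=0.0, gamma_c=0.0)
    proto = BatchProtocol(n_days=6)
    full = run_batch_protocol(initial_state(media), p, E_CROSS, S_CROSS,
                              media, proto, rtol=1e-10, atol=1e-8)

    def rhs(t, y):
        dB, dY, dn = reduced_two_species_derivatives(
            y[0], y[1], y[2:], p, E_CROSS, S_CROSS, media)
        return [dB, dY, *dn]

    y = [1e7, 1e7, 762 * 0.15, 245 * 0.15, 178.0, 95.4, 20.0]
    finals = []
    for _ in range(6):
        sol = solve_ivp(rhs, (0, 24.0), y, method="LSODA", rtol=1e-10,
                        atol=1e-8)
        y = sol.y[:, -1]
        finals.append(y.copy())
        y = np.concatenate([[y[0] * 0.1, y[1] * 0.1],
                            0.9 * np.array([762 * 0.15, 245 * 0.15, 178.0,
                                            95.4, 20.0]) + 0.1 * y[2:]])
    for day, ref in enumerate(finals, start=1):
        s = full.daily[day - 1]
        assert s.B_total == pytest.approx(ref[0], rel=1e-8)
        assert s.Y_total + s.T_total == pytest.approx(ref[1], rel=1e-8)


class TestDilution:
    def test_one_in_ten(self):
        media = MediaConfig()
        st = initial_state(media, 1e7, 1e7)
        out = apply_dilution(st, media)
        assert out.B_f == pytest.approx(1e6)
        assert out.Y_f == pytest.approx(1e6)

    def test_nutrient_replenishment(self):
        media = MediaConfig()
        st = CocultureState(n_Leu=0.0, n_Trp=245.0, n_Glc=20.0)
        out = apply_dilution(st, media)
        assert out.n_Leu == pytest.approx(0.9 * 762)        # 685.8
        assert out.n_Trp == pytest.approx(0.9 * 245 + 0.1 * 245)

    def test_full_carryover_is_identity(self):
        media = MediaConfig()
        st = initial_state(media, 3e6, 4e6)
        out = apply_dilution(st, media, fresh_fraction=0.0,
                             carryover_fraction=1.0)
        np.testing.assert_allclose(out.to_vector(), st.to_vector())

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            apply_dilution(initial_state(MediaConfig()), MediaConfig(),
                           fresh_fraction=0.8, carryover_fraction=0.1)


class TestBatchProtocol:
    def test_zero_days_returns_initial_only(self):
        media = MediaConfig()
        traj = run_batch_protocol(initial_state(media), ModelParams(),
                                  E_CROSS, S_CROSS, media,
                                  BatchProtocol(n_days=0))
        assert len(traj.times) == 1 and not traj.daily

    def test_six_day_structure(self, crossfeeder_trajectory):
        traj = crossfeeder_trajectory
        assert len(traj.daily) == 6
        assert np.all(np.diff(traj.times) > 0)
        # DailySample totals equal the state sums at the pre-dilution instant
        for s in traj.daily:
            i = np.searchsorted(traj.times, s.t_h)
            st = traj.state_at(i)
            assert s.B_total == pytest.approx(st.B_total)
            assert s.T_total == pytest.approx(st.T_total)
            assert s.expected_cfu == pytest.approx(st.T_total * 0.5)

    def test_cumulative_idc_non_decreasing(self, crossfeeder_trajectory):
        cum = crossfeeder_trajectory.states[:, 11]
        assert np.all(np.diff(cum) >= -1e-9)

    def test_mannose_switch_releases_clumps(self):
        media = MediaConfig(f_L=0.15, f_W=0.15)
        proto = BatchProtocol(n_days=8, mannose_switch_day=6)
        traj = run_batch_protocol(initial_state(media), ModelParams(),
                                  E_CROSS, S_CROSS, media, proto,
                                  method="rk4")
        after = traj.times > 6 * 24.0
        clumped = traj.states[after][:, [1, 3, 5]]
        assert np.all(clumped == 0.0)

    def test_sampling_grid_validated(self):
        with pytest.raises(InvalidParameterError):
            BatchProtocol(day_length_h=24.0, sampling_interval_h=0.7)

    def test_screening_integrator_matches_reference_daily(self):
        """Fixed-step RK4 screening path agrees with adaptive LSODA on the
        day-1 population totals."""
        media = MediaConfig(f_L=0.15, f_W=0.15)
        st = initial_state(media)
        _, ref, _ = integrate_day(st, ModelParams(), E_CROSS, S_CROSS, media,
                                  24.0)
        _, fast, _ = integrate_day(st, ModelParams(), E_CROSS, S_CROSS, media,
                                   24.0, method="rk4")
        for cols in ([0, 1], [2, 3], [4, 5]):
            np.testing.assert_allclose(fast[-1, cols].sum(),
                                       ref[-1, cols].sum(), rtol=1e-3)

    def test_deterministic_for_fixed_inputs(self):
        media = MediaConfig(f_L=0.15, f_W=0.15)
        p = ModelParams()
        runs = [run_batch_protocol(initial_state(media), p, E_CROSS, S_CROSS,
                                   media, BatchProtocol(n_days=2),
                                   method="rk4") for _ in range(2)]
        np.testing.assert_array_equal(runs[0].states, runs[1].states)


def test_clump_exchange_conserves_over_a_day():
    """Pure association/dissociation keeps each population total constant to
    1e-8 relative across a day of integration."""
    media = MediaConfig()
    p = ALL_OFF.evolve(k_a=1e-6, k_d=0.3)
    st = CocultureState(B_f=1e6, B_c=2e5, Y_f=8e5, Y_c=1e5, T_f=2e4, T_c=1e4,
                        n_Glc=20.0)
    _, ys, _ = integrate_day(st, p, E_CROSS, S_CROSS, media, 24.0)
    for cols, total in (([0, 1], 1.2e6), ([2, 3], 9e5), ([4, 5], 3e4)):
        np.testing.assert_allclose(ys[:, cols].sum(axis=1), total, rtol=1e-8)
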