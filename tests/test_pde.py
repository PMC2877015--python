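"""Method-of-lines solver, front metrics, dispersion analysis."""

import numpy as np
import pytest

import angiodyn as ad
from angiodyn.pde import InsufficientDataError

REDUCED = ad.Params(eta0=0.5, dp=0.6, delta=0.65, sbeta=0.4,
                    ds_tilde=0.2, sigmap_tilde=0.0)
FULL = ad.load_preset("fig6a").params


class TestGridAndState:
    def test_grid_nodes(self):
        g = ad.Grid1D(L=10.0, n=20)
        assert g.dx == pytest.approx(0.5)
        assert len(g.x) == 21
        assert g.x[0] == 0.0 and g.x[-1] == 10.0

    def test_from_dx(self):
        g = ad.Grid1D.from_dx(250.0, 25.0 / 900.0)
        assert g.n == 9000

    def test_minimum_resolution_enforced(self):
        with pytest.raises(ValueError):
            ad.Grid1D(L=1.0, n=4)


class TestDefaultInitial:
    def test_vasculature_at_carrying_capacity(self):
        g = ad.Grid1D(L=50.0, n=100)
        st = ad.default_initial(g, REDUCED)
        assert np.all(st.v == 1.0)
        assert st.p[0] == 0.01 and np.all(st.p[g.x > 1.0] == 0.0)

    def test_single_node_seed(self):
        g = ad.Grid1D(L=50.0, n=100)
        st = ad.default_initial(g, REDUCED, seed_width=0.0)
        assert st.p[0] == 0.01 and np.all(st.p[1:] == 0.0)

    def test_quasi_steady_oxygen_profile(self):
        g = ad.Grid1D(L=50.0, n=100)
        st = ad.default_initial(g, FULL, variant="full")
        # far field (p = 0): s = 1/(1 + ds/hs) = 10/12 for the fig6 preset
        assert st.s[-1] == pytest.approx(10.0 / 12.0)
        assert np.all(st.c == 0.0)


class TestSimulate:
    def test_mass_conserved_without_kinetics(self):
        # no-flux diffusion conserves the trapezoid mass of each field
        g = ad.Grid1D(L=20.0, n=200)
        rng = np.random.default_rng(3)
        p0 = rng.uniform(0.1, 1.0, g.n + 1)
        v0 = rng.uniform(0.5, 1.5, g.n + 1)
        st0 = ad.TissueState(t=0.0, p=p0.copy(), v=v0.copy())
        states = ad.simulate(REDUCED, g, st0, [0.0, 5.0, 20.0],
                             kinetics=False)
        for st in states:
            for f0, f in ((p0, st.p), (v0, st.v)):
                assert np.trapezoid(f, dx=g.dx) == pytest.approx(
                    np.trapezoid(f0, dx=g.dx), rel=1e-8)

    def test_stable_case_becomes_uniform_at_equilibrium(self):
        # delta/eta0 <= 1: the wake settles to the stable coexistence state
        params = REDUCED.with_(delta=0.45)
        rep = ad.coexistence_equilibrium(params)
        g = ad.Grid1D(L=60.0, n=240)
        init = ad.default_initial(g, params)
        states = ad.simulate(params, g, init, [0.0, 400.0])
        final = states[-1]
        assert np.allclose(final.p, rep.p_star, atol=2e-3)
        assert np.allclose(final.v, rep.v_star, atol=2e-3)

    def test_nonnegative_fields(self):
        g = ad.Grid1D(L=60.0, n=240)
        init = ad.default_initial(g, REDUCED)
        states = ad.simulate(REDUCED, g, init, np.arange(0.0, 201.0, 50.0))
        for st in states:
            for arr in st.fields().values():
                assert arr.min() >= 0.0

    def test_reduced_and_full_agree_on_front_position(self):
        # quasi-steady oxygen is a good approximation at the fig6 exchange
        # and diffusion rates: front positions agree to < 2%
        g = ad.Grid1D(L=80.0, n=720)
        t_out = [0.0, 50.0, 100.0]
        init_r = ad.default_initial(g, FULL)
        red = ad.simulate(FULL, g, init_r, t_out, variant="reduced")
        init_f = ad.default_initial(g, FULL, variant="oxygen")
        ful = ad.simulate(FULL, g, init_f, t_out, variant="oxygen")
        for st_r, st_f in zip(red[1:], ful[1:]):
            xr = ad.front_position(st_r.p, g)
            xf = ad.front_position(st_f.p, g)
            assert xf == pytest.approx(xr, rel=0.02)

    def test_bad_t_out_rejected(self):
        g = ad.Grid1D(L=10.0, n=20)
        init = ad.default_initial(g, REDUCED)
        with pytest.raises(ValueError):
            ad.simulate(REDUCED, g, init, [0.0])


class TestFrontMetrics:
    def test_below_threshold_gives_zero(self):
        g = ad.Grid1D(L=10.0, n=100)
        assert ad.front_position(np.full(101, 1e-5), g) == 0.0

    def test_translation_equivariance(self):
        g = ad.Grid1D(L=100.0, n=400)
        profile = 0.4 / (1.0 + np.exp((g.x - 30.0) / 2.0))
        shifted = np.roll(profile, 10)
        shifted[:10] = profile[0]
        x1 = ad.front_position(profile, g)
        x2 = ad.front_position(shifted, g)
        assert x2 - x1 == pytest.approx(10 * g.dx, abs=1e-9)

    def test_spread_and_speed(self):
        t = np.linspace(0.0, 100.0, 51)
        fm = ad.FrontMetrics(t=t, x_max=0.5 * t + 3.0, p_crit=0.01)
        assert fm.spread(20.0, 80.0) == pytest.approx(30.0)
        assert fm.speed((0.0, 100.0)) == pytest.approx(0.5)
        assert not fm.low_confidence

    def test_nonmonotone_window_flags_low_confidence(self):
        t = np.linspace(0.0, 10.0, 11)
        x = np.array([0, 1, 2, 1.5, 2.5, 3, 4, 5, 6, 7, 8.0])
        fm = ad.FrontMetrics(t=t, x_max=x, p_crit=0.01)
        fm.speed((0.0, 10.0))
        assert fm.low_confidence


class TestMinWaveSpeed:
    def test_independent_of_delta(self):
        speeds = {d: ad.min_wave_speed(FULL.with_(delta=d))
                  for d in (9.0, 11.0, 11.6)}
        assert len(set(speeds.values())) == 1

    def test_reduced_preset_value(self):
        # s_inf = 1/1.2, growth = phi(s_inf) - dp ~ 0.0757
        assert ad.min_wave_speed(REDUCED) == pytest.approx(0.550, abs=1e-3)

    def test_marginal_and_infeasible(self):
        s_inf = ad.quasi_steady_oxygen(0.0, 1.0, REDUCED)
        marginal = REDUCED.with_(dp=ad.phi(s_inf, REDUCED.sbeta))
        assert ad.min_wave_speed(marginal) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            ad.min_wave_speed(REDUCED.with_(dp=0.7))

    def test_measured_speed_below_linear_bound(self):
        # pulled front: the measured speed approaches the linear-spreading
        # speed from below once the profile has relaxed
        g = ad.Grid1D(L=250.0, n=750)
        init = ad.default_initial(g, REDUCED)
        t_out = np.arange(0.0, 401.0, 10.0)
        states = ad.simulate(REDUCED, g, init, t_out)
        fm = ad.front_metrics(states, g)
        c_min = ad.min_wave_speed(REDUCED)
        early = fm.speed((200.0, 300.0))
        late = fm.speed((300.0, 400.0))
        assert late <= c_min * 1.01
        assert late > early          # still accelerating toward the bound


class TestTumourBurden:
    def test_constant_profile(self):
        g = ad.Grid1D(L=30.0, n=60)
        assert ad.tumour_burden(np.full(61, 0.7), g) == pytest.approx(21.0)

    def test_hat_function(self):
        g = ad.Grid1D(L=10.0, n=100)
        hat = np.zeros(101)
        hat[50] = 1.0      # triangle of width 2*dx, trapezoid mass dx
        assert ad.tumour_burden(hat, g) == pytest.approx(g.dx)

    def test_matches_spline_quadrature(self):
        from scipy.integrate import quad
        from scipy.interpolate import CubicSpline
        g = ad.Grid1D(L=50.0, n=500)
        profile = 0.3 * (1.0 + np.sin(2 * np.pi * g.x / 25.0)) \
            * np.exp(-((g.x - 20.0) / 15.0) ** 2)
        spline = CubicSpline(g.x, profile)
        oracle, _ = quad(spline, 0.0, g.L, limit=200)
        assert ad.tumour_burden(profile, g) == pytest.approx(oracle,
                                                             rel=1e-3)


class TestRegularityClassifier:
    def test_sinusoid_regular(self):
        t = np.linspace(0.0, 200.0, 4001)
        y = 1.0 + 0.3 * np.sin(2 * np.pi * t / 10.0)
        assert ad.regularity_classifier(t, y) == "regular"

    def test_modulated_signal_irregular(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 400.0, 8001)
        # strongly varying peak heights and spacings
        y = 1.0 + (0.3 + 0.25 * np.sin(0.05 * t)) * np.sin(
            2 * np.pi * t / (10.0 + 3.0 * np.sin(0.21 * t)))
        assert ad.regularity_classifier(t, y) == "irregular"

    def test_insufficient_peaks(self):
        t = np.linspace(0.0, 20.0, 401)
        y = np.sin(2 * np.pi * t / 10.0)
        with pytest.raises(InsufficientDataError):
            ad.regularity_classifier(t, y)


class TestDiffusionDrivenInstability:
    def _stable_equilibrium(self, params):
        rep = ad.coexistence_equilibrium(params)
        assert rep.exists and np.max(rep.eigenvalues.real) < 0
        return rep

    def test_k_zero_matches_ode_jacobian(self):
        params = REDUCED.with_(delta=0.45)
        rep = self._stable_equilibrium(params)
        growth = ad.ddi_dispersion(params, rep, [0.0])
        assert growth[0] == pytest.approx(np.max(rep.eigenvalues.real),
                                          abs=1e-12)

    def test_equal_diffusivities_never_unstable(self):
        params = REDUCED.with_(delta=0.45, Dv=1.0)
        rep = self._stable_equilibrium(params)
        k = np.linspace(0.0, 20.0, 400)
        assert np.max(ad.ddi_dispersion(params, rep, k)) <= 0.0

    def test_slow_vessel_diffusion_can_destabilise(self):
        # activator-inhibitor structure with v the (self-activating)
        # species: Turing modes need Dv < 1 and a tumour oxygen-consumption
        # feedback (sigmap > 0) so that p provides the stabilising diagonal
        rng = np.random.default_rng(11)
        k = np.linspace(0.01, 30.0, 300)
        found = False
        for _ in range(300):
            eta0 = rng.uniform(0.1, 1.0)
            params = REDUCED.with_(
                eta0=eta0, delta=eta0 * rng.uniform(1.0, 2.5),
                ds_tilde=rng.uniform(0.05, 0.8),
                sigmap_tilde=rng.uniform(0.05, 0.5),
                Dv=rng.uniform(1e-3, 0.05))
            rep = ad.coexistence_equilibrium(params)
            if not rep.exists or np.max(rep.eigenvalues.real) >= 0:
                continue
            if rep.J[1, 1] <= 0:
                continue
            if np.max(ad.ddi_dispersion(params, rep, k)) > 0:
                found = True
                break
        assert found

    def test_unstable_base_state_rejected(self):
        rep = ad.coexistence_equilibrium(REDUCED)   # unstable spiral
        with pytest.raises(ValueError):
            ad.ddi_dispersion(REDUCED, rep, [0.0, 1.0])
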