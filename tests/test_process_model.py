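import numpy as np
import pytest

from fedbatch.params import KineticParameterSet, RateLaw
from fedbatch.process_model import (
    BaseFeedParams,
    ControlProfile,
    FeedSpec,
    ProcessState,
    SamplingEvent,
    base_feed,
    evaluate_rates,
    feed_rate,
    growth_partition,
    maintenance_rate,
    ode_rhs,
    production_uptake_rate,
    simulate,
    uptake_rate,
)


def _params(uptake=None, maintenance=None, production=None,
            Y_XrG=0.5, Y_PG=0.9):
    return KineticParameterSet(
        uptake=uptake or RateLaw(kind="uptake", c=1.0, Km=1.0),
        maintenance=maintenance or RateLaw(kind="maintenance", c=0.0),
        production=production or RateLaw(kind="production", c=0.0, Km=0.1,
                                         mask={"Km": True}),
        Y_XrG=Y_XrG, Y_PG=Y_PG,
    )


class TestRateLaws:
    def test_uptake_zero_substrate(self):
        p = _params()
        assert uptake_rate(0.0, 0.0, 0.0, 30.0, 31.0, p) == 0.0

    def test_uptake_half_saturation(self):
        p = _params(uptake=RateLaw(kind="uptake", c=2.0, Km=0.5))
        assert uptake_rate(0.5, 0, 0, 30, 31.0, p) == pytest.approx(1.0)

    @pytest.mark.parametrize("G,expected", [(1.0, 0.25), (0.0, 0.0)])
    def test_uptake_with_self_inhibition_hand_value(self, G, expected):
        rl = RateLaw(kind="uptake", c=1.0, Km=1.0, K={"G": 1.0},
                     mask={"G": True})
        p = _params(uptake=rl)
        assert uptake_rate(G, 0, 0, 30, 31.0, p) == pytest.approx(expected)

    def test_uptake_bounded_by_scale(self, truth):
        G = np.geomspace(1e-3, 100, 50)
        v = uptake_rate(G, 0.5, 0.1, 40.0, 31.0, truth)
        assert np.all(v <= truth.uptake.c + 1e-12)

    def test_uptake_rejects_negative_inputs(self, truth):
        with pytest.raises(ValueError):
            uptake_rate(-0.1, 0, 0, 30, 31.0, truth)

    def test_maintenance_empty_product_is_baseline(self):
        p = _params(maintenance=RateLaw(kind="maintenance", c=0.01))
        assert maintenance_rate(1.0, 1.0, 1.0, 0.5, 30, 31.0, p) == \
            pytest.approx(0.01)

    def test_maintenance_hand_value(self):
        rl = RateLaw(kind="maintenance", c=0.01,
                     K={"gamma_uptake": 1.0, "PX": 1.0},
                     mask={"gamma_uptake": True, "PX": True})
        p = _params(maintenance=rl)
        assert maintenance_rate(1.0, 0, 0, 1.0, 30, 31.0, p) == \
            pytest.approx(0.04)
        # zero activations -> baseline
        assert maintenance_rate(0.0, 0, 0, 0.0, 30, 31.0, p) == \
            pytest.approx(0.01)

    def test_production_zero_surplus(self):
        p = _params(production=RateLaw(kind="production", c=0.1, Km=0.1,
                                       mask={"Km": True}))
        assert production_uptake_rate(0.2, 0.2, 0, 0, 0, 30, 31.0, p) == 0.0
        # negative surplus clamps to zero, not negative production
        assert production_uptake_rate(0.1, 0.2, 0, 0, 0, 30, 31.0, p) == 0.0

    def test_production_half_saturation_in_surplus(self):
        p = _params(production=RateLaw(kind="production", c=0.1, Km=0.05,
                                       mask={"Km": True}))
        assert production_uptake_rate(0.15, 0.10, 0, 0, 0, 30, 31.0, p) == \
            pytest.approx(0.05)

    def test_production_generation_inhibition_half(self):
        rl = RateLaw(kind="production", c=0.1, Km=1e-9, K={"n": 2.0},
                     mask={"Km": True, "n": True})
        p = _params(production=rl)
        v = production_uptake_rate(10.0, 0.0, 0, 2.0, 0, 30, 31.0, p)
        assert v == pytest.approx(0.05, rel=1e-6)


class TestGrowthPartition:
    def test_hand_arithmetic(self):
        p = _params(Y_XrG=0.5, Y_PG=0.9)
        g_mu, mu, pi = growth_partition(0.3, 0.1, 0.05, p, Xr=0.8, X=1.0)
        assert g_mu == pytest.approx(0.15)
        assert pi == pytest.approx(0.072)
        assert mu == pytest.approx(0.132)

    def test_no_product_case(self):
        p = _params(Y_XrG=0.5, Y_PG=0.9)
        g_mu, mu, pi = growth_partition(0.2, 0.0, 0.0, p, Xr=30.0, X=30.0)
        assert pi == 0.0
        assert mu == pytest.approx(0.2 * 0.5)

    def test_additivity_preserved_exactly(self, truth):
        rng = np.random.default_rng(0)
        G = rng.uniform(0, 5, 200)
        n = rng.uniform(0, 1.5, 200)
        PX = rng.uniform(0, 0.3, 200)
        X = rng.uniform(20, 60, 200)
        r = evaluate_rates(truth, G, n, PX, X, 31.0)
        np.testing.assert_allclose(
            r["gamma_mu"] + r["gamma_pi"] + r["gamma_alpha"],
            r["gamma_circ"], rtol=0, atol=1e-15,
        )


class TestOdeRhsAndFeeds:
    def test_rhs_hand_values(self):
        st = ProcessState(t=0, X=30.0, P=3.0, G=0.1, V=1.3)
        dX, dP, dG, dV = ode_rhs(st, 0.05, 390.0, 0.1, 0.01, 0.2)
        assert dX == pytest.approx(1.8461538, rel=1e-6)
        assert dP == pytest.approx(0.1846154, rel=1e-6)
        assert dG == pytest.approx(8.9961538, rel=1e-6)
        assert dV == pytest.approx(0.05)

    def test_rhs_zero_everything(self):
        st = ProcessState(t=0, X=30.0, P=3.0, G=0.1, V=1.3)
        assert ode_rhs(st, 0.0, 390.0, 0.0, 0.0, 0.0) == (0.0, 0.0, 0.0, 0.0)

    def test_feed_laws(self):
        exp = FeedSpec(kind="exponential", Gf=390.0, f0=1.0, mu_f=0.1)
        assert feed_rate(10.0, exp) == pytest.approx(np.e)
        const = FeedSpec(kind="exponential", Gf=390.0, f0=2.5, mu_f=0.0)
        assert feed_rate(7.0, const) == pytest.approx(2.5)
        lin = FeedSpec(kind="linear", Gf=390.0, phi1=0.022, phi2=0.0053)
        assert feed_rate(10.0, lin) == pytest.approx(0.075)
        neg = FeedSpec(kind="linear", Gf=390.0, phi1=-1.0, phi2=0.01)
        assert feed_rate(0.0, neg) == 0.0

    def test_base_feed(self):
        p = BaseFeedParams()  # a=13900e-7, b=-1.1e-7
        assert base_feed(30.0, 1.3, 0.1, p) == pytest.approx(5.41671e-3,
                                                             rel=1e-5)
        assert base_feed(0.0, 1.3, 0.1, p) == 0.0
        mu_root = 1.1e-7 / 13900e-7
        assert base_feed(30.0, 1.3, mu_root, p) == pytest.approx(0.0, abs=1e-15)


class TestSimulator:
    def test_dilution_conservation(self):
        """With all rates zero, X*V and P*V are constant and V = V0 + f*t."""
        p = _params(uptake=RateLaw(kind="uptake", c=0.0, Km=1.0))
        prof = ControlProfile(t_knots=[0.0, 10.0], feed_values=[39.0, 39.0],
                              T_values=[31.0, 31.0], Gf=390.0, tend=10.0)
        x0 = ProcessState(t=0, X=30.0, P=3.0, G=0.0, V=1.0)
        traj = simulate(p, prof, [], x0, grid=np.linspace(0, 10, 21))
        np.testing.assert_allclose(traj["V"], 1.0 + 0.1 * traj["t"], rtol=1e-6)
        np.testing.assert_allclose(traj["X"] * traj["V"], 30.0, rtol=1e-6)
        np.testing.assert_allclose(traj["P"] * traj["V"], 3.0, rtol=1e-6)

    def test_sampling_event_contract(self, truth):
        """V jumps down by exactly the sampled volume; X, P, G continuous."""
        prof = ControlProfile(t_knots=[0.0, 8.0], feed_values=[8.0, 16.0],
                              T_values=[31.0, 31.0], Gf=390.0, tend=8.0)
        x0 = ProcessState(t=0, X=30.0, P=0.0, G=0.3, V=1.3)
        traj = simulate(truth, prof, [SamplingEvent(4.0, 0.035)], x0,
                        grid=np.linspace(0, 8, 17), base=None)
        at4 = traj[np.isclose(traj["t"], 4.0)]
        assert len(at4) == 2
        pre, post = at4.iloc[0], at4.iloc[1]
        assert pre["V"] - post["V"] == pytest.approx(0.035, abs=1e-12)
        for s in ("X", "P", "G"):
            assert pre[s] == pytest.approx(post[s], rel=1e-12)

    def test_total_mass_drops_proportionally_at_event(self, truth):
        prof = ControlProfile(t_knots=[0.0, 6.0], feed_values=[8.0, 12.0],
                              T_values=[31.0, 31.0], Gf=390.0, tend=6.0)
        x0 = ProcessState(t=0, X=30.0, P=0.0, G=0.3, V=1.3)
        traj = simulate(truth, prof, [SamplingEvent(3.0, 0.05)], x0,
                        grid=np.array([0.0, 3.0, 6.0]), base=None)
        at3 = traj[np.isclose(traj["t"], 3.0)]
        pre, post = at3.iloc[0], at3.iloc[1]
        removed = pre["X"] * 0.05  # concentration times sampled volume
        assert pre["X"] * pre["V"] - post["X"] * post["V"] == \
            pytest.approx(removed, rel=1e-9)

    def test_agrees_with_fixed_step_reference_integrator(self, truth):
        """Independent brute-force oracle: fixed-step RK4 at fine resolution."""
        prof = ControlProfile(t_knots=[0.0, 6.0], feed_values=[8.0, 14.0],
                              T_values=[30.0, 33.0], Gf=390.0, tend=6.0)
        x0 = ProcessState(t=0, X=30.0, P=0.0, G=0.3, V=1.3)
        grid = np.linspace(0, 6, 7)
        traj = simulate(truth, prof, [], x0, grid=grid, base=None)

        def rhs(t, y):
            X, P, G, V = y
            PX = max(P, 0.0) / X
            n = max(np.log2(X * V / (30.0 * 1.3)), 0.0)
            r = evaluate_rates(truth, max(G, 0.0), n, PX, X,
                               float(prof.temperature(t)))
            f_sub = float(prof.feed(t)) / 390.0
            gamma = float(r["gamma_circ"]) * (X - P) / X
            return np.array([
                float(r["mu"]) * X - f_sub / V * X,
                float(r["pi"]) * X - f_sub / V * P,
                -gamma * X + (f_sub * 390.0 - f_sub * G) / V,
                f_sub,
            ])

        h = 6.0 / 6000
        y = np.array([30.0, 0.0, 0.3, 1.3])
        ref = {0.0: y.copy()}
        t = 0.0
        for i in range(6000):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            ref[round(t, 9)] = y.copy()
        for _, row in traj.iterrows():
            expected = ref[round(row["t"], 9)]
            got = np.array([row["X"], row["P"], row["G"], row["V"]])
            np.testing.assert_allclose(got, expected, rtol=1e-4)

    def test_mass_balance_closed(self, truth, center_run_clean):
        """Cumulative substrate fed minus substrate in broth equals the
        integrated uptake within 0.5%."""
        rec = center_run_clean
        prof = ControlProfile(t_knots=rec.t_online,
                              feed_values=rec.f_online,
                              T_values=rec.T_online, Gf=rec.Gf, tend=rec.tend)
        x0 = ProcessState(t=0, X=rec.X0, P=0.0, G=rec.G_meas[0], V=rec.V0)
        grid = np.linspace(0, rec.tend, 481)
        traj = simulate(truth, prof, rec.sampling_events, x0, grid=grid,
                        base=None)
        fed = np.trapezoid(prof.feed(traj["t"]), traj["t"])
        uptake = np.trapezoid(traj["gamma_circ"] * traj["Xr"] * traj["V"],
                              traj["t"])
        # substrate removed by sampling + change in dissolved amount
        in_broth = traj["G"].iloc[-1] * traj["V"].iloc[-1] - \
            traj["G"].iloc[0] * traj["V"].iloc[0]
        sampled = 0.0
        for e in rec.sampling_events:
            pre = traj[np.isclose(traj["t"], e.t_sample)].iloc[0]
            sampled += pre["G"] * e.volume_removed
        assert fed - in_broth - sampled == pytest.approx(uptake, rel=5e-3)

    def test_volume_exhaustion_raises(self, truth):
        prof = ControlProfile(t_knots=[0.0, 4.0], feed_values=[8.0, 8.0],
                              T_values=[31.0, 31.0], Gf=390.0, tend=4.0)
        x0 = ProcessState(t=0, X=30.0, P=0.0, G=0.3, V=0.05)
        from fedbatch.process_model import SimulationError
        with pytest.raises(SimulationError):
            simulate(truth, prof, [SamplingEvent(2.0, 0.12)], x0, base=None)

    def test_reduced_model_matches_general_evaluator(self, truth):
        """The masked general evaluator reproduces the reduced-model algebra
        term for term."""
        G, n, PX, X, T = 0.8, 0.6, 0.12, 45.0, 33.0
        u, m, pr = truth.uptake, truth.maintenance, truth.production
        g_circ = u.c * G / (u.Km + G) / (1 + G / u.K["G"])
        g_alpha = m.c * (1 + g_circ / m.K["gamma_uptake"]) * (1 + PX / m.K["PX"])
        s = g_circ - g_alpha
        g_pi = (float(pr.temp.value(T)) * s / (pr.Km + s) / (1 + n / pr.K["n"]))
        r = evaluate_rates(truth, G, n, PX, X, T)
        assert float(r["gamma_circ"]) == pytest.approx(g_circ, rel=1e-12)
        assert float(r["gamma_alpha"]) == pytest.approx(g_alpha, rel=1e-12)
        assert float(r["gamma_pi"]) == pytest.approx(g_pi, rel=1e-12)
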