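import numpy as np
import pandas as pd
import pytest

import heatfootprint as hf
from heatfootprint import ario
from conftest import chain_mrio, isolated_mrio


class TestCalibration:
    def test_coefficient_identity(self, net_2x2):
        np.testing.assert_allclose(
            net_2x2.a.sum(axis=1) + net_2x2.b, 1.0, atol=1e-12
        )
        assert np.all(net_2x2.a >= 0) and np.all(net_2x2.b >= 0)

    def test_baseline_orders_reproduce_flows(self, mrio_2x2, net_2x2):
        np.testing.assert_allclose(
            net_2x2.fod_bar * 365, mrio_2x2.Z.to_numpy(), rtol=1e-12
        )
        np.testing.assert_allclose(
            net_2x2.hod_bar * 365, mrio_2x2.final_demand.to_numpy(), rtol=1e-12
        )

    def test_zero_intermediate_firm_has_unit_va_coefficient(self):
        net = ario.calibrate(isolated_mrio(), steps_per_year=1)
        assert net.b[0] == pytest.approx(1.0)
        assert np.all(net.a == 0)

    def test_unbalanced_table_rejected(self, mrio_2x2):
        broken = ario.MRIOTable(
            Z=mrio_2x2.Z * 1.01,
            final_demand=mrio_2x2.final_demand,
            value_added=mrio_2x2.value_added,
            gross_output=mrio_2x2.gross_output,
        )
        with pytest.raises(ValueError):
            ario.calibrate(broken)


class TestCapacityOperations:
    def test_labour_and_capital_capacity(self):
        x_bar = np.array([200.0, 80.0])
        np.testing.assert_allclose(
            ario.capacity_labour(np.array([0.0, 1.0]), x_bar), [200.0, 0.0]
        )
        np.testing.assert_allclose(
            ario.capacity_labour(np.array([0.25, 0.5]), x_bar), [150.0, 40.0]
        )
        np.testing.assert_allclose(
            ario.capacity_capital(np.array([0.25, 0.0]), x_bar), [150.0, 80.0]
        )

    def test_inventory_capacity(self):
        S = np.array([[30.0, 0.0], [10.0, 5.0]])
        a = np.array([[0.3, 0.0], [0.0, 0.5]])
        xp = ario.capacity_inventory(S, a)
        assert xp[0, 0] == pytest.approx(100.0)
        assert xp[0, 1] == np.inf  # unused input: no constraint
        assert xp[1, 0] == np.inf
        assert xp[1, 1] == pytest.approx(10.0)
        zero = ario.capacity_inventory(np.array([[0.0]]), np.array([[0.2]]))
        assert zero[0, 0] == 0.0
        with pytest.raises(ValueError):
            ario.capacity_inventory(np.array([[-1.0]]), np.array([[0.2]]))

    def test_max_capacity_is_min_of_constraints(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            xl = rng.uniform(0, 100, 4)
            xk = rng.uniform(0, 100, 4)
            xp = rng.uniform(0, 100, (4, 3))
            got = ario.max_capacity(xl, xk, xp)
            expected = [
                min([xl[i], xk[i]] + list(xp[i])) for i in range(4)
            ]
            np.testing.assert_allclose(got, expected)

    def test_actual_production_demand_vs_supply_limited(self):
        assert ario.actual_production(np.array([100.0]), np.array([70.0]))[0] == 70.0
        assert ario.actual_production(np.array([50.0]), np.array([70.0]))[0] == 50.0


class TestAllocation:
    def test_proportional_rationing_worked_example(self):
        frc, hrc = ario.allocate(
            np.array([50.0]), np.array([[60.0]]), np.array([[40.0]])
        )
        assert frc[0, 0] == pytest.approx(30.0)
        assert hrc[0, 0] == pytest.approx(20.0)

    def test_exact_fill_when_output_meets_orders(self):
        fod = np.array([[10.0, 20.0]])
        hod = np.array([[5.0]])
        frc, hrc = ario.allocate(np.array([35.0]), fod, hod)
        np.testing.assert_allclose(frc, fod)
        np.testing.assert_allclose(hrc, hod)

    def test_conservation_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n, h = 6, 3
            fod = rng.uniform(0, 10, (n, n)) * (rng.random((n, n)) < 0.6)
            hod = rng.uniform(0, 10, (n, h))
            x_a = rng.uniform(0, (fod.sum(1) + hod.sum(1)))
            frc, hrc = ario.allocate(x_a, fod, hod)
            np.testing.assert_allclose(
                frc.sum(1) + hrc.sum(1), x_a, rtol=1e-12
            )

    def test_zero_orders_zero_allocations(self):
        frc, hrc = ario.allocate(
            np.array([10.0]), np.array([[0.0]]), np.array([[0.0]])
        )
        assert frc[0, 0] == 0.0 and hrc[0, 0] == 0.0


class TestOrderIssuing:
    def test_no_gap_no_orders(self, net_2x2):
        S_star = 15.0 * net_2x2.a * net_2x2.x_bar[:, None]
        fod = ario.issue_orders_firm(S_star, S_star, net_2x2.x_bar, net_2x2)
        np.testing.assert_array_equal(fod, 0.0)

    def test_capacity_weighted_split_two_suppliers(self):
        # two identical suppliers of the same product; one at half capacity
        firms = pd.MultiIndex.from_tuples(
            [("RA", "s1"), ("RB", "s1"), ("RC", "s2")],
            names=["region", "sector"],
        )
        Z = pd.DataFrame(
            [[0.0, 0.0, 30.0], [0.0, 0.0, 30.0], [0.0, 0.0, 0.0]],
            index=firms, columns=firms,
        )
        F = pd.DataFrame(
            {"RA": [20.0, 0, 0], "RB": [0, 20.0, 0], "RC": [0, 0, 100.0]},
            index=firms,
        )
        va = pd.Series([50.0, 50.0, 40.0], index=firms)
        x = pd.Series([50.0, 50.0, 100.0], index=firms)
        net = ario.calibrate(
            ario.MRIOTable(Z=Z, final_demand=F, value_added=va, gross_output=x),
            steps_per_year=1,
        )
        S = np.zeros((3, 2))
        S_star = np.zeros((3, 2))
        S_star[2, 0] = 60.0  # client RC wants 60 units of product s1
        x_a = np.array([25.0, 50.0, 100.0])  # supplier RA at half capacity
        fod = ario.issue_orders_firm(S, S_star, x_a, net)
        assert fod[0, 2] == pytest.approx(20.0)  # 1:2 split
        assert fod[1, 2] == pytest.approx(40.0)
        # all suppliers down: fall back to baseline shares
        fod0 = ario.issue_orders_firm(S, S_star, np.array([0.0, 0.0, 100.0]), net)
        assert fod0[0, 2] == pytest.approx(30.0)
        assert fod0[1, 2] == pytest.approx(30.0)
        # exponent 0: fixed baseline shares regardless of capacity
        fodf = ario.issue_orders_firm(S, S_star, x_a, net, exponent=0.0)
        assert fodf[0, 2] == pytest.approx(30.0)

    def test_zero_baseline_flow_never_ordered(self, net_2x2):
        zero_baseline = net_2x2.fod_bar == 0
        if not zero_baseline.any():
            pytest.skip("dense network has no zero baseline flows")
        S = np.zeros_like(net_2x2.a)
        S_star = np.ones_like(net_2x2.a)
        fod = ario.issue_orders_firm(S, S_star, net_2x2.x_bar, net_2x2)
        assert np.all(fod[zero_baseline] == 0.0)

    def test_household_orders_sum_to_demand(self, net_2x2):
        hd = net_2x2.baseline_household_demand() * 1.3
        hod = ario.issue_orders_household(hd, net_2x2.x_bar, net_2x2)
        np.testing.assert_allclose(
            (net_2x2.product_matrix @ hod).T, hd, rtol=1e-12
        )
        hod0 = ario.issue_orders_household(hd * 0.0, net_2x2.x_bar, net_2x2)
        np.testing.assert_array_equal(hod0, 0.0)


class TestSimulation:
    def test_equilibrium_fixed_point(self, net_2x2):
        cfg = hf.SimConfig(horizon=100)
        res = ario.run(net_2x2, ario.ShockSeries.none(100, net_2x2.n_firms), cfg)
        scale = net_2x2.va_bar.sum() * 100
        assert abs(res.tef.sum()) / scale < 1e-10
        assert abs(res.def_.sum()) / scale < 1e-10
        np.testing.assert_allclose(res.x_a[-1], net_2x2.x_bar, rtol=1e-10)

    def test_determinism(self, net_2x2):
        rng = np.random.default_rng(2)
        g = rng.uniform(0, 0.5, (50, net_2x2.n_firms))
        cfg = hf.SimConfig(horizon=50)
        a = ario.run(net_2x2, ario.ShockSeries(gamma_L=g), cfg)
        b = ario.run(net_2x2, ario.ShockSeries(gamma_L=g.copy()), cfg)
        np.testing.assert_array_equal(a.x_a, b.x_a)
        np.testing.assert_array_equal(a.tef, b.tef)

    def test_one_step_outage_absorbed_by_inventories(self, net_2x2):
        g = np.zeros((10, net_2x2.n_firms))
        g[1, 0] = 1.0
        res = ario.run(net_2x2, ario.ShockSeries(gamma_L=g), hf.SimConfig(horizon=10))
        # the shocked firm loses exactly one step of output; its clients
        # keep producing at baseline that step (inventory buffer absorbs)
        assert res.x_a[1, 0] == 0.0
        np.testing.assert_allclose(
            res.x_a[1, 1:], net_2x2.x_bar[1:], rtol=1e-9
        )

    def test_isolated_firm_closed_form(self):
        net = ario.calibrate(isolated_mrio(200.0), steps_per_year=1)
        g = np.zeros((30, 1))
        g[5:15, 0] = 0.1  # 10 steps at 10 percent
        res = ario.run(net, ario.ShockSeries(gamma_L=g), hf.SimConfig(horizon=30))
        expected = 0.1 * 200.0 * 10
        assert res.tef[0] == pytest.approx(expected, rel=1e-12)
        assert res.def_[0] == pytest.approx(expected, rel=1e-12)
        assert res.pef[0] == pytest.approx(0.0, abs=1e-9)

    def test_connected_network_loss_ordering(self, net_2x2):
        g = np.zeros((120, net_2x2.n_firms))
        g[10:70, 0] = 0.3
        res = ario.run(net_2x2, ario.ShockSeries(gamma_L=g), hf.SimConfig(horizon=120))
        tot = res.totals()
        assert tot["TEF"] >= tot["DEF"] >= 0
        assert tot["PEF"] >= 0
        assert tot["TEF"] == pytest.approx(tot["DEF"] + tot["PEF"], rel=1e-12)

    def test_production_bounded_and_inventories_nonnegative(self, net_2x2):
        rng = np.random.default_rng(3)
        cfg = hf.SimConfig(horizon=80)
        g = rng.uniform(0, 1, (80, net_2x2.n_firms)) * (
            rng.random((80, net_2x2.n_firms)) < 0.3
        )
        state = ario.initial_state(net_2x2, cfg)
        hd = net_2x2.baseline_household_demand()
        for t in range(80):
            state, x_a, x_max = ario.step(
                state, net_2x2, g[t], np.zeros(net_2x2.n_firms), hd, cfg
            )
            assert np.all(x_a <= x_max + 1e-12)
            assert np.all(x_max <= net_2x2.x_bar + 1e-9)
            assert np.all(state.S >= -1e-12)

    def test_capital_shock_symmetric_to_labour(self, net_2x2):
        g = np.zeros((40, net_2x2.n_firms))
        g[5:25, 1] = 0.4
        cfg = hf.SimConfig(horizon=40)
        a = ario.run(net_2x2, ario.ShockSeries(gamma_L=g), cfg)
        b = ario.run(
            net_2x2,
            ario.ShockSeries(gamma_L=np.zeros_like(g), gamma_K=g),
            cfg,
        )
        np.testing.assert_allclose(a.tef, b.tef, rtol=1e-12)

    def test_invalid_shocks_rejected(self, net_2x2):
        with pytest.raises(ValueError):
            ario.run(
                net_2x2,
                ario.ShockSeries(gamma_L=np.full((10, net_2x2.n_firms), 1.5)),
                hf.SimConfig(horizon=10),
            )
        with pytest.raises(ValueError):
            hf.SimConfig(horizon=0)
        with pytest.raises(ValueError):
            hf.SimConfig(overproduction=0.5)


class TestTwoFirmChainOracle:
    """Hand-unrolled five-step trajectory on the A -> B chain.

    Firm A (no intermediate inputs) supplies B and a household; B sells
    only to its household. Inventory target n = 2 steps, one step per
    year-equivalent so per-step numbers equal the table. A 50 percent
    labour shock hits A at step 1 only. Every number below is pencil
    arithmetic from the update rules.
    """

    def _run(self):
        net = ario.calibrate(chain_mrio(), steps_per_year=1)
        cfg = hf.SimConfig(horizon=5, inventory_target=2.0)
        g = np.zeros((5, 2))
        g[1, 0] = 0.5
        state = ario.initial_state(net, cfg)
        hd = net.baseline_household_demand()
        xs, states = [], []
        for t in range(5):
            state, x_a, _ = ario.step(
                state, net, g[t], np.zeros(2), hd, cfg
            )
            xs.append(x_a)
            states.append(state.copy())
        return net, np.array(xs), states

    def test_trajectory_matches_hand_unrolled_values(self):
        net, xs, states = self._run()
        i_s1 = net.sectors.index("s1")
        # step 0: equilibrium; A=100, B=90; S_B stays at 2*(2/3)*90 = 120
        np.testing.assert_allclose(xs[0], [100.0, 90.0], rtol=1e-12)
        assert states[0].S[1, i_s1] == pytest.approx(120.0)
        assert states[0].fod_prev[0, 1] == pytest.approx(60.0)
        # step 1: A halved -> x_a = (50, 90); B gets 30 of its 60 order
        # (A rations 50 proportionally over orders 60 + 40);
        # S_B = 120 - 60 + 30 = 90; B reorders its full gap 120 - 60 = 60
        np.testing.assert_allclose(xs[1], [50.0, 90.0], rtol=1e-12)
        assert states[1].S[1, i_s1] == pytest.approx(90.0)
        assert states[1].fod_prev[0, 1] == pytest.approx(60.0)
        # step 2: A recovered, fills all orders; B still at 90 (buffer held);
        # S_B = 90 - 60 + 60 = 90; gap vs target 120 -> order 90
        np.testing.assert_allclose(xs[2], [100.0, 90.0], rtol=1e-12)
        assert states[2].S[1, i_s1] == pytest.approx(90.0)
        assert states[2].fod_prev[0, 1] == pytest.approx(90.0)
        # step 3: A demand = 90 + 40 = 130 > capacity 100 -> rations:
        # B receives 90/130*100 = 69.2308, household RA gets 30.7692;
        # S_B = 90 - 60 + 69.2308 = 99.2308; B orders 120 - 30 = 90 again
        np.testing.assert_allclose(xs[3], [100.0, 90.0], rtol=1e-12)
        assert states[3].S[1, i_s1] == pytest.approx(90 - 60 + 900 / 13)
        assert states[3].fod_prev[0, 1] == pytest.approx(90.0)
        # step 4: same rationing; B's buffer keeps it at 90 throughout
        np.testing.assert_allclose(xs[4], [100.0, 90.0], rtol=1e-12)

    def test_footprint_of_chain_shock(self):
        net = ario.calibrate(chain_mrio(), steps_per_year=1)
        g = np.zeros((5, 2))
        g[1, 0] = 0.5
        res = ario.run(net, ario.ShockSeries(gamma_L=g), hf.SimConfig(horizon=5, inventory_target=2.0))
        # A loses half a step of va (50); B fully buffered
        assert res.tef[0] == pytest.approx(50.0, rel=1e-12)
        assert res.def_[0] == pytest.approx(50.0, rel=1e-12)
        assert res.tef[1] == pytest.approx(0.0, abs=1e-9)


def test_shock_series_validation(net_2x2):
    s = ario.ShockSeries(gamma_L=np.zeros((5, net_2x2.n_firms)))
    s.validate(5, net_2x2.n_firms)
    with pytest.raises(ValueError):
        ario.ShockSeries(gamma_L=np.zeros((4, 2))).validate(5, 2)
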