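"""Marcus rates, feasibility flags, master equation, adiabaticity."""
import numpy as np
import pandas as pd
import pytest

from quadhop import datasets
from quadhop.constants import HBAR_MEV_S, KB_MEV
from quadhop.hopnet import (
    adiabaticity_index,
    boltzmann_from_dg,
    feasibility_graph,
    marcus_rate,
    master_equation,
    potential_from_dg,
    read_table_csv,
    symmetrize_couplings,
)


@pytest.fixture(scope="module")
def dg():
    return datasets.load_reference_dg()


@pytest.fixture(scope="module")
def hab():
    return datasets.load_reference_hab()


class TestMarcusRate:
    def test_activationless_maximum(self):
        lam, T = 800.0, 298.0
        kt = KB_MEV * T
        k = marcus_rate(10.0, -lam, lam, T)
        expected = (2 * np.pi / HBAR_MEV_S) * 100.0 / np.sqrt(4 * np.pi * lam * kt)
        assert k == pytest.approx(expected, rel=1e-12)
        # the activationless point maximizes the rate over dG
        for dg_v in (-1200, -1000, -600, -400, 0):
            assert marcus_rate(10.0, dg_v, lam, T) <= k

    def test_detailed_balance_ratio_for_printed_step(self):
        """Forward/backward ratio for the -320 meV step at 298 K equals
        exp(320 / k_B T)."""
        lam, T = 800.0, 298.0
        ratio = marcus_rate(31.0, -320.0, lam, T) / marcus_rate(31.0, 320.0, lam, T)
        assert ratio == pytest.approx(np.exp(320.0 / (KB_MEV * T)), rel=1e-9)

    def test_zero_coupling_zero_rate(self):
        assert marcus_rate(0.0, -320.0) == 0.0

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            marcus_rate(10.0, 0.0, lam=-5.0)


class TestFeasibilityGraph:
    def test_printed_tables_key_edges(self, dg, hab):
        net = feasibility_graph(dg, hab)
        e_good = net.edges[("124A+", "122D+")]
        assert e_good.feasible_thermo and e_good.feasible_kinetic
        e_bad = net.edges[("124A+", "124D+")]
        # dG +172 fails the +70 meV bound; H_ab = 0.2 fails the strict > 0.2
        assert not e_bad.feasible_thermo
        assert not e_bad.feasible_kinetic

    def test_all_feasible_under_trivial_thresholds(self, dg, hab):
        net = feasibility_graph(dg, hab, dG_max=np.inf, H_min=0.0)
        assert len(net.feasible_edges()) == 12

    def test_every_feasible_path_terminates_at_122D(self, dg, hab):
        net = feasibility_graph(dg, hab)
        assert net.feasible_sinks() == ["122D+"]
        assert net.all_paths_terminate_at("122D+")

    def test_loose_preset_keeps_termination(self, dg, hab):
        net = feasibility_graph(dg, hab, preset="loose")
        assert net.all_paths_terminate_at("122D+")

    def test_missing_pair_rejected(self, dg, hab):
        broken = dg.copy()
        broken.loc["124A", "122D"] = np.nan
        with pytest.raises(ValueError, match="missing pair"):
            feasibility_graph(broken, hab)

    def test_csv_round_trip(self, dg, hab, tmp_path):
        p = tmp_path / "dg.csv"
        dg.to_csv(p)
        again = read_table_csv(p)
        net = feasibility_graph(again, hab)
        assert net.all_paths_terminate_at("122D+")


class TestDetailedBalance:
    def test_symmetric_mode_exact(self, dg, hab):
        net = feasibility_graph(dg, hab, symmetric_coupling=True)
        assert net.detailed_balance_residual() < 1e-12

    def test_asymmetric_mode_reports_residual(self, dg, hab):
        net = feasibility_graph(dg, hab, symmetric_coupling=False)
        # directional couplings break microscopic reversibility
        assert net.detailed_balance_residual() > 0.1

    def test_geometric_mean_symmetrization(self, hab):
        sym = symmetrize_couplings(hab)
        assert sym.loc["124A", "122D"] == pytest.approx(np.sqrt(31 * 25))
        assert sym.loc["122D", "124A"] == pytest.approx(np.sqrt(31 * 25))


class TestMasterEquation:
    def test_two_state_stationary_is_boltzmann(self):
        """For a two-state network the stationary ratio equals
        exp(-ΔG/kT) exactly."""
        from quadhop.hopnet import HopEdge, HopNetwork, marcus_rate as mr

        lam, T = 800.0, 298.0
        edges = {}
        for i, j, d in (("124A+", "122A+", -100.0), ("122A+", "124A+", 100.0)):
            edges[(i, j)] = HopEdge(i, j, d, 10.0, mr(10.0, d, lam, T), True, True)
        net = HopNetwork(("124A+", "122A+"), edges, lam, T)
        res = master_equation(net, {"124A+": 1.0, "122A+": 0.0}, [1e-6])
        ratio = res.stationary_of("122A+") / res.stationary_of("124A+")
        assert ratio == pytest.approx(np.exp(100.0 / (KB_MEV * T)), rel=1e-6)

    def test_population_conservation(self, dg, hab):
        net = feasibility_graph(dg, hab, symmetric_coupling=True)
        res = master_equation(
            net, {"124A+": 1.0, "122A+": 0.0, "122D+": 0.0, "124D+": 0.0},
            np.logspace(-14, -7, 15),
        )
        assert np.allclose(res.populations.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_rates_keep_p0(self):
        from quadhop.hopnet import HopEdge, HopNetwork

        edges = {
            ("124A+", "122A+"): HopEdge("124A+", "122A+", 0.0, 0.0, 0.0, True, False)
        }
        net = HopNetwork(("124A+", "122A+"), edges, 800.0, 298.0)
        res = master_equation(net, {"124A+": 0.3, "122A+": 0.7}, [0.0, 1e-3, 1.0])
        assert np.allclose(res.populations, [0.3, 0.7])
        assert np.allclose(res.stationary, [0.3, 0.7])

    def test_unnormalized_p0_rejected(self, dg, hab):
        net = feasibility_graph(dg, hab)
        with pytest.raises(ValueError, match="normalized"):
            master_equation(net, {"124A+": 0.5}, [1e-9])

    def test_stationary_ordering_from_printed_tables(self, dg, hab):
        """With symmetric couplings and the cycle-consistent free-energy
        landscape, the stationary state is maximal at 122D+ and minimal at
        124D+; the raw (cycle-inconsistent) table keeps 122D+ maximal."""
        p0 = {"124A+": 1.0, "122A+": 0.0, "122D+": 0.0, "124D+": 0.0}
        net_cc = feasibility_graph(dg, hab, symmetric_coupling=True, cycle_consistent=True)
        res = master_equation(net_cc, p0, [1e-9])
        pops = dict(zip(net_cc.nodes, res.stationary))
        assert max(pops, key=pops.get) == "122D+"
        assert min(pops, key=pops.get) == "124D+"
        net_raw = feasibility_graph(dg, hab, symmetric_coupling=True)
        res_raw = master_equation(net_raw, p0, [1e-9])
        assert net_raw.nodes[int(np.argmax(res_raw.stationary))] == "122D+"

    def test_consistent_stationary_matches_boltzmann_potential(self, dg, hab):
        net = feasibility_graph(dg, hab, symmetric_coupling=True, cycle_consistent=True)
        res = master_equation(
            net, {"124A+": 1.0, "122A+": 0.0, "122D+": 0.0, "124D+": 0.0}, [1e-9]
        )
        g = potential_from_dg(dg)
        w = np.exp(-(g - g.min()) / net.kT)
        w = w / w.sum()
        assert np.allclose(res.stationary, w.values, atol=1e-9)


class TestPotentialProjection:
    def test_consistent_table_is_fixed_point(self):
        g = {"124A": 0.0, "122A": 67.0, "122D": -320.0, "124D": 172.0}
        sites = list(g)
        tbl = pd.DataFrame(
            [[g[j] - g[i] for j in sites] for i in sites], index=sites, columns=sites
        )
        got = potential_from_dg(tbl)
        for s in sites:
            assert got[s] == pytest.approx(g[s], abs=1e-9)

    def test_reference_table_potentials(self, dg):
        g = potential_from_dg(dg)
        # least-squares column means of the bundled antisymmetric table
        assert g["122D"] == pytest.approx(-219.5 - 20.25, abs=1e-9)
        assert g["124D"] == pytest.approx(113.0 - 20.25, abs=1e-9)


class TestBoltzmann:
    def test_row_based_boltzmann_ordering(self, dg):
        p = boltzmann_from_dg(dg)
        assert p.idxmax() == "122D+"
        assert p.idxmin() == "124D+"


class TestAdiabaticity:
    def test_limits_and_proportionality(self):
        k0, cls0 = adiabaticity_index(1e-6)
        assert k0 < 1e-6 and cls0 == "nonadiabatic"
        k1, _ = adiabaticity_index(10.0, nu_eff_inv_fs=100.0)
        k2, _ = adiabaticity_index(10.0, nu_eff_inv_fs=200.0)
        assert k2 == pytest.approx(2 * k1)

    def test_independent_rederivation(self):
        """κ re-derived from SI constants: κ = 2π H² / (ħ ν (4πλkT)^1/2)."""
        h_mev, lam, nu_inv_fs, T = 31.0, 800.0, 100.0, 298.0
        hbar_j_s = 1.054571817e-34
        mev = 1.602176634e-22  # J
        kb = 1.380649e-23
        h_j = h_mev * mev
        lam_j = lam * mev
        nu = 1.0 / (nu_inv_fs * 1e-15)
        kappa_si = 2 * np.pi * h_j**2 / (hbar_j_s * nu * np.sqrt(4 * np.pi * lam_j * kb * T))
        kappa, cls = adiabaticity_index(h_mev, lam, nu_inv_fs, T)
        assert kappa == pytest.approx(kappa_si, rel=1e-6)
        assert cls == "adiabatic"
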