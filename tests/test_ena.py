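"""Network-analysis indicators against hand and brute-force oracles."""

import dataclasses

import numpy as np
import pytest

from enashift import (
    compute_all,
    ecosystem_ratios,
    finn_cycle_index,
    fisheries_indices,
    flow_to_detritus_fraction,
    information_decomposition,
    kempton_q,
    make_random_web,
    mean_path_length,
    to_flow_network,
    total_system_throughput,
    trophic_levels,
)
from enashift.foodweb import FlowNetwork, FoodWeb, GroupSpec, solve_missing_ee

from conftest import perm_web


def net_from_flows(n, flows, detritus=()):
    """Build a FlowNetwork from (donor, receiver, value) triplets; 'imp',
    'exp', 'rsp' address the boundary nodes."""
    T = np.zeros((n + 3, n + 3))
    code = {"imp": n, "exp": n + 1, "rsp": n + 2}
    for i, j, v in flows:
        T[code.get(i, i), code.get(j, j)] = v
    det = np.array([k in detritus for k in range(n)])
    return FlowNetwork(T=T, labels=[f"c{k}" for k in range(n)], living=~det, detritus=det)


def fci_walk_oracle(net, maxlen=50):
    """Finn cycling by accumulating return visits over walks up to ``maxlen``."""
    n = net.n
    Tf = net.throughflow()
    G = np.zeros((n, n))
    act = Tf > 0
    G[:, act] = net.internal[:, act] / Tf[act]
    P = np.eye(n)
    Ndiag = np.zeros(n)
    for _ in range(maxlen + 1):
        Ndiag += np.diag(P)
        P = P @ G
    cyc = np.where(Ndiag > 0, (Ndiag - 1) / np.maximum(Ndiag, 1e-300), 0.0) * Tf
    return float(cyc.sum() / net.T.sum())


class TestThroughput:
    def test_single_flow(self):
        net = net_from_flows(2, [(0, 1, 7.0)])
        assert total_system_throughput(net) == 7.0

    def test_chain_sums_every_listed_flow(self):
        net = net_from_flows(2, [("imp", 0, 10.0), (0, 1, 6.0), (1, "exp", 2.0),
                                 (0, "rsp", 4.0), (1, "rsp", 4.0)])
        assert total_system_throughput(net) == 26.0

    def test_empty_network(self):
        assert total_system_throughput(net_from_flows(2, [])) == 0.0


class TestInformation:
    def test_two_disjoint_equal_flows_give_one_bit(self):
        net = net_from_flows(4, [(0, 2, 1.0), (1, 3, 1.0)])
        info = information_decomposition(net)
        assert info["AMI"] == pytest.approx(1.0)

    def test_single_internal_flow_has_no_structure(self):
        net = net_from_flows(2, [(0, 1, 5.0)])
        info = information_decomposition(net)
        assert info["AMI"] == pytest.approx(0.0, abs=1e-12)
        assert info["R"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_capacity_identity_and_ami_bound(self, seed):
        web = make_random_web(seed=seed, n_groups=8 + seed)
        info = information_decomposition(to_flow_network(web))
        total = (info["A"] + info["R"] + info["ov_import"]
                 + info["ov_export"] + info["ov_dissipation"])
        assert total == pytest.approx(info["C"], rel=1e-9)
        assert info["AMI"] <= info["H"] + 1e-12
        assert 0.0 <= info["AC_ratio"] <= 1.0

    def test_collapsing_parallel_flows_never_increases_redundancy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t1, t2 = rng.uniform(0.5, 5.0, 2)
            base = [("imp", 0, t1 + t2), (1, "exp", t1), (2, "exp", t2)]
            split = net_from_flows(3, base + [(0, 1, t1), (0, 2, t2)])
            merged = net_from_flows(3, base + [(0, 1, t1 + t2), (2, "exp", 0)])
            assert (information_decomposition(merged)["R"]
                    <= information_decomposition(split)["R"] + 1e-12)

    def test_zero_tst_is_an_error(self):
        with pytest.raises(ValueError, match="TST"):
            information_decomposition(net_from_flows(2, []))


class TestCycling:
    def test_acyclic_chain_has_no_cycling(self):
        net = net_from_flows(3, [("imp", 0, 10.0), (0, 1, 8.0), (1, 2, 5.0),
                                 (2, "exp", 5.0)])
        assert finn_cycle_index(net) == 0.0

    def test_two_compartment_loop_matches_walk_oracle(self):
        net = net_from_flows(2, [(0, 1, 10.0), (1, 0, 5.0), ("imp", 0, 5.0),
                                 (1, "exp", 5.0)])
        fci = finn_cycle_index(net)
        assert fci == pytest.approx(0.4)  # hand: N_ii = 2, cycled 5+5 of TST 25
        assert fci == pytest.approx(fci_walk_oracle(net), abs=1e-6)

    @pytest.mark.parametrize("seed", range(12))
    def test_random_small_networks_match_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        flows = [("imp", 0, 10.0)]
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < 0.4:
                    flows.append((i, j, float(rng.uniform(0.1, 3.0))))
            flows.append((i, "exp", float(rng.uniform(0.5, 2.0))))
        net = net_from_flows(n, flows)
        assert finn_cycle_index(net) == pytest.approx(
            fci_walk_oracle(net, maxlen=400), abs=1e-6
        )

    def test_detritus_only_cycle_splits_fci_from_pci(self):
        # the only loop passes through the detritus compartment 2
        net = net_from_flows(
            3,
            [("imp", 0, 10.0), (0, 1, 8.0), (1, 2, 4.0), (2, 0, 4.0),
             (1, "exp", 4.0)],
            detritus=(2,),
        )
        assert finn_cycle_index(net, include_detritus=True) > 0.0
        assert finn_cycle_index(net, include_detritus=False) == 0.0


class TestPathAndDetritus:
    def test_straight_through_path_length_two(self):
        net = net_from_flows(1, [("imp", 0, 10.0), (0, "exp", 10.0)])
        assert mean_path_length(net) == pytest.approx(2.0)

    def test_internal_transfer_increases_mpl(self):
        a = net_from_flows(2, [("imp", 0, 10.0), (0, "exp", 10.0)])
        b = net_from_flows(2, [("imp", 0, 10.0), (0, 1, 4.0), (0, "exp", 6.0),
                               (1, "exp", 4.0)])
        assert mean_path_length(b) > mean_path_length(a)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_chain_mpl_grows_linearly(self, k):
        flows = [("imp", 0, 10.0)]
        for i in range(k):
            flows.append((i, i + 1, 10.0))
        flows.append((k, "exp", 10.0))
        net = net_from_flows(k + 1, flows)
        assert mean_path_length(net) == pytest.approx(k + 2)

    def test_mpl_without_input_is_error(self):
        with pytest.raises(ValueError, match="boundary input"):
            mean_path_length(net_from_flows(2, [(0, 1, 3.0)]))

    def test_detritus_inflow_share(self):
        net = net_from_flows(
            3, [("imp", 0, 10.0), (0, 1, 6.0), (0, 2, 4.0), (1, 2, 2.0),
                (1, "exp", 4.0), (2, "exp", 6.0)],
            detritus=(2,),
        )
        tst = total_system_throughput(net)
        assert flow_to_detritus_fraction(net) == pytest.approx(6.0 / tst)
        no_det = net_from_flows(2, [("imp", 0, 5.0), (0, "exp", 5.0)])
        assert flow_to_detritus_fraction(no_det) == 0.0


class TestEcosystemRatios:
    def test_toy_ratios_by_hand(self, toy_web):
        net = to_flow_network(toy_web)
        r = ecosystem_ratios(net, toy_web)
        # TPP = 10*10; TR = consumer respiration 35; ToTP = 100+5; ToTB = 11
        assert r["TPP_TR"] == pytest.approx(100.0 / 35.0)
        assert r["ToTP_ToTB"] == pytest.approx(105.0 / 11.0)
        assert r["TotC"] == 0.0


class TestFisheries:
    def test_single_catch_at_tl2(self, toy_web):
        toy_web.groups[1].landings = {}
        web = FoodWeb(
            [dataclasses.replace(g, landings={"f": 1.0} if g.name == "grazer" else {})
             for g in toy_web.groups],
            fleets=["f"],
        )
        net = to_flow_network(web)
        out = fisheries_indices(net, web)
        assert out["mTLc"] == pytest.approx(2.0)
        # grazer g = PB/QB = 0.1: each caught unit requires 10 producer units
        assert out["PPR"] == pytest.approx(10.0)

    def test_ppr_single_path_closed_form(self):
        groups = [
            GroupSpec(name="p", role="producer", B=100.0, PB=10.0),
            GroupSpec(name="h", role="consumer", B=10.0, PB=10.0, QB=50.0,
                      GS=0.2, diet={"p": 1.0}, landings={"f": 1.0}),
            GroupSpec(name="d", role="detritus", B=10.0, PB=0.0),
        ]
        web = solve_missing_ee(FoodWeb(groups, fleets=["f"]))
        out = fisheries_indices(to_flow_network(web), web)
        assert out["PPR"] == pytest.approx(1.0 / 0.2)  # Y / g

    def test_equal_catches_at_tl2_and_tl4_average_to_3(self):
        groups = [
            GroupSpec(name="p", role="producer", B=1000.0, PB=50.0),
            GroupSpec(name="h", role="consumer", B=50.0, PB=10.0, QB=40.0,
                      GS=0.2, diet={"p": 1.0}, landings={"f": 1.0}),
            GroupSpec(name="m", role="consumer", B=5.0, PB=5.0, QB=20.0,
                      GS=0.2, diet={"h": 1.0}),
            GroupSpec(name="t", role="consumer", B=0.5, PB=2.0, QB=8.0,
                      GS=0.2, diet={"m": 1.0}, landings={"g": 1.0}),
            GroupSpec(name="d", role="detritus", B=10.0, PB=0.0),
        ]
        web = solve_missing_ee(FoodWeb(groups, fleets=["f", "g"]))
        out = fisheries_indices(to_flow_network(web), web)
        assert out["mTLc"] == pytest.approx(3.0)

    def test_zero_catch_gives_missing_value(self, toy_web):
        with pytest.warns(UserWarning, match="zero total catch"):
            out = fisheries_indices(to_flow_network(toy_web), toy_web)
        assert np.isnan(out["mTLc"])


class TestKemptonQ:
    def test_geometric_sequence_closed_form(self):
        S, ratio = 8, 0.5
        B = 100.0 * ratio ** np.arange(S)
        TL = np.full(S, 3.5)
        expected = (S / 2.0) / (0.5 * (S - 1) * np.log10(1.0 / ratio))
        assert kempton_q(B, TL) == pytest.approx(expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        B = rng.uniform(0.1, 10.0, 9)
        TL = np.full(9, 4.0)
        assert kempton_q(2.0 * B, TL) == pytest.approx(kempton_q(B, TL))

    def test_more_even_biomasses_give_larger_q(self):
        TL = np.full(6, 3.5)
        even = np.array([5.0, 4.5, 4.0, 3.6, 3.2, 3.0])
        uneven = np.array([50.0, 10.0, 4.0, 1.0, 0.2, 0.05])
        assert kempton_q(even, TL) > kempton_q(uneven, TL)

    def test_too_few_upper_trophic_groups_is_missing(self):
        assert np.isnan(kempton_q(np.array([1.0, 2.0]), np.array([2.0, 2.5])))


class TestComposition:
    def test_compute_all_equals_individual_operations(self, baltic):
        web, _ = baltic
        net = to_flow_network(web)
        s = compute_all(net, web, year=1974)
        info = information_decomposition(net)
        assert s.TST == pytest.approx(total_system_throughput(net))
        assert s.R_pct_C == pytest.approx(info["R_pct_C"])
        assert s.FCI == pytest.approx(finn_cycle_index(net))
        assert s.PCI == pytest.approx(finn_cycle_index(net, include_detritus=False))
        assert s.MPL == pytest.approx(mean_path_length(net))
        assert s.mTLc == pytest.approx(
            fisheries_indices(net, web, trophic_levels(web))["mTLc"]
        )

    def test_fixture_year_populates_all_fifteen_indicators(self, baltic):
        from enashift import INDICATOR_NAMES

        web, _ = baltic
        s = compute_all(to_flow_network(web), web, year=1974)
        assert len(INDICATOR_NAMES) == 15
        for name in INDICATOR_NAMES:
            assert np.isfinite(getattr(s, name)), name

    def test_indices_invariant_under_compartment_reordering(self, baltic):
        web, _ = baltic
        rng = np.random.default_rng(11)
        web2 = perm_web(web, list(rng.permutation(web.n)))
        s1 = compute_all(to_flow_network(web), web)
        s2 = compute_all(to_flow_network(web2), web2)
        for f in dataclasses.fields(s1):
            v1, v2 = getattr(s1, f.name), getattr(s2, f.name)
            assert v1 == pytest.approx(v2, rel=1e-8), f.name
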