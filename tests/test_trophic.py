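"""Trophic positions, pyramids, transfer efficiency, size spectra, diets."""

import numpy as np
import pytest

from plankweb import (
    PDOM,
    FlowNetworkError,
    diet_composition,
    diet_stoichiometry,
    mean_trophic_position,
    metabolic_activity,
    size_spectrum_slope,
    system_residence_time,
    transfer_efficiency_from_spectrum,
    transfer_efficiency_production,
    trophic_positions,
    trophic_pyramid,
    weighted_ppmr,
)
from plankweb.trophic import fit_allometric_exponent, restrict_chain

from conftest import make_net


def path_expansion_tp(net, node, max_depth=200, tol=1e-13):
    """Independent oracle: TP as the explicit sum over all feeding paths.

    Expands TP_i = 1 + Σ_j f_ij TP_j recursively, following every weighted
    path down to basal nodes; cycles contribute geometrically shrinking
    terms that are truncated below ``tol``.
    """
    intake = net.T.sum(axis=0)
    idx = {n: i for i, n in enumerate(net.nodes)}

    def tp(n, weight, depth):
        if n == PDOM:
            return 0.0
        i = idx[n]
        if intake[i] <= 0:
            return 1.0
        if depth > max_depth or weight < tol:
            return 1.0  # truncation: remaining mass ~ tol
        total = 1.0
        for j, r in enumerate(net.nodes):
            f = net.T[j, i] / intake[i]
            if f > 0:
                total += f * tp(r, weight * f, depth + 1)
        return total

    return tp(node, 1.0, 0)


class TestTrophicPositions:
    def test_pure_consumer_on_producer(self):
        net = make_net(("P", "H"), {("P", "H"): 5.0})
        dec = trophic_positions(net)
        assert dec.tp["P"] == pytest.approx(1.0)
        assert dec.tp["H"] == pytest.approx(2.0)
        assert dec.levels["H"] == pytest.approx({2: 1.0})

    def test_omnivore_mixed_diet(self):
        net = make_net(("P", "H", "O"),
                       {("P", "H"): 1.0, ("P", "O"): 1.0, ("H", "O"): 1.0})
        dec = trophic_positions(net)
        assert dec.tp["O"] == pytest.approx(2.5)
        assert dec.levels["O"][2] == pytest.approx(0.5)
        assert dec.levels["O"][3] == pytest.approx(0.5)

    def test_cannibal_self_loop(self):
        net = make_net(("P", "X"), {("P", "X"): 1.0, ("X", "X"): 1.0})
        dec = trophic_positions(net)
        # x = 1 + 0.5*1 + 0.5*x  =>  x = 3
        assert dec.tp["X"] == pytest.approx(3.0)
        assert sum(dec.levels["X"].values()) == pytest.approx(1.0)

    def test_pdom_and_bacteria_assignment(self):
        net = make_net((PDOM, "Bac", "HNF"),
                       {(PDOM, "Bac"): 2.0, ("Bac", "HNF"): 1.0})
        dec = trophic_positions(net)
        assert dec.tp[PDOM] == 0.0
        assert dec.tp["Bac"] == pytest.approx(1.0)
        assert dec.tp["HNF"] == pytest.approx(2.0)

    def test_declared_consumer_without_ingestion_errors(self):
        net = make_net(("P", "H"), {("P", "H"): 1.0})
        with pytest.raises(FlowNetworkError, match="zero total ingestion"):
            trophic_positions(net, consumers=("P",))

    def test_matches_path_expansion_oracle_on_random_webs(self, rng):
        """Linear solve equals the explicit all-paths expansion (<=6 nodes)."""
        for _ in range(25):
            s = rng.integers(3, 7)
            nodes = tuple(f"n{i}" for i in range(s))
            net = make_net(nodes, {})
            for i in range(1, s):
                # feed on a random set of lower-index nodes, plus occasional
                # self-loops / upward links to create omnivory cycles
                prey = rng.choice(i, size=rng.integers(1, i + 1), replace=False)
                for j in prey:
                    net.T[j, i] = rng.uniform(0.1, 5.0)
                if rng.uniform() < 0.3:
                    net.T[i, i] = rng.uniform(0.1, 1.0)
            dec = trophic_positions(net)
            for n in nodes:
                assert dec.tp[n] == pytest.approx(
                    path_expansion_tp(net, n), abs=1e-9)
                assert sum(dec.levels[n].values()) == pytest.approx(1.0, abs=1e-9)
                mean_level = sum(k * w for k, w in dec.levels[n].items())
                assert mean_level == pytest.approx(dec.tp[n], abs=1e-9)


class TestMeanTrophicPosition:
    def test_uniform_positions(self):
        net = make_net(("P", "A", "B"), {("P", "A"): 1.0, ("P", "B"): 2.0})
        dec = trophic_positions(net)
        assert mean_trophic_position(dec, ("A", "B"), {"A": 1, "B": 99}) == 2.0

    def test_biomass_weighted(self):
        net = make_net(("P", "H", "C"), {("P", "H"): 1.0, ("H", "C"): 0.5})
        dec = trophic_positions(net)
        got = mean_trophic_position(dec, ("H", "C"), {"H": 1.0, "C": 3.0})
        assert got == pytest.approx(2.75)

    def test_empty_consumer_set_errors(self):
        net = make_net(("P", "H"), {("P", "H"): 1.0})
        dec = trophic_positions(net)
        with pytest.raises(FlowNetworkError):
            mean_trophic_position(dec, ())


class TestPyramids:
    def test_pure_chain(self):
        net = make_net(("P", "H", "C"), {("P", "H"): 1.0, ("H", "C"): 0.3})
        dec = trophic_positions(net)
        pyr = trophic_pyramid(dec, {"P": 3.0, "H": 2.0, "C": 1.0})
        assert pyr == pytest.approx({1: 3.0, 2: 2.0, 3: 1.0})

    def test_omnivore_split(self):
        net = make_net(("P", "H", "O"),
                       {("P", "H"): 1.0, ("P", "O"): 1.0, ("H", "O"): 1.0})
        dec = trophic_positions(net)
        pyr = trophic_pyramid(dec, {"O": 4.0})
        assert pyr == pytest.approx({2: 2.0, 3: 2.0})

    def test_conservation(self, scenario):
        net = scenario.networks["Summer"]["C"]
        dec = trophic_positions(net)
        q = {n: float(i + 1) for i, n in enumerate(net.nodes)}
        pyr = trophic_pyramid(dec, q)
        assert sum(pyr.values()) == pytest.approx(sum(q.values()), rel=1e-9)


class TestTransferEfficiency:
    def test_production_ratio(self):
        assert transfer_efficiency_production(
            {1: 100.0, 2: 30.0, 3: 9.0}) == pytest.approx(0.30)

    def test_equal_production_is_one(self):
        assert transfer_efficiency_production({1: 5.0, 2: 5.0, 3: 5.0}) == 1.0

    def test_zero_level_errors(self):
        with pytest.raises(FlowNetworkError, match="level"):
            transfer_efficiency_production({1: 1.0, 2: 0.0, 3: 1.0})

    def test_from_spectrum_sheldon_case(self):
        assert transfer_efficiency_from_spectrum(-1.0, 1e4, 0.25) == pytest.approx(0.1)

    def test_from_spectrum_degenerate_exponent(self):
        assert transfer_efficiency_from_spectrum(-1.0, 1e4, 0.0) == pytest.approx(1.0)

    def test_monotone_in_slope(self):
        tes = [transfer_efficiency_from_spectrum(s, 1e4) for s in (-1.2, -1.0, -0.8)]
        assert tes == sorted(tes)

    def test_spectrum_and_production_routes_agree(self):
        """Both TE estimators agree on a community built to satisfy
        B_{k+1}/B_k = TE * PPMR^A by construction."""
        te, ppmr, a = 0.25, 1e3, 0.25
        # levels k at body mass M_k = PPMR^k, biomass B_k = (te * ppmr**a)**k,
        # production P_k = B_k * M_k**(-a)  =>  P_{k+1}/P_k = te
        prod = {k: (te * ppmr ** a) ** k * (ppmr ** k) ** (-a) for k in (1, 2, 3)}
        assert transfer_efficiency_production(prod) == pytest.approx(te)
        # size spectrum: one class per trophic level, spaced log2(PPMR) apart,
        # class biomass ratio te * ppmr**a by construction
        m = [k * np.log2(ppmr) for k in (1, 2, 3)]
        b = [(te * ppmr ** a) ** k for k in (1, 2, 3)]
        sss = size_spectrum_slope(m, b)
        assert transfer_efficiency_from_spectrum(sss, ppmr, a) == pytest.approx(
            te, rel=1e-9)


class TestPPMR:
    def test_identical_ratios(self):
        assert weighted_ppmr([7.0] * 4) == pytest.approx(7.0)

    def test_hand_exponent_sum(self):
        got = weighted_ppmr([1e2, 1e2, 1e4, 1e4])
        assert got == pytest.approx(10 ** 3.6, rel=1e-12)

    def test_weight_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            weighted_ppmr([1.0] * 4, (0.3, 0.3, 0.3, 0.3))


class TestSizeSpectrum:
    def test_sheldon_spectrum_slope_minus_one(self):
        assert size_spectrum_slope(range(5), [3.0] * 5) == pytest.approx(-1.0)

    def test_doubling_biomass_slope_zero(self):
        m = np.arange(6)
        assert size_spectrum_slope(m, 2.0 ** m) == pytest.approx(0.0, abs=1e-12)

    def test_quadrupling_biomass_slope_plus_one(self):
        m = np.arange(6)
        assert size_spectrum_slope(m, 2.0 ** (2 * m)) == pytest.approx(1.0)

    def test_needs_two_nonempty_classes(self):
        with pytest.raises(FlowNetworkError):
            size_spectrum_slope([1, 2, 3], [0.0, 5.0, 0.0])


class TestMetabolicActivity:
    def test_p_equals_b(self):
        tot, per = metabolic_activity([1.0, 2.0], [1.0, 2.0])
        assert tot == pytest.approx(1.0)
        np.testing.assert_allclose(per, [1.0, 1.0])

    def test_hand_ratio(self):
        tot, _ = metabolic_activity([10.0, 2.0], [20.0, 20.0])
        assert tot == pytest.approx(0.3)

    def test_allometric_recovery(self):
        mass = np.array([1.0, 10.0, 100.0, 1e4])
        pb = 3.0 * mass ** (-0.25)
        assert fit_allometric_exponent(pb, mass) == pytest.approx(-0.25)


class TestResidenceTime:
    def test_stock_over_outflow(self):
        net = make_net(("A",), {}, imports={"A": 20.0},
                       exports={"A": 12.0}, respiration={"A": 8.0})
        assert system_residence_time(net, {"A": 100.0}) == pytest.approx(5.0)

    def test_linear_in_stock(self, scenario):
        net = scenario.networks["CWP"]["C"]
        stock = {n: 50.0 for n in net.nodes}
        assert system_residence_time(net, {n: 100.0 for n in net.nodes}) == (
            pytest.approx(2 * system_residence_time(net, stock)))

    def test_zero_outflow_errors(self):
        net = make_net(("A", "B"), {("A", "B"): 1.0})
        with pytest.raises(FlowNetworkError, match="outflow"):
            system_residence_time(net, {"A": 1.0})


class TestDiets:
    def test_fractions(self):
        net = make_net(("Alg", "Bac", "Graz"),
                       {("Alg", "Graz"): 9.0, ("Bac", "Graz"): 1.0})
        out = diet_composition(net, {"Alg": "autotroph", "Bac": "bacterial"})
        assert out["per_consumer"]["Graz"] == pytest.approx(
            {"autotroph": 0.9, "bacterial": 0.1})
        assert sum(out["pooled"].values()) == pytest.approx(1.0)

    def test_fractions_sum_to_one_per_consumer(self, scenario):
        net = scenario.networks["Summer"]["C"]
        classes = {"Phy": "autotroph", "Bac": "bacterial",
                   **{g: "animal" for g in ("HNF", "Cil", "Rot", "HerbCru",
                                            "CarnCru", "Fish")}}
        out = diet_composition(net, classes,
                               consumers=("Cil", "Rot", "HerbCru"))
        for fr in out["per_consumer"].values():
            assert sum(fr.values()) == pytest.approx(1.0)

    def test_stoichiometry_single_prey(self):
        c = make_net(("A", "X"), {("A", "X"): 100.0})
        p = make_net(("A", "X"), {("A", "X"): 1.0}, element="P")
        assert diet_stoichiometry(c, p)["X"] == pytest.approx(100.0)

    def test_stoichiometry_flow_weighted_pooling(self):
        c = make_net(("A", "B", "X"), {("A", "X"): 100.0, ("B", "X"): 100.0})
        p = make_net(("A", "B", "X"), {("A", "X"): 2.0, ("B", "X"): 2.0 / 3.0},
                     element="P")
        assert diet_stoichiometry(c, p)["X"] == pytest.approx(75.0)

    def test_stoichiometry_scales_with_c_flows(self):
        c = make_net(("A", "X"), {("A", "X"): 10.0})
        p = make_net(("A", "X"), {("A", "X"): 0.1}, element="P")
        r1 = diet_stoichiometry(c, p)["X"]
        r2 = diet_stoichiometry(c.scaled(2.0), p)["X"]
        assert r2 == pytest.approx(2 * r1)

    def test_topology_mismatch_errors(self):
        c = make_net(("A", "X"), {("A", "X"): 1.0})
        p = make_net(("A", "X"), {}, element="P")
        with pytest.raises(FlowNetworkError, match="link set"):
            diet_stoichiometry(c, p)


class TestChainRestriction:
    def test_grazing_chain_drops_detrital_path(self, scenario):
        net = scenario.networks["Autumn"]["C"]
        sub = restrict_chain(net, (PDOM, "Bac"))
        assert PDOM not in sub.nodes and "Bac" not in sub.nodes
        dec = trophic_positions(sub)
        assert dec.tp["Phy"] == 1.0
        assert all(dec.tp[n] > 1.0 for n in sub.nodes if n != "Phy")
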