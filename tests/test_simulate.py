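"""Steady-state label simulation: closed forms, invariants, and the
EMU-vs-brute-force cross-validation."""

import numpy as np
import pytest

from hetflux import synth
from hetflux.midtools import fractional_enrichment
from hetflux.network import NetworkError, complete_fluxes, parse_network
from hetflux.simulate import (
    FragmentTarget,
    IsotopomerDistribution,
    SubstrateLabelling,
    decompose_emus,
    parse_fragment,
    positional_abundances,
    simulate_isotopomers_emu,
    simulate_isotopomers_oracle,
    simulate_mids,
    sweep_toy_network,
)


def toy_b_labelled(n: float, xch01: float) -> float:
    """Closed-form labelled fraction of B in the reversible branch network.

    From the steady-state balances with raw exchange e = xch01/(1-xch01):
    x = (n + 2e - ne) / (1 + 3e - 2ne).
    """
    e = xch01 / (1.0 - xch01)
    return (n + 2 * e - n * e) / (1 + 3 * e - 2 * n * e)


class TestTracers:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SubstrateLabelling({"S": {"10": 0.5, "11": 0.4}})

    def test_emu_mid_mixes_patterns(self):
        tr = SubstrateLabelling({"S": {"10": 0.8, "11": 0.2}})
        np.testing.assert_allclose(tr.emu_mid("S", (1, 2)), [0.0, 0.8, 0.2])
        np.testing.assert_allclose(tr.emu_mid("S", (2,)), [0.8, 0.2])

    def test_natural_abundance_fills_unlabelled_positions(self):
        tr = SubstrateLabelling({"S": {"00": 1.0}}, natural_abundance=0.011)
        mid = tr.emu_mid("S", (1, 2))
        assert mid[0] == pytest.approx(0.989**2)
        assert fractional_enrichment(mid) == pytest.approx(0.011)


class TestToyClosedForms:
    def test_fig1_b_is_linear_in_branch_flux(self, fig1, toy_tracer):
        net, param = fig1
        for n in np.linspace(0, 1, 11):
            state = complete_fluxes(param, [n])
            dists = simulate_isotopomers_emu(net, state, toy_tracer, ["A", "B", "C"])
            b = dists[1]
            assert b["1"] == pytest.approx(n, abs=1e-12)
            # A passes the substrate through unchanged when nothing condenses
            assert dists[0]["10"] == pytest.approx(1.0, abs=1e-12)

    def test_fig2_b_closed_form(self, fig2, toy_tracer):
        net, param = fig2
        for n in (0.0, 0.25, 0.5, 0.9, 1.0):
            for x in (0.0, 0.3, 0.5, 0.99):
                state = complete_fluxes(param, [n, x])
                dists = simulate_isotopomers_emu(net, state, toy_tracer, ["B"])
                assert dists[0]["1"] == pytest.approx(
                    toy_b_labelled(n, x), abs=1e-9
                ), (n, x)

    def test_fig2_intermediate_distribution_at_half(self, fig2, toy_tracer):
        net, param = fig2
        state = complete_fluxes(param, [0.5, 0.5])
        (a,) = simulate_isotopomers_emu(net, state, toy_tracer, ["A"])
        assert a["10"] == pytest.approx(13 / 18, abs=1e-10)
        assert a["01"] == pytest.approx(1 / 18, abs=1e-10)
        assert a["11"] == pytest.approx(1 / 9, abs=1e-10)
        assert a["00"] == pytest.approx(1 / 9, abs=1e-10)

    def test_doubly_and_unlabelled_isotopomers_match(self, fig2, toy_tracer):
        # recombination of B + C makes 00 and 11 in A at identical abundance
        net, param = fig2
        for n in (0.1, 0.5, 0.8):
            for x in (0.2, 0.7, 0.99):
                state = complete_fluxes(param, [n, x])
                (a,) = simulate_isotopomers_emu(net, state, toy_tracer, ["A"])
                assert a["00"] == pytest.approx(a["11"], abs=1e-9)

    def test_label_conservation_between_products(self, fig2, toy_tracer):
        net, param = fig2
        for n in (0.0, 0.4, 1.0):
            for x in (0.0, 0.6, 0.99):
                state = complete_fluxes(param, [n, x])
                b, c = simulate_isotopomers_emu(net, state, toy_tracer, ["B", "C"])
                assert b["1"] + c["1"] == pytest.approx(1.0, abs=1e-9)

    def test_pass_through_network_preserves_substrate(self):
        net = parse_network(
            "METABOLITES\nS 2 substrate\nA 2 internal\nX 2 sink\n"
            "REACTIONS\nR0: S (ab) -> A (ab)\nR1: A (ab) -> X (ab)\n"
            "FREE\nR0.net in [0, 2]\n"
        )
        tr = SubstrateLabelling({"S": {"10": 0.7, "01": 0.3}})
        from hetflux.network import free_flux_basis

        param = free_flux_basis(net)
        state = complete_fluxes(param, [1.0])
        (a,) = simulate_isotopomers_oracle(net, state, tr, ["A"])
        np.testing.assert_allclose(
            a.abundances, tr.isotopomer_distribution("S", 2), atol=1e-12
        )


class TestEMUDecomposition:
    def test_fig1_products_need_only_single_carbons(self, fig1):
        net, _ = fig1
        system = decompose_emus(net, ["B[1-1]", "C[1-1]"])
        assert all(len(e[1]) == 1 for e in system.unknowns)

    def test_canonical_alanine_requires_pyruvate(self, canonical, panel_targets):
        net, _ = canonical
        system = decompose_emus(net, [panel_targets["Ala_M-57"]])
        assert ("PYR", frozenset({1, 2, 3})) in system.unknowns

    def test_out_of_range_carbon_is_rejected(self, fig1):
        net, _ = fig1
        with pytest.raises(NetworkError, match="carbon index"):
            decompose_emus(net, ["A[1-4]"])

    def test_unreachable_fragment_is_named(self):
        net = parse_network(
            "METABOLITES\nS 2 substrate\nA 2 internal\nX 2 sink\nQ 1 internal\n"
            "Qs 1 sink\n"
            "REACTIONS\nR0: S (ab) -> A (ab)\nR1: A (ab) -> X (ab)\n"
            "RQ: Q (a) -> Qs (a) rev\n"
        )
        with pytest.raises(NetworkError, match="Q"):
            decompose_emus(net, ["Q[1-1]"])

    def test_fragment_spec_grammar(self):
        assert parse_fragment("PYR[1-3]").parts == (("PYR", (1, 2, 3)),)
        assert parse_fragment("OAA[1,3]").parts == (("OAA", (1, 3)),)
        with pytest.raises(ValueError):
            parse_fragment("not a fragment!")


class TestEMUAgainstOracle:
    """The production EMU cascade must reproduce the brute-force isotopomer
    balance on every network small enough to enumerate."""

    @pytest.mark.parametrize("case", ["fig1", "fig2", "minicycle"])
    def test_random_flux_states_agree(self, case, request, toy_tracer):
        net, param = request.getfixturevalue(case)
        rng = np.random.default_rng(hash(case) % 2**31)
        tracer = (
            toy_tracer
            if case != "minicycle"
            else SubstrateLabelling({"S": {"10": 0.6, "11": 0.4}})
        )
        mets = [
            m for m in net.internal_names() if net.metabolites[m].n_carbons > 0
        ]
        states = synth.random_feasible_states(param, 12, rng)
        for _, state in states:
            emu = simulate_isotopomers_emu(net, state, tracer, mets)
            oracle = simulate_isotopomers_oracle(net, state, tracer, mets)
            for d_e, d_o in zip(emu, oracle):
                np.testing.assert_allclose(
                    d_e.abundances, d_o.abundances, atol=1e-8,
                    err_msg=f"{case}:{d_e.metabolite}",
                )

    def test_oracle_size_limit(self, canonical, table1_state, toy_tracer):
        net, _ = canonical
        state, _ = table1_state
        with pytest.raises(NetworkError, match="size limit"):
            simulate_isotopomers_oracle(net, state, toy_tracer, ["G6P"])


class TestIsotopeBalance:
    def test_labelled_inflow_equals_outflow_at_every_pool(self, minicycle):
        # flux-weighted 13C balance: per pool, labelled carbon carried in by
        # producing steps equals labelled carbon carried out by consuming steps
        from hetflux.simulate import _unidirectional_steps

        net, param = minicycle
        tracer = SubstrateLabelling({"S": {"10": 1.0}})
        rng = np.random.default_rng(7)
        for _, state in synth.random_feasible_states(param, 5, rng):
            mets = ["AC", "OA", "CIT", "CO2"]
            dists = {
                d.metabolite: d
                for d in simulate_isotopomers_emu(net, state, tracer, mets)
            }
            # per-position labelled fractions of every pool incl. substrates
            marg = {m: positional_abundances(d) for m, d in dists.items()}
            marg["S"] = positional_abundances(
                IsotopomerDistribution(
                    "S", tracer.isotopomer_distribution("S", 2)
                )
            )
            for m in mets:
                inflow = outflow = 0.0
                for st_ in _unidirectional_steps(net):
                    v = (
                        state.forward(st_.reaction)
                        if st_.forward
                        else state.backward(st_.reaction)
                    ) * st_.weight
                    # label delivered into m: trace each product carbon of m
                    # back to the reactant position carrying it
                    reactant_pos = {
                        ch: (rm, k)
                        for rm, rlbl in st_.reactants
                        for k, ch in enumerate(rlbl)
                    }
                    for pmet, plbl in st_.products:
                        if pmet != m:
                            continue
                        for ch in plbl:
                            rm, k = reactant_pos[ch]
                            inflow += v * marg[rm][k]
                    for rmet, rlbl in st_.reactants:
                        if rmet == m:
                            outflow += v * marg[m].sum()
                assert inflow == pytest.approx(outflow, abs=1e-9), m


class TestPositionalAbundances:
    def test_point_mass(self):
        d = IsotopomerDistribution("A", np.array([0, 1.0, 0, 0]))  # pattern 10
        np.testing.assert_allclose(positional_abundances(d), [1.0, 0.0])

    def test_mixed_distribution_marginals(self):
        a = np.zeros(4)
        a[1] = 13 / 18  # 10
        a[2] = 1 / 18  # 01
        a[3] = 1 / 9  # 11
        a[0] = 1 / 9  # 00
        d = IsotopomerDistribution("A", a)
        np.testing.assert_allclose(positional_abundances(d), [5 / 6, 1 / 6])

    def test_uniform_distribution_is_half_labelled(self):
        d = IsotopomerDistribution("A", np.full(4, 0.25))
        np.testing.assert_allclose(positional_abundances(d), [0.5, 0.5])


class TestSweep:
    def test_fig1_grid_is_linear(self, fig1, toy_tracer):
        net, _ = fig1
        grid = {"R1.net": np.linspace(0, 1, 11)}
        records = sweep_toy_network(net, grid, toy_tracer, ["A", "B", "C"])
        assert len(records) == 11
        b_labelled = [r["distributions"]["B"]["1"] for r in records]
        np.testing.assert_allclose(b_labelled, np.linspace(0, 1, 11), atol=1e-10)

    def test_fig2_zero_exchange_row_reduces_to_fig1(self, fig2, toy_tracer):
        net, _ = fig2
        records = sweep_toy_network(
            net, {"R1.net": np.array([0.0, 0.5, 1.0]), "R1.xch": np.array([0.0])},
            toy_tracer, ["B"],
        )
        for r in records:
            assert r["distributions"]["B"]["1"] == pytest.approx(
                r["free"]["R1.net"], abs=1e-10
            )

    def test_solver_stable_at_extreme_exchange(self, fig2, toy_tracer):
        net, _ = fig2
        records = sweep_toy_network(
            net, {"R1.net": np.array([0.5]), "R1.xch": np.array([0.99])},
            toy_tracer, ["A", "B", "C"],
        )
        (rec,) = records
        for dist in rec["distributions"].values():
            assert abs(dist.abundances.sum() - 1.0) < 1e-9
        assert rec["distributions"]["B"]["1"] == pytest.approx(
            toy_b_labelled(0.5, 0.99), abs=1e-9
        )


class TestCanonicalEnrichment:
    def test_uniform_tracer_enrichment_propagates_exactly(
        self, canonical, table1_state, panel_targets
    ):
        # 20% uniformly labelled glucose, closed carbon: every fragment's
        # fractional enrichment is exactly the tracer enrichment
        net, _ = canonical
        state, _ = table1_state
        tracer = synth.glucose_tracer(u13c=0.2)
        mids = simulate_mids(net, state, tracer, list(panel_targets.values()))
        enr = np.array([fractional_enrichment(m) for m in mids])
        np.testing.assert_allclose(enr, 0.200, atol=1e-9)

    def test_natural_abundance_only(self, canonical, table1_state, panel_targets):
        net, _ = canonical
        state, _ = table1_state
        tracer = synth.glucose_tracer(u13c=0.0, natural_abundance=0.011)
        mids = simulate_mids(net, state, tracer, list(panel_targets.values()))
        enr = np.array([fractional_enrichment(m) for m in mids])
        np.testing.assert_allclose(enr, 0.011, atol=1e-9)

    def test_mids_sum_to_one_and_are_nonnegative(
        self, canonical, table1_state, panel_targets
    ):
        net, _ = canonical
        state, _ = table1_state
        tracer = synth.glucose_tracer(u13c=0.2, c1=0.8)
        for mid in simulate_mids(net, state, tracer, list(panel_targets.values())):
            mid.validate(tol=1e-9)
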