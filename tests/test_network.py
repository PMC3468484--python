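"""Structure and dynamics of the mass-action assembly networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mabflux.network import (
    EXPORT_MAP,
    H_EQUIVALENTS,
    L_EQUIVALENTS,
    RateConstantSet,
    SteadyStateError,
    Topology,
    as_topology,
    build_network,
    dxdt,
    jacobian,
    network_to_json,
    reaction_fluxes,
    secretion_rates,
    simulate,
    steady_state,
)


class TestTopologyStructure:
    def test_species_counts(self):
        assert Topology.HL.n_states == 11
        assert Topology.HH.n_states == 13
        assert Topology.COMBINED.n_states == 13
        assert "HH" not in Topology.HL.species
        assert "HHL" not in Topology.HL.species

    def test_unknown_topology_is_named_in_error(self):
        with pytest.raises(ValueError, match="XYZ"):
            as_topology("XYZ")

    def test_hl_network_reaction_count(self):
        rxns = build_network(Topology.HL)
        assert len(rxns) == 14  # incl. the single dilution entry
        producers = [r for r in rxns if "LHHL" in r.products]
        assert len(producers) == 1 and producers[0].name == "dimerise_HL"

    def test_hh_network_has_heavy_dimer_route(self):
        names = {r.name for r in build_network(Topology.HH)}
        assert {"dimerise_HH", "add_L_to_HH", "add_L_to_HHL"} <= names
        assert "dimerise_HL" not in names  # no half-antibody assembly
        # HL is still present as an exported off-pathway by-product
        assert "form_HL" in names and "export_HL" in names

    def test_combined_is_union_of_routes(self):
        combined = {r.name for r in build_network(Topology.COMBINED)}
        hl = {r.name for r in build_network(Topology.HL)}
        hh = {r.name for r in build_network(Topology.HH)}
        assert combined == hl | hh
        assert set(Topology.COMBINED.species) == set(Topology.HH.species)

    def test_chain_conservation_of_assembly_stoichiometry(self):
        """Assembly reactions only rearrange chains: net H- and L-equivalent
        production is zero for every non-synthesis, non-export reaction."""
        for topo in Topology:
            for rxn in build_network(topo):
                if rxn.kind in ("zero_order", "dilution"):
                    continue
                if rxn.name.startswith(("translation", "decay", "export")):
                    continue
                for equiv in (H_EQUIVALENTS, L_EQUIVALENTS):
                    net = sum(c * equiv.get(sp, 0)
                              for sp, c in rxn.products.items())
                    net -= sum(c * equiv.get(sp, 0)
                               for sp, c in rxn.reactants.items())
                    assert net == 0, rxn.name

    def test_network_json_round_trips(self):
        import json
        doc = json.loads(network_to_json("COMBINED", RateConstantSet(mu=0.02)))
        assert doc["topology"] == "COMBINED"
        assert len(doc["species"]) == 13
        assert doc["rate_constants"]["mu"] == 0.02


class TestDerivatives:
    def test_zero_state_leaves_only_transcription(self):
        r = RateConstantSet(mu=0.02, K1=15.6, K3=1214.0, K5=100.0, K7=1e-6)
        dx = dxdt(np.zeros(11), r, "HL")
        idx = Topology.HL.index()
        assert dx[idx["H_RNA"]] == 15.6
        assert dx[idx["L_RNA"]] == 1214.0
        mask = np.ones(11, bool)
        mask[[idx["H_RNA"], idx["L_RNA"]]] = False
        assert np.all(dx[mask] == 0)

    def test_homodimer_convention_monomer_vs_dimer(self):
        # L = 2e6, K10 = 8.5e-6: dimer gain K10*L^2/2 = 1.7e7, monomer loss 2x
        r = RateConstantSet(K10=8.5e-6, mu=0.0)
        x = np.zeros(11)
        idx = Topology.HL.index()
        x[idx["L"]] = 2e6
        dx = dxdt(x, r, "HL")
        assert dx[idx["LL"]] == pytest.approx(1.7e7)
        assert dx[idx["L"]] == pytest.approx(-3.4e7)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            dxdt(np.full(11, -1.0), RateConstantSet(mu=0.01), "HL")

    def test_fitted_steady_state_is_a_fixed_point(self, fits, steady_states):
        """At the fitted 2N2 steady state every derivative is ~0 relative to
        the species scale, and inflow = outflow + mu*x per species."""
        for topo in Topology:
            res = fits[topo][0]
            x = steady_states[(topo, "2N2")]
            dx = dxdt(x, res.rates, topo)
            n_intra = len(topo.intracellular)
            assert np.max(np.abs(dx[:n_intra]) / (x[:n_intra] + 1)) < 1e-6
            # inflow = outflow + mu*x, i.e. net production including dilution
            fx = reaction_fluxes(x, res.rates, topo)
            scale = max(abs(v) for v in fx.values())
            assert np.max(np.abs(dx[:n_intra])) < 1e-6 * scale

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_chain_conservation_at_random_states(self, seed):
        """Assembly reactions conserve H- and L-equivalents at any state."""
        rng = np.random.default_rng(seed)
        topo = Topology.COMBINED
        x = rng.uniform(0, 1e7, topo.n_states)
        r = RateConstantSet(
            mu=0, K7=rng.uniform(0, 1e-6), K10=rng.uniform(0, 1e-6),
            K16=rng.uniform(0, 1e-9), K19=rng.uniform(0, 1e-7),
            K21=rng.uniform(0, 1e-5), K22=rng.uniform(0, 1e-5))
        dx = dxdt(x, r, topo)
        idx = topo.index()
        for equiv in (H_EQUIVALENTS, L_EQUIVALENTS):
            net = sum(equiv.get(sp, 0) * dx[idx[sp]] for sp in topo.species)
            assert abs(net) <= 1e-9 * np.max(np.abs(dx) + 1)


class TestSimulate:
    def test_zero_rates_trajectory_constant(self):
        x0 = np.linspace(1, 11, 11) * 1e3
        sim = simulate(RateConstantSet(), "HL", x0, 100.0,
                       t_eval=[0, 50, 100])
        assert np.allclose(sim.y, x0[:, None])

    def test_transcription_only_matches_closed_form(self):
        r = RateConstantSet(mu=0.02, K1=15.6)
        sim = simulate(r, "HL", np.zeros(11), 200.0,
                       t_eval=np.linspace(0, 200, 21), atol=1e-8)
        expect = 15.6 / 0.02 * (1 - np.exp(-0.02 * sim.t))
        assert np.allclose(sim.series("H_RNA"), expect, rtol=1e-6)

    def test_t_end_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate(RateConstantSet(), "HL", np.zeros(11), -1.0)

    def test_fitted_steady_state_persists_500h(self, fit_2n2_hl,
                                               steady_states):
        x0 = steady_states[(Topology.HL, "2N2")]
        sim = simulate(fit_2n2_hl.rates, "HL", x0, 500.0,
                       t_eval=[0, 250, 500], method="LSODA")
        n_intra = len(Topology.HL.intracellular)
        rel = np.abs(sim.y[:n_intra] - x0[:n_intra, None]) / (
            x0[:n_intra, None] + 1)
        assert np.max(rel) < 0.01

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_non_negativity_preserved(self, seed):
        rng = np.random.default_rng(seed)
        r = RateConstantSet(
            mu=rng.uniform(0.01, 0.04), K1=rng.uniform(0, 100),
            K2=rng.uniform(0, 0.4), K3=rng.uniform(0, 5000),
            K4=rng.uniform(0, 0.1), K5=rng.uniform(0, 3e4),
            K8=rng.uniform(0, 2e3), K7=rng.uniform(0, 1e-5),
            K10=rng.uniform(0, 1e-5), K16=rng.uniform(0, 1e-9),
            kexp_mab=rng.uniform(0, 0.3), kexp_hl=rng.uniform(0, 0.1),
            kexp_ll=rng.uniform(0, 10), kexp_l=rng.uniform(0, 20))
        x0 = rng.uniform(0, 1e6, 11)
        sim = simulate(r, "HL", x0, 50.0, t_eval=np.linspace(0, 50, 11),
                       method="LSODA")
        assert np.all(sim.y >= 0)


class TestSteadyState:
    def test_linear_subsystem_closed_form(self):
        # K1 = 15.6, mu = 0.020, K2 = 0 -> H.RNA = 780 (Table-level value 781)
        r = RateConstantSet(mu=0.020, K1=15.6)
        x = steady_state(r, "HL")
        assert x[Topology.HL.index()["H_RNA"]] == pytest.approx(780.0,
                                                                rel=1e-9)

    def test_zero_inflow_gives_zero_vector(self):
        x = steady_state(RateConstantSet(mu=0.02), "COMBINED")
        assert np.all(x == 0)

    def test_no_fixed_point_without_outflow(self):
        with pytest.raises(SteadyStateError):
            steady_state(RateConstantSet(mu=0.0, K1=10.0), "HL")

    def test_round_trip_reproduces_panel(self, fits, steady_states, by_name):
        """steady_state(infer(dataset)) reproduces the non-censored
        intracellular abundances within 2%."""
        for topo in Topology:
            for res in fits[topo]:
                x = steady_states[(topo, res.line)]
                data = by_name[res.line]
                idx = topo.index()
                for sp in topo.intracellular:
                    if data.is_measured(sp):
                        assert x[idx[sp]] == pytest.approx(
                            data.values[sp], rel=0.02), (topo, res.line, sp)

    def test_combined_with_zeroed_routes_matches_submodels(self, fits):
        """Zeroing one route's constants in COMBINED reproduces the other
        sub-topology exactly (trajectories and steady states)."""
        from dataclasses import replace

        rc = fits[Topology.COMBINED][0].rates
        t_eval = np.linspace(0, 50, 11)
        ci, hi = Topology.COMBINED.index(), Topology.HL.index()

        r_hl = replace(rc, K19=0.0, K21=0.0, K22=0.0)
        simC = simulate(r_hl, "COMBINED", np.zeros(13), 50, t_eval=t_eval,
                        rtol=1e-12, atol=1e-8)
        simH = simulate(r_hl, "HL", np.zeros(11), 50, t_eval=t_eval,
                        rtol=1e-12, atol=1e-8)
        for sp in Topology.HL.species:
            np.testing.assert_allclose(
                simC.y[ci[sp]], simH.y[hi[sp]],
                rtol=1e-9, atol=1e-9 * (np.max(simH.y[hi[sp]]) + 1))

        r_hh = replace(rc, K16=0.0)
        simC2 = simulate(r_hh, "COMBINED", np.zeros(13), 50, t_eval=t_eval,
                         method="LSODA")
        simH2 = simulate(r_hh, "HH", np.zeros(13), 50, t_eval=t_eval,
                         method="LSODA")
        np.testing.assert_allclose(simC2.y, simH2.y, rtol=1e-9, atol=1e-9)

    def test_secretion_rates_read_from_state(self, fit_2n2_hl):
        x = np.zeros(11)
        x[Topology.HL.index()["LHHL"]] = 12e6
        q = secretion_rates(fit_2n2_hl.rates, x, "HL")
        assert q["qmAb"] == pytest.approx(fit_2n2_hl.rates.kexp_mab * 12e6)


class TestJacobian:
    def test_extracellular_columns_never_feed_back(self, fits, steady_states):
        topo = Topology.COMBINED
        res = fits[topo][0]
        A = jacobian(steady_states[(topo, "2N2")], res.rates, topo)
        n_intra = len(topo.intracellular)
        assert np.all(A[:n_intra, n_intra:] == 0)
        assert np.all(A[n_intra:, n_intra:] == 0)

    def test_matches_central_finite_differences_at_operating_point(
            self, fits, steady_states):
        topo = Topology.COMBINED
        res = fits[topo][0]
        x = steady_states[(topo, "2N2")]
        A = jacobian(x, res.rates, topo)
        fd = np.zeros_like(A)
        for j in range(topo.n_states):
            h = 1e-4 * abs(x[j]) or 1e-4
            e = np.zeros(topo.n_states)
            e[j] = h
            fd[:, j] = (dxdt(x + e, res.rates, topo)
                        - dxdt(x - e, res.rates, topo)) / (2 * h)
        scale = np.abs(A) + 1e-9 * np.max(np.abs(A))
        assert np.max(np.abs(A - fd) / scale) < 1e-6
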