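"""Linearisation, step responses, observability and conditioning."""

import numpy as np
import pytest

from mabflux.engineering import (
    LinearStateModel,
    conditioning,
    linearise,
    minimal_observable_set,
    observability,
    observability_matrix,
    step_response_compare,
)
from mabflux.network import RateConstantSet, Topology, simulate


class TestLinearise:
    def test_linear_system_linearises_exactly(self):
        """With all bimolecular constants zero the model is linear: A is
        state-independent and linear and nonlinear trajectories coincide."""
        r = RateConstantSet(mu=0.02, K1=15.6, K2=0.01, K3=1214.0, K4=0.02,
                            K5=100.0, K8=10.0, kexp_l=0.5)
        x_op = np.zeros(11)
        div = step_response_compare(r, "HL", x_op, parameter="K1", step=0.5,
                                    horizon=200.0)
        assert max(div.values()) < 1e-8

    def test_block_triangular_structure(self, fits, steady_states):
        model = linearise(fits[Topology.COMBINED][0].rates, "COMBINED",
                          steady_states[(Topology.COMBINED, "2N2")])
        n_intra = len(Topology.COMBINED.intracellular)
        assert np.all(model.A[:n_intra, n_intra:] == 0)

    def test_warns_away_from_fixed_point(self, fits):
        with pytest.warns(UserWarning, match="not a fixed point"):
            linearise(fits[Topology.HL][0].rates, "HL",
                      np.full(11, 1e6))


class TestStepResponse:
    def test_zero_step_zero_divergence(self, fit_2n2_hl, steady_states):
        div = step_response_compare(fit_2n2_hl.rates, "HL",
                                    steady_states[(Topology.HL, "2N2")],
                                    parameter="K1", step=0.0, horizon=50.0)
        assert max(div.values()) < 1e-9

    def test_small_step_small_divergence(self, fit_2n2_hl, steady_states):
        """1% transcription step: linear and nonlinear model agree within 2%
        over 100 h (first-order accuracy of the linearisation)."""
        div = step_response_compare(fit_2n2_hl.rates, "HL",
                                    steady_states[(Topology.HL, "2N2")],
                                    parameter="K1", step=0.01, horizon=100.0)
        assert max(div.values()) < 0.02

    def test_divergence_monotone_in_step_size(self, fit_2n2_hl,
                                              steady_states):
        x = steady_states[(Topology.HL, "2N2")]
        divs = [max(step_response_compare(
            fit_2n2_hl.rates, "HL", x, parameter="K5", step=s,
            horizon=100.0).values()) for s in (0.01, 0.10, 0.50)]
        assert divs[0] <= divs[1] <= divs[2]

    def test_invalid_step_rejected(self, fit_2n2_hl, steady_states):
        with pytest.raises(ValueError):
            step_response_compare(fit_2n2_hl.rates, "HL",
                                  steady_states[(Topology.HL, "2N2")],
                                  step=-1.5)


class TestObservability:
    def test_all_states_measured_reconstructs_output(self, fits,
                                                     steady_states):
        model = linearise(fits[Topology.COMBINED][0].rates, "COMBINED",
                          steady_states[(Topology.COMBINED, "2N2")])
        rank, ok = observability(model, model.species)
        assert ok and rank == model.n

    def test_extracellular_sensors_see_intracellular_dynamics(
            self, fits, steady_states):
        """Cumulative secreted pools integrate the intracellular dynamics,
        so sensors on them reconstruct qmAb (through the mAb_ex slope)."""
        model = linearise(fits[Topology.COMBINED][0].rates, "COMBINED",
                          steady_states[(Topology.COMBINED, "2N2")])
        rank, ok = observability(model, ["mAb_ex", "HL_ex", "LL_ex", "L_ex"])
        assert ok
        assert rank >= 9

    def test_empty_subset_rejected(self, fits, steady_states):
        model = linearise(fits[Topology.COMBINED][0].rates, "COMBINED",
                          steady_states[(Topology.COMBINED, "2N2")])
        with pytest.raises(ValueError):
            observability(model, [])

    def test_zero_output_row_has_rank_zero(self):
        O = observability_matrix(np.eye(3), np.zeros((1, 3)))
        assert not np.any(O)

    def test_rank_invariant_under_similarity_transform(self, fits,
                                                       steady_states):
        model = linearise(fits[Topology.COMBINED][0].rates, "COMBINED",
                          steady_states[(Topology.COMBINED, "2N2")])
        rng = np.random.default_rng(3)
        n = model.n
        T = rng.normal(size=(n, n)) + 3 * np.eye(n)
        A2 = T @ model.A @ np.linalg.inv(T)
        C2 = model.C @ np.linalg.inv(T)
        r1 = np.linalg.matrix_rank(observability_matrix(model.A, model.C),
                                   tol=1e-8)
        r2 = np.linalg.matrix_rank(observability_matrix(A2, C2), tol=1e-8)
        assert r1 == r2 == 9

    def test_adding_sensors_never_decreases_rank(self, fits, steady_states):
        model = linearise(fits[Topology.COMBINED][0].rates, "COMBINED",
                          steady_states[(Topology.COMBINED, "2N2")])
        subset = ["LHHL"]
        prev = observability(model, subset)[0]
        for sp in ("HL", "H", "L_RNA", "LL"):
            subset.append(sp)
            rank = observability(model, subset)[0]
            assert rank >= prev
            prev = rank


class TestMinimalSet:
    def test_diagonal_system_minimal_set_is_output_state(self):
        A = np.diag([-1.0, -2.0, -3.0])
        C = np.array([[1.0, 0.0, 0.0]])
        model = LinearStateModel(A, C, np.zeros(3), ("s1", "s2", "s3"),
                                 ("y",), Topology.HL,
                                 RateConstantSet(mu=0.01))
        model.topology = Topology.HL  # species names unused beyond labels
        rep = minimal_observable_set(model)
        assert rep.minimal_count == 1
        assert rep.minimal_sets == [("s1",)]

    def test_combined_model_needs_exactly_nine_intracellular_states(
            self, fits, steady_states):
        """The secretion behaviour of the 13-state combined model is fixed by
        the nine intracellular abundances at every operating point."""
        for res in fits[Topology.COMBINED]:
            model = linearise(res.rates, "COMBINED",
                              steady_states[(Topology.COMBINED, res.line)])
            rep = minimal_observable_set(model)
            assert rep.minimal_count == 9, res.line
            assert rep.all_intracellular
            assert rep.minimal_sets == [Topology.COMBINED.intracellular]

    def test_hl_model_minimal_set_excludes_extracellular(self, fits,
                                                         steady_states):
        res = fits[Topology.HL][0]
        model = linearise(res.rates, "HL",
                          steady_states[(Topology.HL, "2N2")])
        rep = minimal_observable_set(model)
        assert rep.minimal_count == 7
        assert rep.all_intracellular

    def test_qmab_only_output_excludes_the_ll_dead_end(self, fits,
                                                       steady_states):
        """With qmAb as the sole output the light-chain dimer drops out:
        LL never feeds back into the assembly chain, so only 8 states
        matter.  (The four-rate secretion block is the default output.)"""
        res = fits[Topology.COMBINED][0]
        model = linearise(res.rates, "COMBINED",
                          steady_states[(Topology.COMBINED, "2N2")],
                          output="qmAb")
        rep = minimal_observable_set(model)
        assert rep.minimal_count == 8
        assert all("LL" != sp for sp in rep.minimal_sets[0])


class TestConditioning:
    def test_identity(self):
        assert conditioning(np.eye(4)).condition == pytest.approx(1.0)

    def test_closed_form_diagonal(self):
        rep = conditioning(np.diag([1e8, 1e-2]))
        assert rep.condition_raw == pytest.approx(1e10)

    def test_rank_deficient_reports_infinite_raw_condition(self):
        rep = conditioning(np.array([[1.0, 0.0], [2.0, 0.0]]))
        assert np.isinf(rep.condition_raw)
        assert rep.rank == 1

    def test_state_matrix_is_ill_conditioned(self, fits, steady_states):
        model = linearise(fits[Topology.COMBINED][0].rates, "COMBINED",
                          steady_states[(Topology.COMBINED, "2N2")])
        n_intra = len(Topology.COMBINED.intracellular)
        rep = conditioning(model.A[:n_intra, :n_intra])
        assert rep.condition > 1e3  # h^-1 scales span decades
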