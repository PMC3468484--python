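"""Productivity prediction for an unseen cell line from a reduced panel.

The observability analysis shows that the secretion behaviour of the model
is determined by the nine intracellular abundances (plus growth rate), so a
new line can be characterised without mRNA measurements or supernatant time
courses.  The missing pieces are supplied by transfer from trained lines:

* export constants kexp_* transfer as the geometric mean over training
  lines whose defining q-value was actually measured (censored-derived
  export constants are bounds, not measurements, and are excluded);
* translation constants K5/K8 transfer likewise, giving implied mRNA levels
  (production flux / translation constant) and hence K1, K3;
* everything else (K7, K10, K16, the HH chain) is re-inferred from the new
  panel itself with the transferred exports standing in for the unmeasured
  secretion rates.

Two prediction routes are computed: the *nonlinear* route solves the fully
parameterised mass-action model for its steady state and reads
qmAb = kexp_mAb * [LHHL]; the *linear* route takes a single first-order
(Newton) step from each training line's operating point under the new
parameter set.  The linear route is retained for comparison only — it
demonstrates that the linearised model, useful for structural analysis, is
not itself a reliable productivity predictor.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .engineering import ObservabilityReport, linearise, minimal_observable_set
from .inference import (
    ABUNDANCE_KEYS,
    Censor,
    CellLineDataset,
    DETECTION_LIMIT,
    InferenceResult,
    Q_OF_SPECIES,
    infer_rate_constants,
)
from .network import (
    EXPORT_MAP,
    RateConstantSet,
    Topology,
    as_topology,
    dxdt,
    jacobian,
    secretion_rates,
    steady_state,
)

__all__ = ["ReducedPanel", "PredictionReport", "estimate_k8",
           "infer_rna_constants", "predict_qmab", "transfer_constant"]

#: the reduced measurement set: the nine intracellular species
REDUCED_SPECIES = ("H_RNA", "L_RNA", "H", "L", "LL", "HL", "HH", "HHL",
                   "LHHL")


@dataclass
class ReducedPanel:
    """Growth rate plus the nine intracellular abundances (mRNA optional)."""

    name: str
    mu: float
    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, Censor] = field(default_factory=dict)
    detection_limit: float = DETECTION_LIMIT

    @classmethod
    def from_dataset(cls, data: CellLineDataset) -> "ReducedPanel":
        """Strip a full panel down to the reduced (intracellular) set."""
        vals = {k: v for k, v in data.values.items() if k in REDUCED_SPECIES}
        flags = {k: f for k, f in data.flags.items() if k in REDUCED_SPECIES}
        return cls(data.name, data.mu, vals, flags, data.detection_limit)

    def flag(self, key: str) -> Censor:
        if key in self.flags:
            return self.flags[key]
        return Censor.MEASURED if key in self.values else Censor.MISSING

    def abundance(self, sp: str) -> float:
        if self.flag(sp) is Censor.MISSING:
            raise KeyError(f"{self.name}: {sp} is missing")
        return self.values[sp]


def transfer_constant(trained: Sequence[InferenceResult], name: str,
                      estimator: str = "geometric") -> float:
    """Pool one constant across training lines.

    Lines whose value of the constant was derived from censored inputs are
    excluded (their constants are bounds, not estimates).  ``estimator`` is
    ``geometric`` (default; the constants are positive and span decades),
    ``arithmetic``, or ``max_q`` (the line with the highest measured qmAb —
    a nearest-to-productive proxy).
    """
    usable = [r for r in trained
              if name not in r.censored_derived and r.rates.get(name) > 0]
    if not usable:
        raise ValueError(f"no training line provides an uncensored {name}")
    vals = np.array([r.rates.get(name) for r in usable])
    if estimator == "geometric":
        return float(np.exp(np.mean(np.log(vals))))
    if estimator == "arithmetic":
        return float(np.mean(vals))
    if estimator == "max_q":
        best = max(usable, key=lambda r: r.dataset.q("qmAb", "zero")
                   if r.dataset else 0.0)
        return float(best.rates.get(name))
    raise ValueError(f"unknown estimator {estimator!r}")


def _transfer_mean(trained: Sequence[InferenceResult], name: str) -> float:
    """Arithmetic mean without censoring exclusion (for decay constants)."""
    return float(np.mean([r.rates.get(name) for r in trained]))


def _production_fluxes(reduced: ReducedPanel, kexp: Mapping[str, float],
                       topology: Topology, route_fraction: float,
                       ) -> dict[str, float]:
    """Heavy-/light-chain production fluxes implied by the reduced panel."""
    mu = reduced.mu

    def level(sp, dilution=False):
        f = reduced.flag(sp)
        if f is Censor.BELOW_LIMIT:
            return 0.0 if dilution else reduced.values[sp]
        return reduced.abundance(sp)

    q = {name: kexp[kname] * level(sp)
         for sp, (_, kname) in EXPORT_MAP.items()
         for name in (Q_OF_SPECIES[sp],)}
    phi = {Topology.HL: 0.0, Topology.HH: 1.0,
           Topology.COMBINED: route_fraction}[topology]
    f_lhhl = q["qmAb"] + mu * level("LHHL", dilution=True)
    v16 = (1 - phi) * f_lhhl
    v_chain = phi * f_lhhl
    v7 = 2 * v16 + q["qHL"] + mu * level("HL", dilution=True)
    v10 = q["qLL"] + mu * level("LL", dilution=True)
    p_h = v7 + 2 * v_chain + mu * level("H", dilution=True)
    p_l = (v7 + 2 * v10 + 2 * v_chain + q["qL"]
           + mu * level("L", dilution=True))
    return {"P_H": p_h, "P_L": p_l, "F_LHHL": f_lhhl, **q}


def estimate_k8(reduced: ReducedPanel,
                trained_by_topology: Mapping[Topology, Sequence[InferenceResult]],
                *, estimator: str = "geometric",
                route_fraction: float = 0.5) -> dict[str, float]:
    """Estimate the light-chain translation constant for a naive line.

    K8 is only identifiable from a reduced panel jointly with an assumed
    mRNA level, so the light-chain production flux implied by each
    sub-model's balances is divided by the geometric-mean training L.RNA.
    The combined-model estimate is the arithmetic mean of the HL and HH
    estimates.
    """
    ests: dict[str, float] = {}
    for topo in (Topology.HL, Topology.HH):
        trained = trained_by_topology.get(topo)
        if not trained:
            continue
        kexp = {kname: transfer_constant(trained, kname, estimator)
                for _, (_, kname) in EXPORT_MAP.items()}
        p_l = _production_fluxes(reduced, kexp, topo, route_fraction)["P_L"]
        if p_l <= 0:
            raise ValueError(f"{reduced.name}: no light-chain production "
                             "flux derivable (no L-containing species "
                             "measured)")
        lrna = np.exp(np.mean([np.log(r.dataset.value("L_RNA"))
                               for r in trained if r.dataset]))
        ests[topo.value] = p_l / float(lrna)
    if not ests:
        raise ValueError("no trained sub-models supplied")
    if len(ests) == 2:
        ests["COMBINED"] = 0.5 * (ests["HL"] + ests["HH"])
    return ests


def infer_rna_constants(reduced: ReducedPanel,
                        trained: Sequence[InferenceResult], *,
                        topology: Topology | str = Topology.COMBINED,
                        estimator: str = "geometric",
                        route_fraction: float = 0.5) -> dict[str, float]:
    """Estimate transcription constants K1, K3 when mRNA was not measured.

    Implied mRNA = production flux / pooled training translation constant;
    then K1 = (mu + mean K2) * [H.RNA]_implied (likewise K3).  Every
    intermediate is returned for auditability.
    """
    topology = as_topology(topology)
    kexp = {kname: transfer_constant(trained, kname, estimator)
            for _, (_, kname) in EXPORT_MAP.items()}
    k5 = transfer_constant(trained, "K5", estimator)
    k8 = transfer_constant(trained, "K8", estimator)
    if k5 <= 0 or k8 <= 0:
        raise ValueError("training translation constants are zero")
    k2 = _transfer_mean(trained, "K2")
    k4 = _transfer_mean(trained, "K4")
    p = _production_fluxes(reduced, kexp, topology, route_fraction)
    h_rna = p["P_H"] / k5
    l_rna = p["P_L"] / k8
    return {
        "K1": (reduced.mu + k2) * h_rna,
        "K3": (reduced.mu + k4) * l_rna,
        "H_RNA_implied": h_rna,
        "L_RNA_implied": l_rna,
        "K2_transfer": k2, "K4_transfer": k4,
        "K5_transfer": k5, "K8_transfer": k8,
        **{f"kexp_{k}": v for k, v in
           zip(("mab", "hl", "ll", "l"), (kexp["kexp_mab"], kexp["kexp_hl"],
                                          kexp["kexp_ll"], kexp["kexp_l"]))},
        **p,
    }


@dataclass
class PredictionReport:
    line: str
    topology: Topology
    qmab_nonlinear: float
    qmab_linear: float
    qmab_linear_per_line: dict[str, float]
    rates: RateConstantSet
    steady_state: np.ndarray
    observability: ObservabilityReport
    k8_estimates: dict[str, float]
    diagnostics: dict[str, float]
    kexp_estimator: str


def _as_full_dataset(reduced: ReducedPanel, diag: Mapping[str, float],
                     ) -> CellLineDataset:
    values = dict(reduced.values)
    flags = dict(reduced.flags)
    values["H_RNA"] = diag["H_RNA_implied"]
    values["L_RNA"] = diag["L_RNA_implied"]
    flags.pop("H_RNA", None), flags.pop("L_RNA", None)
    values["H_RNA_decay"] = diag["K2_transfer"]
    values["L_RNA_decay"] = diag["K4_transfer"]
    for qname, key in (("qmAb", "qmAb"), ("qHL", "qHL"), ("qLL", "qLL"),
                       ("qL", "qL")):
        values[qname] = diag[key]
    return CellLineDataset(reduced.name, reduced.mu, values, flags,
                           detection_limit=reduced.detection_limit)


def predict_qmab(reduced: ReducedPanel,
                 trained: Sequence[InferenceResult], *,
                 topology: Topology | str = Topology.COMBINED,
                 kexp_estimator: str = "geometric",
                 route_fraction: float = 0.5,
                 trained_by_topology: Mapping[Topology, Sequence[InferenceResult]] | None = None,
                 ) -> PredictionReport:
    """Predict cell-specific productivity for a reduced panel.

    ``trained`` are inference results for the prediction topology on the
    training lines.  Raises if LHHL is censored (the prediction target's
    own precursor is then undefined).
    """
    topology = as_topology(topology)
    if reduced.flag("LHHL") is not Censor.MEASURED:
        raise ValueError(f"{reduced.name}: LHHL is censored; qmAb "
                         "prediction undefined")
    diag = infer_rna_constants(reduced, trained, topology=topology,
                               estimator=kexp_estimator,
                               route_fraction=route_fraction)
    full = _as_full_dataset(reduced, diag)
    result = infer_rate_constants(full, topology,
                                  route_fraction=route_fraction)
    rates = result.rates
    x_ss = steady_state(rates, topology, x0=result.operating_point())
    q_nl = secretion_rates(rates, x_ss, topology)["qmAb"]

    # linear route: one first-order step from each training operating point
    lin: dict[str, float] = {}
    idx = topology.index()
    n_intra = len(topology.intracellular)
    for tr in trained:
        x_op = tr.operating_point()
        A = jacobian(x_op, tr.rates, topology)[:n_intra, :n_intra]
        f_new = dxdt(x_op, rates, topology)[:n_intra]
        try:
            dx = np.linalg.solve(A, -f_new)
        except np.linalg.LinAlgError:
            continue
        lhhl = x_op[idx["LHHL"]] + dx[idx["LHHL"]]
        lin[tr.line] = float(rates.kexp_mab * max(lhhl, 0.0))
    q_lin = float(np.median(list(lin.values()))) if lin else np.nan

    model = linearise(rates, topology, x_ss, output="secretion")
    report = minimal_observable_set(model)

    k8_est = {}
    if trained_by_topology:
        k8_est = estimate_k8(reduced, trained_by_topology,
                             estimator=kexp_estimator,
                             route_fraction=route_fraction)
    return PredictionReport(
        line=reduced.name, topology=topology,
        qmab_nonlinear=float(q_nl), qmab_linear=q_lin,
        qmab_linear_per_line=lin, rates=rates, steady_state=x_ss,
        observability=report, k8_estimates=k8_est,
        diagnostics=diag, kexp_estimator=kexp_estimator)
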