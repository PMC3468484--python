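"""Steady-state inference of apparent rate constants from measured panels.

The central assumption is zero intracellular protein turnover: at steady
state the entire outflow of mass is the four secretion rates (qmAb, qHL,
qLL, qL) plus dilution by growth.  Mass conservation then fixes the
molecular flux through every branch of the assembly network, and apparent
rate constants follow by dividing each flux by the steady-state abundance(s)
of its substrate(s).

Censoring conventions (documented in docs/methods.md):

* abundances below the detection limit contribute zero dilution flux, but
  stand in at the detection limit where a constant needs them as a divisor;
* secretion rates reported only as "< limit" are imputed at the detection
  limit by default (``censored_q="limit"``), because a bounded but nonzero
  export is the physically sensible reading for a line that demonstrably
  secretes product; ``censored_q="zero"`` is available;
* constants whose computation touched any censored input are flagged in
  ``InferenceResult.censored_derived``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import block_diag, svd
from scipy.optimize import minimize_scalar

from .network import (
    EXPORT_MAP,
    RateConstantSet,
    Topology,
    as_topology,
    build_network,
    secretion_rates,
    steady_state,
)

__all__ = [
    "Censor",
    "CellLineDataset",
    "FluxMap",
    "InferenceResult",
    "InconsistentMeasurementsError",
    "infer_fluxes",
    "infer_rate_constants",
    "fit_censored_intermediates",
    "combined_pseudo_inverse_fit",
    "ConditioningReport",
]

DETECTION_LIMIT = 1e5  # molecules/cell, full-antibody western detection limit

ABUNDANCE_KEYS = ("H_RNA", "L_RNA", "H", "L", "LL", "HL", "HH", "HHL", "LHHL")
Q_KEYS = ("qL", "qLL", "qmAb", "qHL")
DECAY_KEYS = ("H_RNA_decay", "L_RNA_decay")

#: q-value measured for each exported species
Q_OF_SPECIES = {"LHHL": "qmAb", "HL": "qHL", "LL": "qLL", "L": "qL"}


class Censor(enum.Enum):
    MEASURED = "measured"
    BELOW_LIMIT = "below_limit"
    ABOVE_LIMIT = "above_limit"
    MISSING = "missing"


class InconsistentMeasurementsError(ValueError):
    """Measurements imply a negative flux under the chosen topology."""


@dataclass
class CellLineDataset:
    """One cell line's steady-state measurement panel.

    ``values`` maps quantity names (ABUNDANCE_KEYS, Q_KEYS, DECAY_KEYS) to
    numbers; censored entries carry the censoring limit, not a guess, with
    the corresponding flag in ``flags``.
    """

    name: str
    mu: float
    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, Censor] = field(default_factory=dict)
    detection_limit: float = DETECTION_LIMIT

    def __post_init__(self):
        if not (np.isfinite(self.mu) and self.mu >= 0):
            raise ValueError(f"{self.name}: growth rate mu must be "
                             f"non-negative, got {self.mu!r}")
        for k, v in self.values.items():
            if self.flag(k) is not Censor.MISSING and (
                    not np.isfinite(v) or v < 0):
                raise ValueError(f"{self.name}: {k} must be >= 0, got {v!r}")

    def flag(self, key: str) -> Censor:
        if key in self.flags:
            return self.flags[key]
        return Censor.MEASURED if key in self.values else Censor.MISSING

    def is_measured(self, key: str) -> bool:
        return self.flag(key) is Censor.MEASURED

    def value(self, key: str) -> float:
        if self.flag(key) is Censor.MISSING:
            raise KeyError(f"{self.name}: {key} is missing")
        return self.values[key]

    # -- censoring policies -------------------------------------------------
    def abundance_for_dilution(self, sp: str) -> float:
        """Abundance entering a dilution flux (censored -> 0)."""
        f = self.flag(sp)
        if f is Censor.MEASURED:
            return self.values[sp]
        if f is Censor.BELOW_LIMIT:
            return 0.0
        if f is Censor.ABOVE_LIMIT:
            return self.values[sp]  # the bound: best available lower value
        raise KeyError(f"{self.name}: abundance {sp} is missing")

    def abundance_for_divisor(self, sp: str) -> float:
        """Abundance used as a divisor (censored -> the censoring bound)."""
        f = self.flag(sp)
        if f is Censor.MISSING:
            raise KeyError(f"{self.name}: abundance {sp} is missing")
        return self.values[sp]

    def q(self, name: str, censored_q: str = "limit") -> float:
        f = self.flag(name)
        if f is Censor.MEASURED:
            return self.values[name]
        if f is Censor.BELOW_LIMIT:
            return self.values[name] if censored_q == "limit" else 0.0
        raise KeyError(f"{self.name}: secretion rate {name} is "
                       f"{f.value}")

    def decay(self, key: str) -> float:
        """mRNA decay constant; upper bounds ("<x") and missing map to 0."""
        f = self.flag(key)
        if f is Censor.MEASURED:
            return self.values[key]
        return 0.0

    def scaled(self, c: float, *, qs: bool = True) -> "CellLineDataset":
        """Copy with abundances (and optionally q-values) multiplied by c."""
        keys = set(ABUNDANCE_KEYS) | (set(Q_KEYS) if qs else set())
        vals = {k: (v * c if k in keys else v) for k, v in self.values.items()}
        return replace(self, values=vals,
                       detection_limit=self.detection_limit * c)


@dataclass
class FluxMap:
    """Steady-state molecular flux through every reaction of a topology.

    Keys follow the reaction names of :func:`mabflux.network.build_network`,
    with dilution split per species (``dilution_<sp>``).  Values are reaction
    extents in molecules/cell/h (a homodimerisation extent counts dimers
    formed; the monomer is consumed at twice the extent).
    """

    topology: Topology
    fluxes: dict[str, float]
    line: str = ""

    def __getitem__(self, key: str) -> float:
        return self.fluxes[key]

    def balance_residuals(self) -> dict[str, float]:
        """Per-intracellular-species net production (should be ~0)."""
        net = {sp: 0.0 for sp in self.topology.intracellular}
        for rxn in build_network(self.topology):
            if rxn.kind == "dilution":
                for sp in rxn.reactants:
                    net[sp] -= self.fluxes[f"dilution_{sp}"]
                continue
            v = self.fluxes[rxn.name]
            for sp, c in rxn.reactants.items():
                if sp in net:
                    net[sp] -= c * v
            for sp, c in rxn.products.items():
                if sp in net:
                    net[sp] += c * v
        return net

    def max_relative_imbalance(self) -> float:
        scale = max(abs(v) for v in self.fluxes.values()) or 1.0
        return max(abs(v) for v in self.balance_residuals().values()) / scale

    def normalised(self) -> "FluxMap":
        from .pathway import normalised_fluxes  # convenience re-export
        return normalised_fluxes(self)


def _default_route_fraction(topology: Topology) -> float:
    # share of the LHHL-formation flux carried by the HH chain
    return {Topology.HL: 0.0, Topology.HH: 1.0, Topology.COMBINED: 0.5}[topology]


def _chain_levels(data: CellLineDataset, f_hh: float, hhl_level: float):
    """Closed-form HH-chain intermediates given the chain flux and [HHL].

    With K21 = K22 tied, the chain 2H -> HH -> HHL -> LHHL carrying flux
    ``f_hh`` into LHHL is solved exactly for any assumed steady [HHL]:
    K22 = f_hh / ([HHL]*[L]), [HH] from the HHL balance, K19 from the HH
    balance.  Every point of this one-parameter family reproduces the
    measured panel; the data cannot distinguish among them (the intermediates
    sit below the detection limit).
    """
    mu = data.mu
    L = data.abundance_for_divisor("L")
    H = data.abundance_for_divisor("H")
    k22 = f_hh / (hhl_level * L)
    k21 = k22
    hh_level = (f_hh + mu * hhl_level) / (k21 * L)
    k19 = 2.0 * (k21 * hh_level * L + mu * hh_level) / H**2
    return k19, k21, k22, hh_level, hhl_level


def infer_fluxes(data: CellLineDataset, topology: Topology | str, *,
                 censored_q: str = "limit",
                 route_fraction: float | None = None,
                 hh_level: float = 0.0,
                 hhl_level: float = 0.0) -> FluxMap:
    """Back-propagate mass conservation from the five measured rates.

    ``hh_level``/``hhl_level`` are the assumed steady abundances of the
    sub-detection intermediates (zero by default; the censored-intermediate
    fit supplies its fitted values so the map balances exactly).
    """
    topology = as_topology(topology)
    mu = data.mu
    q = {k: data.q(k, censored_q) for k in Q_KEYS}
    phi = (_default_route_fraction(topology) if route_fraction is None
           else float(route_fraction))
    if topology is Topology.HL:
        phi = 0.0
    elif topology is Topology.HH:
        phi = 1.0
    if not 0.0 <= phi <= 1.0:
        raise ValueError("route_fraction must lie in [0, 1]")

    dil = {sp: mu * data.abundance_for_dilution(sp)
           for sp in topology.intracellular
           if sp not in ("HH", "HHL")}
    dil["HH"] = mu * hh_level
    dil["HHL"] = mu * hhl_level

    fx: dict[str, float] = {}
    for sp in topology.intracellular:
        fx[f"dilution_{sp}"] = dil[sp]
    for sp, (_, _) in EXPORT_MAP.items():
        fx[f"export_{sp}"] = q[Q_OF_SPECIES[sp]]

    f_lhhl = q["qmAb"] + dil["LHHL"]
    v22 = phi * f_lhhl
    v16 = (1.0 - phi) * f_lhhl
    if topology is not Topology.HL:
        fx["add_L_to_HHL"] = v22
        fx["add_L_to_HH"] = v21 = v22 + dil["HHL"]
        fx["dimerise_HH"] = v19 = v21 + dil["HH"]
    else:
        v21 = v19 = 0.0
    if topology is not Topology.HH:
        fx["dimerise_HL"] = v16
    else:
        v16 = 0.0

    fx["form_HL"] = v7 = 2.0 * v16 + q["qHL"] + dil["HL"]
    fx["dimerise_LL"] = v10 = q["qLL"] + dil["LL"]
    fx["translation_H"] = v7 + 2.0 * v19 + dil["H"]
    fx["translation_L"] = (v7 + 2.0 * v10 + v21 + v22 + q["qL"] + dil["L"])
    for chain, decay_key in (("H", "H_RNA_decay"), ("L", "L_RNA_decay")):
        rna = f"{chain}_RNA"
        k_decay = data.decay(decay_key)
        level = data.abundance_for_dilution(rna)
        fx[f"transcription_{chain}"] = (mu + k_decay) * level
        fx[f"decay_{chain}_RNA"] = k_decay * level

    for name, v in fx.items():
        if v < 0:
            raise InconsistentMeasurementsError(
                f"{data.name}: inferred flux {name} = {v:g} < 0; the "
                f"measurements are inconsistent with the {topology.value} "
                "topology")
    return FluxMap(topology, fx, line=data.name)


@dataclass
class InferenceResult:
    """Inferred constants plus provenance of each."""

    rates: RateConstantSet
    topology: Topology
    line: str
    fluxes: FluxMap
    censored_derived: frozenset[str] = frozenset()
    fitted_intermediates: dict[str, float] = field(default_factory=dict)
    dataset: CellLineDataset | None = None

    def operating_point(self) -> np.ndarray:
        """Measured panel mapped onto the topology's state vector."""
        idx = self.topology.index()
        x = np.zeros(self.topology.n_states)
        assert self.dataset is not None
        for sp in self.topology.intracellular:
            if sp == "HH":
                x[idx[sp]] = self.fitted_intermediates.get("HH", 0.0)
            elif sp == "HHL":
                x[idx[sp]] = self.fitted_intermediates.get("HHL", 0.0)
            else:
                x[idx[sp]] = self.dataset.abundance_for_divisor(sp)
        return x


def _touched_censored(data: CellLineDataset, keys: Iterable[str]) -> bool:
    return any(data.flag(k) is not Censor.MEASURED for k in keys)


def infer_rate_constants(data: CellLineDataset, topology: Topology | str, *,
                         censored_q: str = "limit",
                         route_fraction: float | None = None,
                         ) -> InferenceResult:
    """Infer the full apparent-rate-constant set for one cell line.

    Flux / abundance division for everything that the panel identifies
    directly; the HH-chain constants (K19, K21 = K22) are delegated to
    :func:`fit_censored_intermediates` whenever HH or HHL is censored (which
    is the case for all the measured NS0 panels).
    """
    topology = as_topology(topology)
    hh_route = topology is not Topology.HL and (
        route_fraction is None or route_fraction > 0)
    hh_censored = (not data.is_measured("HH")) or (not data.is_measured("HHL"))
    if hh_route and hh_censored:
        return fit_censored_intermediates(data, topology,
                                          censored_q=censored_q,
                                          route_fraction=route_fraction)
    hh = data.abundance_for_divisor("HH") if hh_route else 0.0
    hhl = data.abundance_for_divisor("HHL") if hh_route else 0.0
    return _constants_from_fluxes(
        data, topology, censored_q=censored_q, route_fraction=route_fraction,
        hh_level=hh, hhl_level=hhl)


def _constants_from_fluxes(data, topology, *, censored_q, route_fraction,
                           hh_level, hhl_level,
                           chain_constants=None) -> InferenceResult:
    fx = infer_fluxes(data, topology, censored_q=censored_q,
                      route_fraction=route_fraction,
                      hh_level=hh_level, hhl_level=hhl_level)
    mu = data.mu
    div = data.abundance_for_divisor
    censored: set[str] = set()

    def _mark(const, *keys):
        if _touched_censored(data, keys):
            censored.add(const)

    kw: dict[str, float] = {"mu": mu}
    kw["K2"] = data.decay("H_RNA_decay")
    kw["K4"] = data.decay("L_RNA_decay")
    _mark("K2", "H_RNA_decay"), _mark("K4", "L_RNA_decay")
    kw["K1"] = fx["transcription_H"]
    kw["K3"] = fx["transcription_L"]
    _mark("K1", "H_RNA", "H_RNA_decay"), _mark("K3", "L_RNA", "L_RNA_decay")

    kw["K5"] = fx["translation_H"] / div("H_RNA")
    kw["K8"] = fx["translation_L"] / div("L_RNA")
    _mark("K5", "H_RNA", "H", "HL", "qHL", "qmAb", "LHHL")
    _mark("K8", "L_RNA", "L", "LL", "HL", "qL", "qLL", "qHL", "qmAb", "LHHL")

    for sp, (_, kname) in EXPORT_MAP.items():
        qname = Q_OF_SPECIES[sp]
        v = fx[f"export_{sp}"]
        x = div(sp)
        if x == 0.0:
            if v > 0:
                raise InconsistentMeasurementsError(
                    f"{data.name}: nonzero {qname} with zero abundance of "
                    f"{sp}")
            kw[kname] = 0.0
        else:
            kw[kname] = v / x
        _mark(kname, sp, qname)

    kw["K7"] = fx["form_HL"] / (div("H") * div("L"))
    _mark("K7", "H", "L", "HL", "qHL", "qmAb", "LHHL")
    kw["K10"] = 2.0 * fx["dimerise_LL"] / div("L") ** 2
    _mark("K10", "L", "LL", "qLL")

    if chain_constants is not None:
        # the chain was fitted against unobserved intermediates: any point of
        # the zero-residual family reproduces the panel, so these three are
        # bounds-dependent, not estimates.  (K5/K8 pick up only a bounded
        # mu*[intermediate] correction and remain usable estimates.)
        kw["K19"], kw["K21"], kw["K22"] = chain_constants
        censored.update(("K19", "K21", "K22"))
    elif "dimerise_HH" in fx.fluxes:
        kw["K19"] = 2.0 * fx["dimerise_HH"] / div("H") ** 2
        kw["K21"] = fx["add_L_to_HH"] / (hh_level * div("L")) if hh_level else 0.0
        kw["K22"] = (fx["add_L_to_HHL"] / (hhl_level * div("L"))
                     if hhl_level else 0.0)
        for c in ("K19", "K21", "K22"):
            _mark(c, "H", "L", "HH", "HHL", "qmAb", "LHHL")
    if "dimerise_HL" in fx.fluxes:
        kw["K16"] = 2.0 * fx["dimerise_HL"] / div("HL") ** 2
        _mark("K16", "HL", "qmAb", "LHHL")

    rates = RateConstantSet(**kw).for_topology(topology)
    fitted = {"HH": hh_level, "HHL": hhl_level} if hh_level or hhl_level else {}
    return InferenceResult(rates, topology, data.name, fx,
                           frozenset(censored), fitted, dataset=data)


def fit_censored_intermediates(data: CellLineDataset,
                               topology: Topology | str = Topology.HH, *,
                               censored_q: str = "limit",
                               route_fraction: float | None = None,
                               n_grid: int = 13) -> InferenceResult:
    """Least-squares fit of the HH-chain constants under detection limits.

    K19 and the tied pair K21 = K22 are chosen so that the model's steady
    state reproduces every measured abundance and q-value while keeping
    [HH] and [HHL] at or below the detection limit.  The fit is
    underdetermined (a one-parameter family of chain constants reproduces
    the data exactly, because the intermediates themselves are unobserved),
    so the objective carries a tiny tie-break regulariser toward
    [HHL] = detection_limit / 2; the search is a deterministic log-spaced
    grid refined by bounded scalar minimisation.
    """
    topology = as_topology(topology)
    if topology is Topology.HL:
        raise ValueError("the censored-intermediate fit applies to the HH "
                         "and COMBINED topologies")
    phi = (_default_route_fraction(topology) if route_fraction is None
           else float(route_fraction))
    limit = data.detection_limit
    mu = data.mu
    f_lhhl = data.q("qmAb", censored_q) + mu * data.abundance_for_dilution("LHHL")
    f_hh = phi * f_lhhl
    if f_hh <= 0:
        return _constants_from_fluxes(data, topology, censored_q=censored_q,
                                      route_fraction=0.0,
                                      hh_level=0.0, hhl_level=0.0)

    def _build(hhl_level: float) -> InferenceResult:
        k19, k21, k22, hh_level, _ = _chain_levels(data, f_hh, hhl_level)
        return _constants_from_fluxes(
            data, topology, censored_q=censored_q, route_fraction=phi,
            hh_level=hh_level, hhl_level=hhl_level,
            chain_constants=(k19, k21, k22))

    targets = _panel_targets(data, topology, censored_q)
    # the searched [HHL] level is additionally capped by the assembled-
    # antibody pool: an intermediate far above it is physically meaningless
    # and numerically explosive when the limit itself is relaxed
    cap = min(limit, data.abundance_for_divisor("LHHL") or limit)

    def objective(log_hhl: float) -> float:
        hhl_level = float(np.exp(log_hhl))
        res = _build(hhl_level)
        x = steady_state(res.rates, topology, x0=res.operating_point())
        sq = _relative_residuals(x, res.rates, topology, targets)
        idx = topology.index()
        penalty = sum(max(0.0, x[idx[sp]] / limit - 1.0) ** 2
                      for sp in ("HH", "HHL"))
        tie = 1e-12 * (log_hhl - np.log(cap / 2.0)) ** 2
        return float(np.sum(sq)) + 1e3 * penalty + tie

    grid = np.log(np.geomspace(cap * 1e-6, cap * 0.98, n_grid))
    values = [objective(g) for g in grid]
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    opt = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    best = opt.x if opt.fun <= values[i] else grid[i]
    return _build(float(np.exp(best)))


def _panel_targets(data: CellLineDataset, topology: Topology,
                   censored_q: str) -> dict[str, float]:
    """Measured (non-censored) quantities a fitted model must reproduce."""
    targets: dict[str, float] = {}
    for sp in topology.intracellular:
        if data.is_measured(sp):
            targets[sp] = data.values[sp]
    for qname in Q_KEYS:
        if data.is_measured(qname):
            targets[qname] = data.values[qname]
    return targets


def _relative_residuals(x: np.ndarray, rates: RateConstantSet,
                        topology: Topology,
                        targets: Mapping[str, float]) -> np.ndarray:
    idx = topology.index()
    qs = secretion_rates(rates, x, topology)
    out = []
    for key, obs in targets.items():
        model = qs[key] if key in qs else x[idx[key]]
        out.append((model - obs) / obs if obs else model)
    return np.asarray(out)


def panel_reproduction_error(result: InferenceResult, *,
                             censored_q: str = "limit") -> float:
    """Max relative error of the forward steady state vs measured panel."""
    data = result.dataset
    assert data is not None
    x = steady_state(result.rates, result.topology,
                     x0=result.operating_point())
    targets = _panel_targets(data, result.topology, censored_q)
    res = _relative_residuals(x, result.rates, result.topology, targets)
    return float(np.max(np.abs(res)))


def shared_k16(results: Sequence[InferenceResult]) -> float:
    """Pooled (geometric-mean) half-antibody dimerisation constant.

    The per-line K16 values are the defaults throughout (a single shared
    value cannot reproduce every line's steady state, since HL levels span
    three orders of magnitude across lines); this helper provides the
    single-shared-value alternative for comparison.
    """
    vals = [r.rates.K16 for r in results
            if r.rates.K16 > 0 and "K16" not in r.censored_derived]
    if not vals:
        raise ValueError("no line provides an uncensored K16")
    return float(np.exp(np.mean(np.log(vals))))


# --------------------------------------------------------------------------
# pseudo-inverse fit of the combined model
# --------------------------------------------------------------------------

UNKNOWNS = ("K1", "K3", "K5", "K8", "K7", "K10", "K16", "K19", "K21", "K22",
            "kexp_mab", "kexp_hl", "kexp_ll", "kexp_l")


@dataclass
class ConditioningReport:
    shape: tuple[int, int]
    singular_values: np.ndarray
    rank: int
    condition: float          # sigma_max / smallest singular value above cutoff
    condition_raw: float      # sigma_max / sigma_min (inf if rank-deficient)
    cutoff: float


def conditioning_of(matrix: np.ndarray,
                    rtol: float | None = None) -> ConditioningReport:
    a = np.atleast_2d(np.asarray(matrix, dtype=float))
    if a.size == 0:
        raise ValueError("matrix is empty")
    s = svd(a, compute_uv=False)
    if rtol is None:
        rtol = max(a.shape) * np.finfo(float).eps
    cutoff = s[0] * rtol if s[0] > 0 else 0.0
    above = s[s > cutoff]
    rank = int(above.size)
    cond = float(s[0] / above[-1]) if rank else np.inf
    cond_raw = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    return ConditioningReport(a.shape, s, rank, cond, cond_raw, cutoff)


def _design_matrix(data: CellLineDataset, *, censored_q: str = "limit"):
    """Linear steady-state system A theta = b in the unknown constants.

    Rows: the nine intracellular balances of the COMBINED topology followed
    by the four secretion-rate definitions.  Abundances appear at their
    divisor values (censored at the bound); dilution right-hand sides use
    the zero-flux convention for censored abundances.  No row or column
    scaling is applied: the raw system is exactly the ill-conditioned object
    whose conditioning is being reported.
    """
    col = {k: j for j, k in enumerate(UNKNOWNS)}
    mu = data.mu
    d = data.abundance_for_divisor
    dil = data.abundance_for_dilution
    hrna, lrna = d("H_RNA"), d("L_RNA")
    H, L, LLv, HLv = d("H"), d("L"), d("LL"), d("HL")
    # sub-detection HH/HHL are modelled as absent (their columns vanish and
    # the minimum-norm solution assigns the assembly flux to the HL route)
    HHv = d("HH") if data.is_measured("HH") else 0.0
    HHLv = d("HHL") if data.is_measured("HHL") else 0.0
    LHHLv = d("LHHL")
    k2, k4 = data.decay("H_RNA_decay"), data.decay("L_RNA_decay")
    q = {k: data.q(k, censored_q) for k in Q_KEYS}

    A = np.zeros((13, len(UNKNOWNS)))
    b = np.zeros(13)
    A[0, col["K1"]] = 1.0
    b[0] = (k2 + mu) * dil("H_RNA")
    A[1, col["K3"]] = 1.0
    b[1] = (k4 + mu) * dil("L_RNA")
    # H balance
    A[2, col["K5"]], A[2, col["K7"]], A[2, col["K19"]] = hrna, -H * L, -H * H
    b[2] = mu * dil("H")
    # L balance
    A[3, col["K8"]] = lrna
    A[3, col["K7"]] = -H * L
    A[3, col["K10"]] = -L * L
    A[3, col["K21"]] = -HHv * L
    A[3, col["K22"]] = -HHLv * L
    A[3, col["kexp_l"]] = -L
    b[3] = mu * dil("L")
    # LL balance
    A[4, col["K10"]], A[4, col["kexp_ll"]] = L * L / 2.0, -LLv
    b[4] = mu * dil("LL")
    # HL balance
    A[5, col["K7"]], A[5, col["K16"]], A[5, col["kexp_hl"]] = (
        H * L, -HLv * HLv, -HLv)
    b[5] = mu * dil("HL")
    # HH balance (censored levels enter at the bound with zero dilution)
    A[6, col["K19"]], A[6, col["K21"]] = H * H / 2.0, -HHv * L
    b[6] = mu * (dil("HH") if data.is_measured("HH") else 0.0)
    # HHL balance
    A[7, col["K21"]], A[7, col["K22"]] = HHv * L, -HHLv * L
    b[7] = mu * (dil("HHL") if data.is_measured("HHL") else 0.0)
    # LHHL balance
    A[8, col["K16"]] = HLv * HLv / 2.0
    A[8, col["K22"]] = HHLv * L
    A[8, col["kexp_mab"]] = -LHHLv
    b[8] = mu * dil("LHHL")
    # secretion definitions
    for i, (sp, (_, kname)) in enumerate(EXPORT_MAP.items()):
        A[9 + i, col[kname]] = d(sp)
        b[9 + i] = q[Q_OF_SPECIES[sp]]
    return A, b


@dataclass
class CombinedFitResult:
    estimates: dict[str, RateConstantSet]
    residuals: dict[str, float]          # relative residual ||A t - b||/||b||
    per_line_conditioning: dict[str, ConditioningReport]
    stacked_conditioning: ConditioningReport
    unknowns: tuple[str, ...] = UNKNOWNS


def combined_pseudo_inverse_fit(datasets: Sequence[CellLineDataset], *,
                                censored_q: str = "limit",
                                rcond: float = 1e-12) -> CombinedFitResult:
    """Moore-Penrose solution of the combined-topology steady-state system.

    The system is solved per cell line (each line has its own constants);
    the conditioning report covers both the per-line design matrices and
    the block-diagonal stack over all supplied lines, and refers to the
    *raw* (unscaled) system — that is the ill-conditioned object of
    interest, with singular values spanning ~14 decades on the measured
    panels.  For the numerical solve the columns are equilibrated to unit
    norm first (otherwise the SVD cutoff silently truncates the
    molecules-scale transcription columns); the pseudo-inverse of the
    equilibrated system is applied with the configurable ``rcond`` cutoff.
    Minimum-norm pseudo-inversion resolves the underdetermined split
    between the HL and HH assembly routes; tiny negative components
    (numerical) are clipped to zero.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    estimates, residuals, conds, blocks = {}, {}, {}, []
    for data in datasets:
        A, b = _design_matrix(data, censored_q=censored_q)
        if not np.any(A):
            raise ValueError(f"{data.name}: all-zero design matrix")
        scale = np.linalg.norm(A, axis=0)
        scale[scale == 0] = 1.0
        theta = np.linalg.pinv(A / scale, rcond=rcond) @ b / scale
        resid = float(np.linalg.norm(A @ theta - b)
                      / (np.linalg.norm(b) or 1.0))
        theta = np.where(theta < 0, 0.0, theta)
        kw = dict(zip(UNKNOWNS, theta))
        kw.update(mu=data.mu, K2=data.decay("H_RNA_decay"),
                  K4=data.decay("L_RNA_decay"))
        estimates[data.name] = RateConstantSet(**kw)
        residuals[data.name] = resid
        conds[data.name] = conditioning_of(A)
        blocks.append(A)
    stacked = conditioning_of(block_diag(*blocks))
    return CombinedFitResult(estimates, residuals, conds, stacked)
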