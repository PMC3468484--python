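"""Control-engineering analysis of the assembly network.

The nonlinear mass-action model is linearised at its steady-state operating
point, giving a state matrix A (the analytic Jacobian: the bilinear assembly
terms contribute their partial derivatives at the operating point) and an
output map C built from the first-order export constants (each secretion
rate is q_s = kexp_s * [s], so its output row is kexp_s on that species).

Two distinct observability questions are answered:

``observability(model, measured_subset)``
    the classical Kalman sensor question: given sensors on a subset of
    states, what is the rank of [C; CA; ...; CA^(n-1)], and does the qmAb
    output direction lie in its row space (i.e. can qmAb be reconstructed
    from those sensors)?

``minimal_observable_set(model)``
    which initial-state coordinates does the output trajectory actually
    depend on?  A subset S determines the output iff every column of the
    observability matrix outside S is zero, so the unique minimal set is the
    support of the nonzero columns.  For the 13-state models with the
    secretion-rate output block this support is exactly the nine
    intracellular species: the cumulative extracellular pools never feed
    back, so qmAb is predictable from intracellular measurements alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .network import (
    EXPORT_MAP,
    RateConstantSet,
    Topology,
    as_topology,
    dxdt,
    jacobian,
    simulate,
)
from .inference import Q_OF_SPECIES, ConditioningReport, conditioning_of

__all__ = [
    "LinearStateModel",
    "ObservabilityReport",
    "linearise",
    "observability_matrix",
    "observability",
    "minimal_observable_set",
    "step_response_compare",
    "conditioning",
]

#: default rank tolerance multiplier (the paper-scale conditioning makes
#: rank decisions tolerance-sensitive, so this is deliberately exposed)
RANK_TOL_FACTOR = 1e3


@dataclass
class LinearStateModel:
    """x' = A (x - x_op); y = C (x - x_op) + y_op."""

    A: np.ndarray
    C: np.ndarray
    operating_point: np.ndarray
    species: tuple[str, ...]
    outputs: tuple[str, ...]
    topology: Topology
    rates: RateConstantSet

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def output_row(self, name: str) -> np.ndarray:
        return self.C[self.outputs.index(name)]


def _output_map(rates: RateConstantSet, topology: Topology,
                output: str) -> tuple[np.ndarray, tuple[str, ...]]:
    idx = topology.index()
    rows, names = [], []
    wanted = (Q_OF_SPECIES.values() if output == "secretion"
              else [output if output.startswith("q") else "qmAb"])
    for sp, (_, kname) in EXPORT_MAP.items():
        qname = Q_OF_SPECIES[sp]
        if qname in wanted:
            row = np.zeros(topology.n_states)
            row[idx[sp]] = rates.get(kname)
            rows.append(row)
            names.append(qname)
    return np.vstack(rows), tuple(names)


def linearise(rates: RateConstantSet, topology: Topology | str,
              operating_point, *, output: str = "secretion",
              residual_warn: float = 1e-6) -> LinearStateModel:
    """Linearise the network at (ideally) a fixed point.

    ``output`` is ``"secretion"`` (all four q's; the model's measurable
    outputs) or a single rate name such as ``"qmAb"``.  A warning residual
    is computed but non-fatal: any state is linearisable.
    """
    topology = as_topology(topology)
    x_op = np.asarray(operating_point, dtype=float)
    r = rates.for_topology(topology)
    n_intra = len(topology.intracellular)
    res = np.max(np.abs(dxdt(np.maximum(x_op, 0), r, topology)[:n_intra])
                 / (np.abs(x_op[:n_intra]) + 1.0))
    if res > residual_warn:
        import warnings
        warnings.warn(f"operating point is not a fixed point "
                      f"(residual {res:.2g}); linearisation proceeds",
                      stacklevel=2)
    A = jacobian(x_op, r, topology)
    C, names = _output_map(r, topology, output)
    return LinearStateModel(A, C, x_op, topology.species, names, topology, r)


def observability_matrix(A: np.ndarray, C: np.ndarray,
                         normalise: bool = True) -> np.ndarray:
    """Kalman observability matrix [C; CA; ...; CA^(n-1)].

    Rows are normalised to unit infinity-norm by default so that the rank
    and column-support tests are insensitive to the h^-1-scale spread of
    the rate constants.
    """
    n = A.shape[0]
    blocks, row = [], np.atleast_2d(C).astype(float)
    for _ in range(n):
        blocks.append(row)
        row = row @ A
    O = np.vstack(blocks)
    if normalise:
        norms = np.max(np.abs(O), axis=1, keepdims=True)
        O = np.where(norms > 0, O / np.where(norms == 0, 1.0, norms), O)
    return O


def _rank(M: np.ndarray, tol_factor: float = RANK_TOL_FACTOR) -> int:
    if not np.any(M):
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    tol = s[0] * max(M.shape) * np.finfo(float).eps * tol_factor
    return int(np.sum(s > tol))


def observability(model: LinearStateModel,
                  measured_subset: Iterable[str], *,
                  tol_factor: float = RANK_TOL_FACTOR,
                  target: str = "qmAb") -> tuple[int, bool]:
    """Rank test for a sensor set; can the target output be reconstructed?

    ``measured_subset`` names the directly measured states (C is the
    corresponding selector).  Returns (rank of the observability matrix,
    whether the target output's state direction lies in its row space).
    """
    subset = list(measured_subset)
    if not subset:
        raise ValueError("measured subset must be non-empty")
    idx = {s: i for i, s in enumerate(model.species)}
    C = np.zeros((len(subset), model.n))
    for r, sp in enumerate(subset):
        C[r, idx[sp]] = 1.0
    O = observability_matrix(model.A, C)
    rank = _rank(O, tol_factor)
    c_t = _output_map(model.rates, model.topology, target)[0][0]
    norm = np.max(np.abs(c_t))
    if norm == 0:
        return rank, False
    reconstructible = _rank(np.vstack([O, c_t / norm]), tol_factor) == rank
    return rank, reconstructible


@dataclass
class ObservabilityReport:
    rank: int
    minimal_count: int
    minimal_sets: list[tuple[str, ...]]
    column_tolerance: float
    outputs: tuple[str, ...]
    all_intracellular: bool = False


def minimal_observable_set(model: LinearStateModel, *,
                           column_tol: float = 1e-10,
                           tol_factor: float = RANK_TOL_FACTOR,
                           ) -> ObservabilityReport:
    """Smallest state subsets whose initial values determine the output.

    Exhaustive search over subsets, smallest first, lexicographic in the
    state ordering; a subset passes iff every observability-matrix column
    outside it is numerically zero (relative to the largest entry).  All
    minimal subsets found at the first passing size are reported.
    """
    if model.n > 20:
        raise ValueError("exhaustive subset search is limited to n <= 20")
    O = observability_matrix(model.A, model.C)
    col_mag = np.max(np.abs(O), axis=0)
    scale = np.max(col_mag) or 1.0
    tol = column_tol * scale

    def determines(subset: tuple[int, ...]) -> bool:
        mask = np.ones(model.n, dtype=bool)
        mask[list(subset)] = False
        return bool(np.all(col_mag[mask] <= tol))

    minimal: list[tuple[str, ...]] = []
    for k in range(1, model.n + 1):
        for subset in combinations(range(model.n), k):
            if determines(subset):
                minimal.append(tuple(model.species[i] for i in subset))
        if minimal:
            break
    intra = set(model.topology.intracellular)
    all_intra = all(set(s) <= intra for s in minimal)
    return ObservabilityReport(
        rank=_rank(O, tol_factor),
        minimal_count=len(minimal[0]) if minimal else 0,
        minimal_sets=minimal,
        column_tolerance=tol,
        outputs=model.outputs,
        all_intracellular=all_intra,
    )


def step_response_compare(rates: RateConstantSet, topology: Topology | str,
                          operating_point, *, parameter: str = "K1",
                          step: float = 0.01, horizon: float = 100.0,
                          n_eval: int = 101,
                          method: str = "LSODA") -> dict[str, float]:
    """Max relative divergence between nonlinear and linearised responses.

    A fractional ``step`` is applied to one rate constant at t = 0; both the
    nonlinear model and its linearisation at the operating point are
    integrated over ``horizon`` hours and compared per species (relative to
    the nonlinear trajectory, with a 1-molecule floor).
    """
    topology = as_topology(topology)
    if step <= -1:
        raise ValueError("step must exceed -1 (a -100% step zeroes the rate)")
    r0 = rates.for_topology(topology)
    x_op = np.asarray(operating_point, dtype=float)
    r1 = r0.scaled(**{parameter: 1.0 + step})
    t_eval = np.linspace(0.0, horizon, n_eval)

    nonlin = simulate(r1, topology, x_op, horizon, method=method,
                      rtol=1e-10, atol=1e-6, t_eval=t_eval)
    A = jacobian(x_op, r0, topology)
    drift = dxdt(x_op, r1, topology)  # constant forcing under new rates

    def rhs(t, y):
        return A @ (y - x_op) + drift

    from scipy.integrate import solve_ivp
    sol = solve_ivp(rhs, (0.0, horizon), x_op, method="LSODA",
                    jac=lambda t, y: A, rtol=1e-10, atol=1e-6, t_eval=t_eval)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError("linear response diverged (non-finite values)")
    if not np.all(np.isfinite(nonlin.y)):
        raise RuntimeError("nonlinear response diverged (non-finite values)")
    div = {}
    for i, sp in enumerate(topology.species):
        ref = np.abs(nonlin.y[i]) + 1.0
        div[sp] = float(np.max(np.abs(sol.y[i] - nonlin.y[i]) / ref))
    return div


def conditioning(matrix_or_model, rtol: float | None = None
                 ) -> ConditioningReport:
    """Condition number (sigma_max/sigma_min) of a matrix or state model."""
    if isinstance(matrix_or_model, LinearStateModel):
        return conditioning_of(matrix_or_model.A, rtol)
    return conditioning_of(matrix_or_model, rtol)
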