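"""Flux maps, parameter clustering and in-silico perturbation scans.

These analyses interrogate the fitted per-line models: which branches carry
the mass (flux maps), which parameters co-vary with productivity across cell
lines (Spearman hierarchical clustering), and what happens to the four
secretion rates when heavy- or light-chain production is scaled
(perturbation scans).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

from .inference import (
    ABUNDANCE_KEYS,
    Censor,
    CellLineDataset,
    FluxMap,
    InferenceResult,
    Q_KEYS,
)
from .network import (
    RateConstantSet,
    SteadyStateError,
    Topology,
    as_topology,
    secretion_rates,
    steady_state,
)

__all__ = [
    "normalised_fluxes",
    "export_partition",
    "ExportPartition",
    "parameter_matrix",
    "cluster_parameters",
    "ClusterResult",
    "perturb_scan",
    "PerturbationScan",
    "fluxmap_to_dot",
]


def normalised_fluxes(fluxmap: FluxMap) -> FluxMap:
    """Fluxes scaled to [0, 1] by the largest single reaction flux."""
    peak = max(fluxmap.fluxes.values())
    if peak <= 0:
        raise ValueError(f"{fluxmap.line}: all fluxes are zero; "
                         "nothing to normalise")
    return FluxMap(fluxmap.topology,
                   {k: v / peak for k, v in fluxmap.fluxes.items()},
                   line=fluxmap.line)


@dataclass
class ExportPartition:
    """Productive (qmAb) vs non-productive (qL + qLL + qHL) export split."""

    fractions: dict[str, float]          # line -> productive fraction
    productive: dict[str, float]
    non_productive: dict[str, float]
    cv_fraction: float                   # cross-line CV of the fraction
    cv_qmab: float                       # cross-line CV of absolute qmAb


def _cv(values: Sequence[float]) -> float:
    a = np.asarray(values, dtype=float)
    if a.size < 2:
        return 0.0
    return float(np.std(a, ddof=1) / np.mean(a))


def export_partition(fluxmaps: Sequence[FluxMap]) -> ExportPartition:
    """Partition each line's total export into productive and by-product.

    The paper-level observation this quantifies: the productive fraction is
    far more stable across lines than absolute productivity, consistent with
    a common non-selective export mechanism.
    """
    if not fluxmaps:
        raise ValueError("at least one flux map is required")
    fractions, productive, nonprod = {}, {}, {}
    for fm in fluxmaps:
        p = fm["export_LHHL"]
        np_ = fm["export_L"] + fm["export_LL"] + fm["export_HL"]
        total = p + np_
        if total <= 0:
            raise ValueError(f"{fm.line}: zero total export")
        fractions[fm.line] = p / total
        productive[fm.line] = p
        nonprod[fm.line] = np_
    return ExportPartition(fractions, productive, nonprod,
                           cv_fraction=_cv(list(fractions.values())),
                           cv_qmab=_cv(list(productive.values())))


RATE_ROWS = ("K1", "K2", "K3", "K4", "K5", "K7", "K8", "K10", "K16", "K19",
             "K21", "K22", "kexp_mab", "kexp_hl", "kexp_ll", "kexp_l")


def parameter_matrix(results: Sequence[InferenceResult]) -> pd.DataFrame:
    """Cell-line parameter matrix: rows = parameters, columns = lines.

    Rows combine the measured steady-state abundances and q-values (censored
    entries as 0, mirroring "not detected") with the inferred rate and
    export constants on their native scales.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 cell lines for any correlation")
    cols = {}
    for res in results:
        data = res.dataset
        assert data is not None
        col: dict[str, float] = {}
        for key in ABUNDANCE_KEYS + Q_KEYS:
            if data.flag(key) is Censor.MEASURED:
                col[key] = data.values[key]
            elif data.flag(key) is not Censor.MISSING:
                col[key] = 0.0
        for k in RATE_ROWS:
            v = res.rates.get(k)
            if v or any(r.rates.get(k) for r in results):
                col[k] = v
        cols[res.line] = col
    return pd.DataFrame(cols)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    flat: dict[str, int]                   # parameter -> flat cluster id
    distance: pd.DataFrame                 # 1 - spearman rho
    cophenetic: pd.DataFrame
    cut: float
    dropped: list[str] = field(default_factory=list)
    significance: dict[int, float] = field(default_factory=dict)

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.labels[node.id]
            return (f"({walk(node.left)},{walk(node.right)})"
                    f":{node.dist:.6g}")

        return walk(tree) + ";"

    def cluster_of(self, name: str) -> int:
        return self.flat[name]


def cluster_parameters(pm: pd.DataFrame, *, cut: float = 0.5,
                       n_permutations: int = 999,
                       seed: int = 0) -> ClusterResult:
    """Hierarchical clustering of parameters by Spearman rank correlation.

    Distance = 1 - Spearman rho across cell lines; average linkage;
    deterministic (rows sorted alphabetically before linkage, ranks with
    average tie-breaking).  Constant rows have undefined rho and are dropped
    with a warning.  Cluster 'significance' is reported as an empirical
    permutation p-value of each flat cluster's mean within-cluster distance
    under row-wise rank shuffles (an interpretation: the original analysis
    marks significant clusters without naming a test).
    """
    if pm.shape[0] < 3:
        raise ValueError("need >= 3 parameters to cluster")
    if pm.shape[1] < 3:
        warnings.warn("fewer than 3 cell lines: rank correlations are "
                      "nearly degenerate", stacklevel=2)
    pm = pm.sort_index()
    constant = pm.index[(pm.nunique(axis=1) <= 1)].tolist()
    if constant:
        warnings.warn(f"dropping constant-valued rows {constant} "
                      "(Spearman rho undefined)", stacklevel=2)
        pm = pm.drop(index=constant)
    ranks = pm.rank(axis=1, method="average")
    rho = ranks.T.corr(method="pearson")  # pearson of ranks == spearman
    dist = 1.0 - rho
    labels = list(pm.index)
    condensed = dist.values[np.triu_indices(len(labels), k=1)]
    condensed = np.clip(condensed, 0.0, None)
    Z = hierarchy.linkage(condensed, method="average")
    flat_ids = hierarchy.fcluster(Z, t=cut, criterion="distance")
    flat = dict(zip(labels, (int(i) for i in flat_ids)))
    coph = hierarchy.cophenet(Z)
    coph_df = pd.DataFrame(np.zeros((len(labels), len(labels))),
                           index=labels, columns=labels)
    iu = np.triu_indices(len(labels), k=1)
    coph_df.values[iu] = coph
    coph_df.values[(iu[1], iu[0])] = coph

    significance = _cluster_significance(ranks, flat, n_permutations, seed)
    return ClusterResult(Z, labels, flat, dist, coph_df, cut,
                         dropped=constant, significance=significance)


def _cluster_significance(ranks: pd.DataFrame, flat: Mapping[str, int],
                          n_perm: int, seed: int) -> dict[int, float]:
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    r = ranks.values

    def mean_within(mat: np.ndarray, members: np.ndarray) -> float:
        sub = mat[members]
        rho = np.corrcoef(sub)
        iu = np.triu_indices(len(members), k=1)
        return float(np.mean(1.0 - rho[iu]))

    labels = list(ranks.index)
    for cid in sorted(set(flat.values())):
        members = np.array([i for i, name in enumerate(labels)
                            if flat[name] == cid])
        if len(members) < 2:
            out[cid] = 1.0
            continue
        obs = mean_within(r, members)
        hits = 0
        for _ in range(n_perm):
            perm = r.copy()
            for row in perm:
                rng.shuffle(row)
            if mean_within(perm, members) <= obs:
                hits += 1
        out[cid] = (hits + 1) / (n_perm + 1)
    return out


@dataclass
class PerturbationScan:
    target: str
    multipliers: np.ndarray
    q: pd.DataFrame              # columns qmAb/qHL/qLL/qL, index multipliers
    converged: np.ndarray
    line: str = ""

    def series(self, qname: str) -> np.ndarray:
        return self.q[qname].values


def perturb_scan(rates: RateConstantSet, topology: Topology | str,
                 target: str = "K5",
                 multipliers: Sequence[float] | None = None, *,
                 line: str = "") -> PerturbationScan:
    """Scan a production constant and record the four secretion rates.

    ``target`` is one of K5/K8 (translation) or K1/K3 (transcription).  At
    steady state a K1 scan is equivalent to a K5 scan (only the product
    K1*K5 enters the protein-level balances), which is asserted as a
    property in the test-suite.
    """
    topology = as_topology(topology)
    if target not in ("K1", "K3", "K5", "K8"):
        raise ValueError(f"scan target must be K1/K3/K5/K8, got {target!r}")
    if multipliers is None:
        multipliers = np.geomspace(0.1, 10.0, 21)
    multipliers = np.asarray(multipliers, dtype=float)
    if np.any(multipliers <= 0):
        raise ValueError("multipliers must be positive")
    rows, ok = [], []
    x_prev = None
    for m in multipliers:
        r = rates.scaled(**{target: m})
        try:
            x = steady_state(r, topology, x0=x_prev)
            x_prev = x
            rows.append(secretion_rates(r, x, topology))
            ok.append(True)
        except SteadyStateError:
            rows.append({k: np.nan for k in ("qmAb", "qHL", "qLL", "qL")})
            ok.append(False)
    q = pd.DataFrame(rows, index=multipliers)
    return PerturbationScan(target, multipliers, q, np.asarray(ok), line)


def plot_scan(scan: PerturbationScan, ax=None):
    """Functional matplotlib plot of a perturbation scan (q's vs multiplier,
    both axes logarithmic, normalised to the unperturbed baseline)."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(4.5, 3.5))
    i1 = int(np.argmin(np.abs(scan.multipliers - 1.0)))
    for qname in scan.q.columns:
        base = scan.q[qname].iloc[i1]
        if base > 0:
            ax.loglog(scan.multipliers, scan.q[qname] / base, label=qname)
    ax.axvline(1.0, color="0.7", lw=0.8)
    ax.set_xlabel(f"{scan.target} multiplier")
    ax.set_ylabel("secretion rate (fold baseline)")
    ax.set_title(scan.line or scan.target)
    ax.legend(fontsize=8)
    return ax


def fluxmap_to_dot(fluxmap: FluxMap, *, normalised: bool = True) -> str:
    """Graphviz DOT rendering of a flux map (edge labels = fluxes)."""
    fm = normalised_fluxes(fluxmap) if normalised else fluxmap
    from .network import build_network
    lines = [f'digraph "{fm.line or fm.topology.value}" {{',
             "  rankdir=LR;"]
    for rxn in build_network(fm.topology):
        if rxn.kind == "dilution":
            continue
        v = fm[rxn.name]
        srcs = list(rxn.reactants) or ["source"]
        dsts = list(rxn.products) or ["sink"]
        for s in srcs:
            for d in dsts:
                lines.append(f'  "{s}" -> "{d}" [label="{v:.3g}"];')
    lines.append("}")
    return "\n".join(lines)
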