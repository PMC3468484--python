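"""Synthetic cell lines and cultures with the statistical structure of the
measured panels.

A virtual cell line is a ground-truth rate-constant set; its "measurement"
is the exact model steady state (plus exact secretion rates) corrupted by
multiplicative log-normal noise and left-censored at the western-blot
detection limit of 1e5 molecules/cell.  Log-normal noise reflects the
multiplicative error structure of quantitative western blotting and qRT-PCR.

Default sampling ranges bracket the constants observed across the four
measured NS0 lines (and, for the HH-route constants, the wider ranges
reported for CHO cells), so a default draw is a plausible NS0-like producer.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .culture import GrowthTimeSeries
from .inference import (
    ABUNDANCE_KEYS,
    Censor,
    CellLineDataset,
    DETECTION_LIMIT,
    Q_KEYS,
    Q_OF_SPECIES,
)
from .network import (
    RateConstantSet,
    Topology,
    as_topology,
    secretion_rates,
    steady_state,
)

__all__ = ["SyntheticTruth", "DEFAULT_RANGES", "DEFAULT_NOISE_CV",
           "sample_rates", "generate_panel", "generate_culture"]

#: log-uniform sampling ranges per constant (units as in RateConstantSet)
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "mu": (0.018, 0.036),
    "K1": (5.0, 110.0),
    "K2": (0.01, 0.4),
    "K3": (28.0, 5500.0),
    "K4": (0.01, 0.11),
    "K5": (2e3, 4e4),
    "K8": (1.7e2, 2.2e3),
    "K7": (8e-8, 1.5e-5),
    "K10": (1e-7, 8.5e-6),
    "K16": (2e-10, 3e-9),
    "K19": (2.6e-8, 6.1e-5),
    "K21": (0.001, 6.5),
    "K22": (0.001, 6.5),
    "kexp_mab": (0.04, 0.25),
    "kexp_hl": (0.01, 0.1),
    "kexp_ll": (0.1, 10.0),
    "kexp_l": (0.07, 22.0),
}

#: default measurement noise (coefficient of variation) per quantity class
DEFAULT_NOISE_CV = {"protein": 0.20, "mrna": 0.25, "q": 0.15}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one virtual cell line."""

    rates: RateConstantSet
    topology: Topology
    seed: int
    noise_cv: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_CV))
    detection_limit: float = DETECTION_LIMIT
    name: str = "synthetic"
    #: censor on the noiseless value (the limit is an assay property); set
    #: False to censor on the noisy value instead
    censor_on_true: bool = True

    def __post_init__(self):
        if any(cv < 0 for cv in self.noise_cv.values()):
            raise ValueError("noise CV must be >= 0")

    def to_manifest(self) -> str:
        return json.dumps({
            "name": self.name,
            "topology": self.topology.value,
            "seed": self.seed,
            "noise_cv": self.noise_cv,
            "detection_limit": self.detection_limit,
            "censor_on_true": self.censor_on_true,
            "rates": self.rates.to_dict(),
        }, indent=2)


def _line_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-line substream via stable hashing of the name."""
    sub = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def sample_rates(seed: int, topology: Topology | str,
                 ranges: dict[str, tuple[float, float]] | None = None,
                 ) -> RateConstantSet:
    """Draw a rate-constant set log-uniformly within per-constant ranges."""
    topology = as_topology(topology)
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    rng = np.random.default_rng(seed)
    kw = {}
    for name in sorted(ranges):
        lo, hi = ranges[name]
        if not (0 < lo <= hi):
            raise ValueError(f"range for {name} must be positive and "
                             f"non-empty, got ({lo}, {hi})")
        kw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    rates = RateConstantSet(**kw).for_topology(topology)
    if topology is not Topology.HL:
        # keep the light-chain additions tied, as in the fitted models
        rates = replace(rates, K22=rates.K21)
    return rates


_CLASS = {**{k: "protein" for k in ABUNDANCE_KEYS},
          "H_RNA": "mrna", "L_RNA": "mrna",
          **{k: "q" for k in Q_KEYS}}


def generate_panel(truth: SyntheticTruth) -> CellLineDataset:
    """Measure a virtual line: steady state + noise + left-censoring.

    The censoring decision is made on the noiseless value by default (the
    detection limit is a property of the assay, the noise of the individual
    measurement); censored entries carry the limit itself.
    """
    topology = truth.topology
    rates = truth.rates.for_topology(topology)
    x = steady_state(rates, topology)
    idx = topology.index()
    q = secretion_rates(rates, x, topology)
    rng = _line_rng(truth.seed, truth.name)

    values: dict[str, float] = {}
    flags: dict[str, Censor] = {}

    def _noisy(v: float, cv: float) -> float:
        if cv <= 0 or v == 0:
            return v
        sigma = np.sqrt(np.log1p(cv * cv))
        return float(v * rng.lognormal(-sigma * sigma / 2.0, sigma))

    for sp in ABUNDANCE_KEYS:
        true = x[idx[sp]] if sp in idx else 0.0
        cv = truth.noise_cv.get(_CLASS[sp], 0.0)
        noisy = _noisy(true, cv)
        basis = true if truth.censor_on_true else noisy
        if sp in ("H_RNA", "L_RNA"):
            values[sp] = noisy       # qRT-PCR: no western detection limit
        elif basis < truth.detection_limit:
            values[sp] = truth.detection_limit
            flags[sp] = Censor.BELOW_LIMIT
        else:
            values[sp] = noisy
    for qname in Q_KEYS:
        true = q[qname]
        noisy = _noisy(true, truth.noise_cv.get("q", 0.0))
        basis = true if truth.censor_on_true else noisy
        if basis < truth.detection_limit:
            values[qname] = truth.detection_limit
            flags[qname] = Censor.BELOW_LIMIT
        else:
            values[qname] = noisy
    values["H_RNA_decay"] = rates.K2
    values["L_RNA_decay"] = rates.K4
    return CellLineDataset(truth.name, rates.mu, values, flags,
                           detection_limit=truth.detection_limit)


def generate_culture(truth: SyntheticTruth, mu: float | None = None,
                     duration: float = 96.0, sampling: float = 24.0,
                     v0: float = 2e5, capacity: float | None = None,
                     ) -> GrowthTimeSeries:
    """Simulate a batch culture of a virtual line at per-cell steady state.

    VCC grows exponentially at mu (optionally logistically capped at
    ``capacity``); each cumulative product pool accumulates as the integral
    of q * VCC, evaluated in closed form on the sampling grid.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rates = truth.rates.for_topology(truth.topology)
    mu = rates.mu if mu is None else mu
    x = steady_state(rates, truth.topology)
    q = secretion_rates(rates, x, truth.topology)
    t = np.arange(0.0, duration + 0.5 * sampling, sampling)
    if capacity is None:
        vcc = v0 * np.exp(mu * t)
        integral = (vcc - v0) / mu if mu > 0 else v0 * t
    else:
        a = capacity / v0 - 1.0
        vcc = capacity / (1.0 + a * np.exp(-mu * t))
        integral = (capacity / mu) * np.log((1.0 + a * np.exp(-mu * t))
                                            * np.exp(mu * t) / (1.0 + a))
    products = {Q_OF_SPECIES[sp]: qv * integral
                for sp, qv in zip(("L", "LL", "LHHL", "HL"),
                                  (q["qL"], q["qLL"], q["qmAb"], q["qHL"]))}
    # product pools keyed by their q-name for direct comparison with qp()
    return GrowthTimeSeries(t, vcc, products)
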