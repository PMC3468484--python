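"""Culture-level measurement processing: IVC, cell-specific productivity,
and first-order mRNA decay fits.

Cell-specific productivity q_P for a secreted species is the cumulative
product increment divided by the time integral of viable cells (IVC):

    q_P = (P(t2) - P(t1)) / IVC(t1, t2),
    IVC(t1, t2) = integral of VCC(t) dt  (trapezoidal on the sampled curve),

with product in molecules/mL and VCC in cells/mL, so q_P comes out in
molecules per cell per hour.  mRNA half-lives come from an ordinary
least-squares fit of log(relative level) against time after transcription
arrest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrowthTimeSeries", "DecaySeries", "ivc", "qp", "decay_fit",
           "DecayFit"]


@dataclass
class GrowthTimeSeries:
    """Sampled batch-culture curve.

    t            hours, strictly increasing
    vcc          viable cell concentration, cells/mL
    products     per-species cumulative concentration, molecules/mL
    """

    t: np.ndarray
    vcc: np.ndarray
    products: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.vcc = np.asarray(self.vcc, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("need at least two timepoints")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.vcc.shape != self.t.shape or np.any(self.vcc < 0):
            raise ValueError("VCC must be non-negative and match timepoints")
        self.products = {k: np.asarray(v, dtype=float)
                         for k, v in self.products.items()}
        for k, v in self.products.items():
            if v.shape != self.t.shape or np.any(v < 0):
                raise ValueError(f"product series {k} must be non-negative "
                                 "and match timepoints")

    def _interp(self, y: np.ndarray, t: float) -> float:
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t = {t:g} h outside the sampled range "
                             f"[{self.t[0]:g}, {self.t[-1]:g}]")
        return float(np.interp(t, self.t, y))


@dataclass
class DecaySeries:
    """Relative mRNA level after transcription arrest (level(0) = 1)."""

    t: np.ndarray
    level: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.level = np.asarray(self.level, dtype=float)
        if self.t.size != self.level.size or self.t.size < 3:
            raise ValueError("need >= 3 matching timepoints")
        if np.any(self.level <= 0):
            raise ValueError("relative levels must be positive for a "
                             "log-linear fit")
        if self.level[0] != 0 and abs(self.level[0] - 1.0) > 1e-9:
            self.level = self.level / self.level[0]


def ivc(series: GrowthTimeSeries, t1: float, t2: float) -> float:
    """Time integral of viable cells over [t1, t2], cell*h/mL.

    Trapezoidal: each interval contributes its average VCC times its width;
    endpoints inside an interval are handled by linear interpolation, which
    is exactly consistent with the trapezoid rule.
    """
    if t1 >= t2:
        raise ValueError("t1 must be < t2")
    v1, v2 = series._interp(series.vcc, t1), series._interp(series.vcc, t2)
    inner = (series.t > t1) & (series.t < t2)
    t = np.concatenate([[t1], series.t[inner], [t2]])
    v = np.concatenate([[v1], series.vcc[inner], [v2]])
    return float(np.trapezoid(v, t))


def qp(series: GrowthTimeSeries, species: str, t1: float = 0.0,
       t2: float = 96.0) -> float:
    """Cell-specific productivity, molecules/cell/h, over [t1, t2].

    The default window matches a day-0-to-day-4 sampling of the
    constant-productivity exponential phase.
    """
    if species not in series.products:
        raise KeyError(f"no product series named {species!r}")
    denom = ivc(series, t1, t2)
    if denom <= 0:
        raise ValueError("IVC over the window is zero; q_P undefined")
    p = series.products[species]
    dp = series._interp(p, t2) - series._interp(p, t1)
    return dp / denom


@dataclass
class DecayFit:
    k: float          # first-order decay constant, 1/h
    half_life: float  # ln 2 / k, hours (inf for a non-decaying series)
    r_squared: float


def decay_fit(series: DecaySeries) -> DecayFit:
    """OLS fit of log(level) vs time; only decay (k >= 0) is reported.

    A non-decaying series (non-negative fitted slope) yields k = 0 with a
    warning and an infinite half-life.
    """
    y = np.log(series.level)
    slope, intercept = np.polyfit(series.t, y, 1)
    fitted = slope * series.t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0:
        if slope > 0:
            warnings.warn("series does not decay (positive fitted slope); "
                          "reporting k = 0", stacklevel=2)
        return DecayFit(0.0, np.inf, r2)
    k = -float(slope)
    return DecayFit(k, float(np.log(2.0) / k), r2)
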