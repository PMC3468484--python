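"""Readers and writers for cell-line panels, rate tables and reports.

The canonical panel dialect is a TSV with one row per quantity and one
column per cell line::

    quantity  unit            2N2      2P      ...
    mu        1/h             0.020    0.025
    H         molecules/cell  4.7x10^6 2.5x10^6
    HH        molecules/cell  <0.1x10^6 ...

Scientific notation is accepted in the "a x 10^b" (also with a literal
multiplication sign) and "aEb" forms.  Censoring is encoded in the value
itself: ``<x`` (below the limit x), ``>x`` (above x), ``n.m.`` / ``n.d.`` /
empty (missing).  The packaged fixtures ``table1.tsv`` (four training lines)
and ``table3.tsv`` (the naive 2X line) use this dialect.
"""

from __future__ import annotations

import csv
import json
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .inference import (
    ABUNDANCE_KEYS,
    Censor,
    CellLineDataset,
    DECAY_KEYS,
    DETECTION_LIMIT,
    InferenceResult,
    Q_KEYS,
)

__all__ = ["parse_value", "read_panel", "write_panel", "load_table1",
           "load_table3", "write_rate_table", "PanelFormatError"]

_NUM = re.compile(
    r"^\s*(?P<mant>[0-9]*\.?[0-9]+)\s*(?:[x×]\s*10\^?(?P<exp>[+-]?[0-9]+)"
    r"|[eE](?P<exp2>[+-]?[0-9]+))?\s*$")

MISSING_TOKENS = {"", "n.m.", "n.m", "nm", "n.d.", "na", "n/a", "-"}


class PanelFormatError(ValueError):
    pass


def parse_value(token: str) -> tuple[float | None, Censor]:
    """Parse one panel cell into (value, censoring flag)."""
    s = token.strip()
    if s.lower() in MISSING_TOKENS:
        return None, Censor.MISSING
    flag = Censor.MEASURED
    if s.startswith("<"):
        flag, s = Censor.BELOW_LIMIT, s[1:]
    elif s.startswith(">"):
        flag, s = Censor.ABOVE_LIMIT, s[1:]
    m = _NUM.match(s)
    if not m:
        raise PanelFormatError(f"malformed numeric token {token!r}")
    v = float(m.group("mant"))
    exp = m.group("exp") or m.group("exp2")
    if exp is not None:
        v *= 10.0 ** int(exp)
    if v < 0:
        raise PanelFormatError(f"negative value {token!r}")
    return v, flag


KNOWN_QUANTITIES = ("mu",) + ABUNDANCE_KEYS + Q_KEYS + DECAY_KEYS


def read_panel(path, *, detection_limit: float = DETECTION_LIMIT
               ) -> list[CellLineDataset]:
    """Read a panel TSV into one dataset per cell-line column."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise PanelFormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if header[:2] != ["quantity", "unit"]:
        raise PanelFormatError(
            f"{path}: first columns must be 'quantity' and 'unit', "
            f"got {header[:2]}")
    lines = header[2:]
    if not lines:
        raise PanelFormatError(f"{path}: no cell-line columns")
    values = {name: {} for name in lines}
    flags = {name: {} for name in lines}
    for r, row in enumerate(rows[1:], start=2):
        if not row or not row[0].strip():
            continue
        qty = row[0].strip()
        if qty not in KNOWN_QUANTITIES:
            raise PanelFormatError(f"{path}:{r}: unknown quantity {qty!r}")
        for c, name in enumerate(lines, start=2):
            token = row[c] if c < len(row) else ""
            try:
                v, flag = parse_value(token)
            except PanelFormatError as e:
                raise PanelFormatError(f"{path}:{r} column {name}: {e}") from e
            if flag is Censor.MISSING:
                continue
            values[name][qty] = v
            if flag is not Censor.MEASURED:
                flags[name][qty] = flag
    out = []
    for name in lines:
        if "mu" not in values[name]:
            raise PanelFormatError(f"{path}: column {name} has no growth "
                                   "rate 'mu'")
        mu = values[name].pop("mu")
        out.append(CellLineDataset(name, mu, values[name], flags[name],
                                   detection_limit=detection_limit))
    return out


def _format_value(v: float | None, flag: Censor) -> str:
    if flag is Censor.MISSING or v is None:
        return "n.m."
    prefix = {Censor.BELOW_LIMIT: "<", Censor.ABOVE_LIMIT: ">",
              Censor.MEASURED: ""}[flag]
    return f"{prefix}{v:.6g}"


_UNITS = {"mu": "1/h",
          **{k: "molecules/cell" for k in ABUNDANCE_KEYS},
          **{k: "molecules/cell/h" for k in Q_KEYS},
          **{k: "1/h" for k in DECAY_KEYS}}


def write_panel(path, datasets: Sequence[CellLineDataset]) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["quantity", "unit"] + [d.name for d in datasets])
        w.writerow(["mu", _UNITS["mu"]] + [f"{d.mu:.6g}" for d in datasets])
        for qty in ABUNDANCE_KEYS + Q_KEYS + DECAY_KEYS:
            row = [qty, _UNITS[qty]]
            for d in datasets:
                flag = d.flag(qty)
                row.append(_format_value(d.values.get(qty), flag))
            w.writerow(row)


def _fixture(name: str) -> Path:
    return Path(str(resources.files("mabflux").joinpath("data", name)))


def load_table1() -> list[CellLineDataset]:
    """The four training NS0 cell-line panels (2N2, 2P, 4O, 4R)."""
    return read_panel(_fixture("table1.tsv"))


def load_table3() -> CellLineDataset:
    """The naive 2X validation panel."""
    return read_panel(_fixture("table3.tsv"))[0]


RATE_TABLE_ROWS = ("mu", "K1", "K2", "K3", "K4", "K5", "K8", "K7", "K10",
                   "K16", "K19", "K21", "K22", "kexp_mab", "kexp_hl",
                   "kexp_ll", "kexp_l")


def write_rate_table(path, results: Sequence[InferenceResult]) -> None:
    """Rate-constant table TSV (rows = constants, columns = cell lines)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["constant"] + [r.line for r in results])
        for k in RATE_TABLE_ROWS:
            w.writerow([k] + [f"{r.rates.get(k):.6g}" for r in results])


def write_json(path, payload, *, config: dict | None = None) -> None:
    """Write a JSON report, embedding the resolved run configuration."""
    from . import __version__

    doc = {"mabflux_version": __version__}
    if config:
        doc["config"] = config
    doc.update(payload)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(doc, indent=2, default=_default))
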