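#!/usr/bin/env python
"""Steady-state flux maps and the productive/non-productive export split.

Computes the molecular flux through every reaction per cell line (absolute
and normalised to each line's largest flux) and partitions total export into
assembled antibody vs by-products.  The headline observation: the productive
fraction is far more stable across lines than absolute productivity,
consistent with a common non-selective export mechanism.

Writes: results/fluxes_hl.json, results/flux_graph_<line>.dot,
        results/export_partition.json
"""

import json
from pathlib import Path

from mabflux.inference import infer_fluxes
from mabflux.io import load_table1
from mabflux.pathway import export_partition, fluxmap_to_dot, normalised_fluxes

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    panels = load_table1()
    maps = {d.name: infer_fluxes(d, "HL") for d in panels}
    payload = {name: {"absolute": fm.fluxes,
                      "normalised": normalised_fluxes(fm).fluxes}
               for name, fm in maps.items()}
    (OUT / "fluxes_hl.json").write_text(json.dumps(payload, indent=2))
    for name, fm in maps.items():
        (OUT / f"flux_graph_{name}.dot").write_text(fluxmap_to_dot(fm))

    quantifiable = [maps[n] for n in ("2N2", "2P", "4O")]
    part = export_partition(quantifiable)
    (OUT / "export_partition.json").write_text(json.dumps({
        "productive_fraction": part.fractions,
        "cv_fraction": part.cv_fraction,
        "cv_qmab": part.cv_qmab,
    }, indent=2))
    print("productive export fraction per line:",
          {k: round(v, 3) for k, v in part.fractions.items()})
    print(f"cross-line CV of the fraction {part.cv_fraction:.2f} vs CV of "
          f"absolute qmAb {part.cv_qmab:.2f} -> export split is the stable "
          "quantity")


if __name__ == "__main__":
    main()
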