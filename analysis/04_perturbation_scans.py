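#!/usr/bin/env python
"""Where should one intervene to raise productivity?

Scans heavy- and light-chain translation constants (K5, K8) over 0.1-10x at
every line's fitted constants and follows the four secretion rates.  Raising
heavy-chain translation selectively raises qmAb; raising light-chain
translation mostly feeds the qL/qLL by-products.

Writes: results/scan_<line>_<target>.tsv, results/scan_summary.json
"""

import json
from pathlib import Path

import numpy as np

from mabflux.inference import infer_rate_constants
from mabflux.io import load_table1
from mabflux.pathway import perturb_scan, plot_scan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
FIG = Path(__file__).resolve().parents[1] / "scratch"
FIG.mkdir(exist_ok=True)


def main():
    panels = load_table1()
    summary = {}
    for data in panels:
        res = infer_rate_constants(data, "HL")
        line = {}
        for target in ("K5", "K8"):
            scan = perturb_scan(res.rates, "HL", target, line=data.name)
            scan.q.rename_axis("multiplier").to_csv(
                OUT / f"scan_{data.name}_{target}.tsv", sep="\t")
            ax = plot_scan(scan)
            ax.figure.savefig(FIG / f"scan_{data.name}_{target}.png",
                              dpi=120, bbox_inches="tight")
            q = scan.q
            i1 = int(np.argmin(np.abs(scan.multipliers - 1.0)))
            line[target] = {
                "qmAb_gain_at_2x": float(
                    q["qmAb"].iloc[np.searchsorted(scan.multipliers, 2.0)]
                    / q["qmAb"].iloc[i1]),
                "qLL_gain_at_2x": float(
                    q["qLL"].iloc[np.searchsorted(scan.multipliers, 2.0)]
                    / q["qLL"].iloc[i1]),
            }
        summary[data.name] = line
        print(f"{data.name}: 2x K5 -> qmAb x{line['K5']['qmAb_gain_at_2x']:.2f} "
              f"(qLL x{line['K5']['qLL_gain_at_2x']:.2f}); "
              f"2x K8 -> qmAb x{line['K8']['qmAb_gain_at_2x']:.2f} "
              f"(qLL x{line['K8']['qLL_gain_at_2x']:.2f})")
    (OUT / "scan_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
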