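#!/usr/bin/env python
"""Does the inference machinery recover known constants from noisy panels?

Generates 100 virtual cell lines (log-uniform constants bracketing the
measured panels), measures each with the synthetic assay (log-normal noise,
1e5 molecules/cell detection limit), re-infers the constants and compares
with truth.  Noiseless panels recover every identifiable constant to
machine precision; at 10% measurement CV the median error stays well under
the 25% design target.

Writes: results/parameter_recovery.json
"""

import argparse
import json
from pathlib import Path

import numpy as np

from mabflux.inference import infer_rate_constants
from mabflux.network import Topology
from mabflux.synth import SyntheticTruth, generate_panel, sample_rates

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

CHECK = ("K1", "K3", "K10", "kexp_mab", "kexp_hl", "kexp_ll", "kexp_l")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-lines", type=int, default=100)
    args = ap.parse_args()

    seeds = np.random.SeedSequence(args.seed).generate_state(
        args.n_lines) % (2**31)
    errs = {0.0: [], 0.10: [], 0.20: []}
    censored_share = []
    for s in seeds:
        rates = sample_rates(int(s), "HL")
        for cv in errs:
            truth = SyntheticTruth(
                rates, Topology.HL, int(s),
                noise_cv={"protein": cv, "mrna": cv, "q": cv},
                name=f"line{s}")
            panel = generate_panel(truth)
            res = infer_rate_constants(panel, "HL")
            if cv == 0.0:
                censored_share.append(len(panel.flags) / 13)
            for k in CHECK:
                if rates.get(k) > 0 and k not in res.censored_derived:
                    errs[cv].append(abs(res.rates.get(k) - rates.get(k))
                                    / rates.get(k))
    summary = {
        f"cv_{int(cv*100)}": {
            "median_rel_error": float(np.median(e)),
            "p90_rel_error": float(np.quantile(e, 0.9)),
            "n_constants": len(e),
        } for cv, e in errs.items()
    }
    summary["mean_censored_share"] = float(np.mean(censored_share))
    (OUT / "parameter_recovery.json").write_text(json.dumps(summary,
                                                            indent=2))
    for cv, e in errs.items():
        print(f"CV {cv:4.0%}: median rel error {np.median(e):.3g} "
              f"(90th pct {np.quantile(e, 0.9):.3g}, n = {len(e)})")


if __name__ == "__main__":
    main()
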