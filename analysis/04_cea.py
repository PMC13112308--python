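#!/usr/bin/env python
"""Incremental cost-effectiveness analysis with bootstrap uncertainty.

For each outcome (energy reduction per order, percentage-point increase in
'Everyday' items) and perspective (health service, societal), computes the
incremental cost per student, the incremental effect, the ICER, and 2000
seeded bootstrap replicates yielding percentile uncertainty intervals, the
cost-effectiveness plane and the acceptability curve.  Writes one JSON
block plus plane/CEAC CSVs per analysis, and results/icer_table.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from canteen_cea.cea import AnalysisInputs, CEASettings, EffectSpec, run_cea
from canteen_cea.costing import PERSPECTIVES
from canteen_cea.reporting import read_ledger_csv, read_orders_csv


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--bootstrap-iterations", "-B", type=int,
                        default=2000)
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    inputs = AnalysisInputs(
        orders=read_orders_csv(args.data_dir / "orders.csv"),
        cost_ledger=read_ledger_csv(args.data_dir / "cost_ledger.csv"))
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for outcome in ("energy_reduction_kj", "everyday_pp_increase"):
        for perspective in PERSPECTIVES:
            settings = CEASettings(
                spec=EffectSpec(outcome=outcome),
                perspective=perspective, B=args.bootstrap_iterations,
                seed=args.seed)
            res = run_cea(inputs, settings)
            key = f"{outcome}__{perspective}"
            (args.out_dir / f"cea_{key}.json").write_text(
                json.dumps(res.to_dict(), indent=2) + "\n")
            res.replicates.to_csv(args.out_dir / f"plane_{key}.csv",
                                  index=False)
            res.ceac.to_csv(args.out_dir / f"ceac_{key}.csv", index=False)
            unit = "kJ" if outcome.startswith("energy") else "pp"
            print(f"{outcome:<22} {perspective:<14} "
                  f"ΔC ${res.delta_cost:5.2f}/student, "
                  f"ΔE {res.delta_effect:6.2f} {unit}, "
                  f"ICER ${res.icer.value:.3f}/{unit} "
                  f"(UI ${res.ui_icer['lower']:.3f}-"
                  f"${res.ui_icer['upper']:.3f}); "
                  f"{res.quadrant_counts['NE']}/{res.B} replicates in the "
                  f"more-costly-more-effective quadrant")
            rows.append({"outcome": outcome, "perspective": perspective,
                         **{k: v for k, v in res.to_dict().items()
                            if k not in ("outcome", "perspective")}})
    pd.json_normalize(rows).to_csv(args.out_dir / "icer_table.csv",
                                   index=False)


if __name__ == "__main__":
    main()
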