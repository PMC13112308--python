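#!/usr/bin/env python
"""Value and aggregate the intervention's delivery costs.

Reads the cost ledger written by 01_simulate.py, values each activity at
minutes/60 x hourly rate x oncosts, and reports per-school totals by
category and bearer under both the health-service and societal
perspectives.  Writes results/cost_table.csv and results/cost_totals.json.
"""

import argparse
import json
from pathlib import Path

from canteen_cea.costing import PERSPECTIVES, summarise_costs
from canteen_cea.reporting import read_ledger_csv, render_tables


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    ledger = read_ledger_csv(args.data_dir / "cost_ledger.csv")
    cost_table, _ = render_tables(ledger, {})
    args.out_dir.mkdir(parents=True, exist_ok=True)
    cost_table.to_csv(args.out_dir / "cost_table.csv", index=False)

    payload = {}
    for perspective in PERSPECTIVES:
        s = summarise_costs(ledger, perspective)
        payload[perspective] = {
            "overall_total": s.overall_total,
            "mean_per_school": s.mean_per_school,
            "min_per_school": s.min_per_school,
            "max_per_school": s.max_per_school,
        }
        print(f"{perspective:>14}: total ${s.overall_total:,.2f}, "
              f"mean ${s.mean_per_school:,.2f}/school "
              f"(range ${s.min_per_school:,.2f}-${s.max_per_school:,.2f})")
    (args.out_dir / "cost_totals.json").write_text(
        json.dumps(payload, indent=2) + "\n")
    school_share = (payload["societal"]["mean_per_school"]
                    - payload["health_service"]["mean_per_school"])
    print(f"bearer split per school: "
          f"${payload['health_service']['mean_per_school']:,.2f} health "
          f"service + ${school_share:,.2f} school")


if __name__ == "__main__":
    main()
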