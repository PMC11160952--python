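#!/usr/bin/env python
"""Descriptive summaries of the quantified cohort.

Produces the two standard summary layouts: mean +/- SD of every metric per
stage and side, and median (Q1; Q3) of the per-patient asymmetry index and
absolute intereye difference per stage.  Writes both as CSVs under
results/tables/.
"""

from pathlib import Path

import pandas as pd

from octa_intereye import pair_eyes, summarize

ROOT = Path(__file__).resolve().parents[1]
METRICS = ROOT / "results" / "image_analysis" / "metrics.csv"
OUT = ROOT / "results" / "tables"

if __name__ == "__main__":
    if not METRICS.exists():
        raise SystemExit("run analysis/02_quantify_images.py first")
    metrics = pd.read_csv(METRICS, dtype={"patient_id": str})
    metrics = metrics[~metrics["metric"].str.startswith("qc_")]
    pairs, unpaired = pair_eyes(metrics)
    tables = summarize(metrics, pairs)

    OUT.mkdir(parents=True, exist_ok=True)
    tables["by_stage_side"].to_csv(OUT / "metrics_by_stage_side.csv",
                                   index=False, float_format="%.6f")
    tables["intereye_by_stage"].to_csv(OUT / "intereye_by_stage.csv",
                                       index=False, float_format="%.6f")

    vd = tables["by_stage_side"]
    vd = vd[vd["metric"] == "vd_scp_total"]
    print("SCP vessel density by stage and side (mean +/- sd):")
    for _, row in vd.iterrows():
        print(f"  {row['stage']:>9} {row['side']:>5}: "
              f"{row['mean']:.4f} +/- {row['sd']:.4f} (n={row['n']})")
    print(f"unpaired eyes: {len(unpaired)}")
    print(f"tables in {OUT}")
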