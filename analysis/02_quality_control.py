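#!/usr/bin/env python
"""Motion QC: edge trimming, 5-minute clean-window inclusion, filtering.

Reads the simulated cohort, applies the scrubbing rules (0.25 mm edge
trim; at least 5 continuous minutes with all displacements <= 1 mm), and
writes qc_report.csv plus the filtered series used downstream.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from neoconn import io, qc

ROOT = Path(__file__).resolve().parents[1]
WORK = ROOT / "scratch" / "analysis"
TABLES = ROOT / "results" / "analysis"


def main() -> None:
    manifest, series, traces, tr = io.load_cohort_dir(WORK / "cohort")
    clean_dir = WORK / "clean_series"
    clean_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in manifest["subject_id"]:
        filtered, report = qc.qc_subject(sid, series[sid], traces[sid])
        rows.append(dataclasses.asdict(report))
        if filtered is not None:
            io.write_series(filtered, clean_dir / f"{sid}.tsv")
    report_df = pd.DataFrame(rows)
    TABLES.mkdir(parents=True, exist_ok=True)
    report_df.to_csv(TABLES / "qc_report.csv", index=False)
    included = int(report_df["included"].sum())
    print(f"qc report: {TABLES / 'qc_report.csv'}")
    print(f"included {included}/{len(report_df)} subjects")
    if included < len(report_df):
        print(report_df.loc[~report_df["included"], "reason"].value_counts().to_string())


if __name__ == "__main__":
    main()
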