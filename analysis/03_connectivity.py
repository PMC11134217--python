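#!/usr/bin/env python
"""Regional functional connectivity: |Pearson r| between region pairs.

Builds one 92 x 92 connectivity matrix per included subject from the
cleaned series and summarises region-mean connectivity by treatment group.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from neoconn import io
from neoconn.connectivity import abs_pearson, region_mean_connectivity

WORK = Path(__file__).resolve().parents[1] / "scratch" / "analysis"


def main() -> None:
    manifest = io.read_manifest(WORK / "cohort" / "manifest.csv")
    conn_dir = WORK / "connectivity"
    conn_dir.mkdir(parents=True, exist_ok=True)
    grand_means = {}
    for path in sorted((WORK / "clean_series").glob("*.tsv")):
        series = io.read_series(path, tr_seconds=3.0)
        mat = abs_pearson(series)
        pd.DataFrame(mat.values, index=mat.labels, columns=mat.labels).to_csv(
            conn_dir / path.name, sep="\t", float_format="%.8g"
        )
        grand_means[path.stem] = float(np.mean(region_mean_connectivity(mat)))
    summary = manifest.set_index("subject_id").join(
        pd.Series(grand_means, name="mean_connectivity"), how="inner"
    )
    print(f"wrote {len(grand_means)} matrices to {conn_dir}")
    print("mean |r| by group:")
    print(summary.groupby("group")["mean_connectivity"].agg(["mean", "std"]).round(4))


if __name__ == "__main__":
    main()
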