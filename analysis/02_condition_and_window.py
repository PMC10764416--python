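#!/usr/bin/env python
"""Condition the simulated cohort and build labeled window datasets.

Applies the conditioning chain (artifact masking with a +/-0.25 s guard,
zero-phase 0.3-15 Hz Butterworth, 60 Hz standardization), cuts 2-s windows
with 75 % overlap, and applies the >=25 % FOG labeling rule. Writes the
seven-sensor window datasets to scratch/ and a class-balance table to
results/.

Run analysis/01_simulate_cohort.py first.
"""

from pathlib import Path

import pandas as pd

from fogdetect.dataio import read_manifest
from fogdetect.windowing import assemble_dataset, save_dataset

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, role in (("cohort", "train"), ("unseen", "unseen")):
        manifest = read_manifest(SCRATCH / name / "manifest.json")
        ds = assemble_dataset(manifest, "seven", role=role)
        save_dataset(ds, SCRATCH / f"windows_{name}.npz")
        counts = ds.class_counts()
        rows.append(
            {
                "cohort": name,
                "windows": len(ds),
                "fog_windows": counts["POS"],
                "no_fog_windows": counts["NEG"],
                "ambiguous_discarded": counts["DISCARD"],
                "fog_window_percent": 100.0 * counts["POS"] / len(ds),
            }
        )
        print(
            f"{name}: {len(ds)} windows "
            f"({counts['POS']} FOG / {counts['NEG']} no-FOG / "
            f"{counts['DISCARD']} ambiguous)"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "window_counts.csv", index=False)
    print(f"wrote {RESULTS / 'window_counts.csv'}")


if __name__ == "__main__":
    main()
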