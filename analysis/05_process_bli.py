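"""Process raw BLI measurements into net and week-1-normalized flux series.

Reads bli_measurements.csv (three exposures per timepoint), subtracts the
caudal background flux per measurement, keeps the best of three, normalizes
each animal to week 1, and writes flux.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_config

from t2flux import process_bli_table


def main() -> None:
    cfg = load_config()
    out = cfg["cohort_dir"]
    raw = pd.read_csv(out / "bli_measurements.csv")
    flux = process_bli_table(raw)
    flux.to_csv(out / "flux.csv", index=False)

    last_week = flux.week.max()
    end = flux[flux.week == last_week]
    print(f"{len(raw)} raw measurements -> {len(flux)} timepoints in {out/'flux.csv'}")
    print(f"week-{last_week} relative flux: mean {end.relative_flux.mean():.0f} "
          f"(range {end.relative_flux.min():.0f}-{end.relative_flux.max():.0f}; "
          f"absolute {end.net_flux.mean():.2e} p/s)")


if __name__ == "__main__":
    main()
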