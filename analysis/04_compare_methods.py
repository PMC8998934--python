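"""Bland-Altman comparison of tumor volumes from the two contrast methods.

Reads volumes.csv, pairs T2-map and T2-average volumes per session, writes
agreement.json and the Bland-Altman plot, and prints the paired t-test.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_config

from t2flux import bland_altman
from t2flux.io import bland_altman_plot


def main() -> None:
    cfg = load_config()
    out = cfg["cohort_dir"]
    volumes = pd.read_csv(out / "volumes.csv")
    wide = volumes.pivot_table(
        index=["animal_id", "week"], columns="method", values="volume_mm3"
    ).dropna()
    r = bland_altman(wide["t2_map"].to_numpy(), wide["t2_average"].to_numpy())

    report = {
        "n_pairs": int(len(wide)),
        "mean_difference_mm3": r.mean_difference,
        "sd_difference_mm3": r.sd_difference,
        "loa_lower_mm3": r.loa_lower,
        "loa_upper_mm3": r.loa_upper,
        "t": r.t, "df": r.df, "p": r.p,
    }
    (out / "agreement.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    bland_altman_plot(r, out / "bland_altman.png")

    print(f"{len(wide)} paired sessions; mean difference (map - average) "
          f"{r.mean_difference:+.4f} mm^3, limits [{r.loa_lower:.4f}, {r.loa_upper:.4f}]")
    if r.t_defined:
        print(f"paired t-test: t({r.df}) = {r.t:.2f}, p = {r.p:.2f} "
              f"({'no evidence of' if r.p > 0.05 else 'evidence of'} a method difference)")
    else:
        print("differences have zero variance: methods agree exactly on every session")


if __name__ == "__main__":
    main()
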