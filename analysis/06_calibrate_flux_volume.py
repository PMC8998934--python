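"""Calibrate BLI total flux against MRI tumor volume on the log-log scale.

Pairs T2-average volumes with net flux by (animal, week), fits
log10(flux) = intercept + slope * log10(volume), and writes fit.json,
residuals.csv and the calibration/residual panels.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_config

from t2flux import loglog_fit, pair_modalities, predict_flux, residuals
from t2flux.io import calibration_plot


def main() -> None:
    cfg = load_config()
    out = cfg["cohort_dir"]
    volumes = pd.read_csv(out / "volumes.csv")
    flux = pd.read_csv(out / "flux.csv")

    pairs = pair_modalities(volumes, flux, weeks=cfg["weeks"], method="t2_average")
    pairs = pairs[pairs["volume_mm3"] > 0].reset_index(drop=True)
    fit = loglog_fit(pairs["volume_mm3"], pairs["net_flux"])
    expected = [predict_flux(v, fit) for v in pairs["volume_mm3"]]
    res = residuals(pairs["net_flux"].tolist(), expected)

    report = {
        "intercept": fit.intercept, "slope": fit.slope, "a": fit.a,
        "r_squared": fit.r_squared, "spearman_rho": fit.spearman_rho,
        "p": fit.p_value, "n": fit.n,
        "generator": {"intercept": cfg["flux_log10_intercept"], "slope": cfg["flux_slope"]},
    }
    (out / "fit.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    pd.DataFrame(res).to_csv(out / "residuals.csv", index=False)
    calibration_plot(pairs, fit, res, out / "calibration.png")

    print(f"n = {fit.n} paired sessions")
    print(f"log10(flux) = {fit.intercept:.2f} + {fit.slope:.2f} log10(V)   "
          f"[generator: {cfg['flux_log10_intercept']:.2f} + {cfg['flux_slope']:.2f} x]")
    print(f"R^2 = {fit.r_squared:.3f}, Spearman rho = {fit.spearman_rho:.3f}, p = {fit.p_value:.2e}")


if __name__ == "__main__":
    main()
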