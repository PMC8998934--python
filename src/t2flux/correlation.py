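"""Cross-modality calibration: BLI total flux against MRI tumor volume.

Both quantities are transformed with the decadic logarithm and related by
ordinary least squares,

    log10(flux) = log10(a) + b * log10(volume),

equivalent to the power law flux = a * volume^b.  The fit reports R^2, the
Spearman rank correlation with its two-sided p, and the overall-fit
significance from the one-predictor F test (identical to the slope t-test).
Expected fluxes come from inverse transformation of the fitted line;
absolute residuals are observed minus expected and relative residuals are
absolute residuals divided by the observed value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationFit",
    "ResidualRecord",
    "loglog_fit",
    "predict_flux",
    "residuals",
    "pair_modalities",
]


@dataclass
class CalibrationFit:
    """Power-law calibration of flux (p/s) against volume (mm^3).

    ``intercept`` is log10(a) and ``slope`` is the exponent b; ``a`` is the
    flux predicted at 1 mm^3.  ``p_value`` is the overall-fit (ANOVA F)
    significance of the regression.
    """

    intercept: float
    slope: float
    a: float
    r_squared: float
    spearman_rho: float
    spearman_p: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not math.isclose(self.a, 10.0 ** self.intercept, rel_tol=1e-12):
            raise ValueError("a must equal 10**intercept")
        if not -1.0 <= self.spearman_rho <= 1.0:
            raise ValueError("spearman_rho out of [-1, 1]")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared out of [0, 1]")


class ResidualRecord(NamedTuple):
    """Observed vs power-law-expected flux for one session.

    ``absolute = observed - expected`` (p/s);
    ``relative = absolute / observed`` (dimensionless, None when observed=0).
    """

    observed: float
    expected: float
    absolute: float
    relative: float | None


def loglog_fit(volumes: Sequence[float], fluxes: Sequence[float]) -> CalibrationFit:
    """OLS of log10(flux) on log10(volume), with rank correlation.

    Non-positive values cannot be log-transformed and are rejected with an
    error naming the offending record — never silently dropped.  Requires at
    least 3 pairs.
    """
    v = np.asarray(volumes, dtype=float)
    f = np.asarray(fluxes, dtype=float)
    if v.shape != f.shape or v.ndim != 1:
        raise ValueError("volumes and fluxes must be 1-D and equal length")
    if v.size < 3:
        raise ValueError(f"need at least 3 pairs, got {v.size}")
    for name, arr in (("volume", v), ("flux", f)):
        bad = np.nonzero(arr <= 0)[0]
        if bad.size:
            raise ValueError(f"non-positive {name} at record {int(bad[0])}: {arr[bad[0]]!r}")

    x = np.log10(v)
    y = np.log10(f)
    if np.allclose(x, x[0]):
        raise ValueError("all volumes identical; slope is unidentifiable")

    res = stats.linregress(x, y)
    ssr = float(np.sum((y - (res.intercept + res.slope * x)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 0.0 if sst == 0.0 else 1.0 - ssr / sst
    # One-predictor ANOVA F == squared slope t; linregress's p is that test.
    p_value = float(res.pvalue) if sst > 0 else 1.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, rho_p = stats.spearmanr(x, y)
    if math.isnan(rho):  # constant flux: rank correlation undefined -> 0 by convention
        rho, rho_p = 0.0, 1.0
    # Perfectly concordant/discordant ranks are exactly +-1, not 1 - eps.
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.array_equal(rx, ry):
        rho = 1.0
    elif np.array_equal(rx, len(ry) + 1 - ry):
        rho = -1.0
    return CalibrationFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        a=float(10.0 ** res.intercept),
        r_squared=r_squared,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        p_value=p_value,
        n=int(v.size),
    )


def predict_flux(volume_mm3: float, fit: CalibrationFit) -> float:
    """Expected total flux a * volume^b from the calibration (p/s)."""
    if volume_mm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    return fit.a * volume_mm3 ** fit.slope


def residuals(observed: Sequence[float], expected: Sequence[float]) -> list[ResidualRecord]:
    """Per-record absolute and relative residuals of observed vs expected flux."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be 1-D and equal length")
    out = []
    for o, e in zip(obs, exp):
        absolute = float(o - e)
        relative = None if o == 0 else absolute / o
        out.append(ResidualRecord(float(o), float(e), absolute, relative))
    return out


def pair_modalities(
    volumes: pd.DataFrame,
    flux: pd.DataFrame,
    weeks: Sequence[int] | None = None,
    method: str = "t2_average",
) -> pd.DataFrame:
    """Join volume and flux tables on exact (animal_id, week) matches.

    ``volumes`` needs columns (animal_id, week, method, volume_mm3) and
    ``flux`` (animal_id, week, net_flux).  Sessions without a counterpart in
    the other modality are excluded; the count of exclusions is recorded in
    the result's ``attrs['n_excluded']``.  ``weeks`` optionally restricts the
    analysis to a week range.
    """
    vol = volumes[volumes["method"] == method][["animal_id", "week", "volume_mm3"]]
    flx = flux[["animal_id", "week", "net_flux"]]
    if weeks is not None:
        weeks = set(int(w) for w in weeks)
        vol = vol[vol["week"].isin(weeks)]
        flx = flx[flx["week"].isin(weeks)]
    merged = vol.merge(flx, on=["animal_id", "week"], how="inner")
    merged.attrs["n_excluded"] = (len(vol) - len(merged)) + (len(flx) - len(merged))
    return merged.sort_values(["animal_id", "week"]).reset_index(drop=True)
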