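"""Bioluminescence (BLI) flux processing.

Each imaging timepoint comprises up to three exposures (60 s, 30 s, auto) of
a luciferase-expressing tumor.  Per measurement, the total flux (photons/s)
of a caudal background region is subtracted from the tumor-ROI flux; the
highest net flux of the timepoint is kept; and the longitudinal series of an
animal is normalized to its week-1 value, yielding dimensionless relative
flux with week 1 = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["FluxSeries", "net_flux", "best_of_three", "normalize_series", "process_bli_table", "NET_FLUX_FLOOR"]

#: Floor applied when background exceeds ROI flux, photons/s.
NET_FLUX_FLOOR = 1.0

EXPOSURE_LABELS = ("60s", "30s", "auto")


@dataclass
class FluxSeries:
    """One animal's longitudinal net and week-1-normalized flux."""

    animal_id: str
    net_flux: dict[int, float]
    relative_flux: dict[int, float]

    def __post_init__(self) -> None:
        if 1 in self.relative_flux and self.relative_flux[1] != 1.0:
            raise ValueError("relative flux at week 1 must equal 1")


def net_flux(roi_flux: float, bkg_flux: float) -> float:
    """Background-subtracted total flux, floored at 1 p/s.

    Raises on negative inputs; warns (and clamps) when the background
    exceeds the ROI flux so downstream log transforms stay defined.
    """
    if roi_flux < 0 or bkg_flux < 0:
        raise ValueError(f"fluxes must be >= 0, got roi={roi_flux}, bkg={bkg_flux}")
    net = roi_flux - bkg_flux
    if net < NET_FLUX_FLOOR:
        warnings.warn(
            f"background flux ({bkg_flux:g} p/s) >= ROI flux ({roi_flux:g} p/s); "
            f"net flux clamped to {NET_FLUX_FLOOR} p/s",
            stacklevel=2,
        )
        return NET_FLUX_FLOOR
    return net


def best_of_three(net_fluxes: Sequence[float]) -> float:
    """Highest net flux among the (1-3) exposures of one timepoint."""
    if not 1 <= len(net_fluxes) <= 3:
        raise ValueError(f"expected 1-3 measurements per timepoint, got {len(net_fluxes)}")
    return float(max(net_fluxes))


def normalize_series(net_by_week: Mapping[int, float]) -> dict[int, float]:
    """Relative flux: each week's net flux divided by the week-1 value.

    Week 1 must be present and exceed the clamp floor; re-baselining to a
    later week is never done silently.
    """
    if 1 not in net_by_week:
        raise ValueError(f"week 1 missing from series (weeks present: {sorted(net_by_week)})")
    baseline = net_by_week[1]
    if baseline <= NET_FLUX_FLOOR:
        raise ValueError(f"week-1 net flux ({baseline:g} p/s) is at or below the clamp floor")
    return {week: flux / baseline for week, flux in net_by_week.items()}


def process_bli_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Raw measurement table -> tidy per-(animal, week) flux table.

    Input columns: animal_id, week, exposure_label, roi_flux, bkg_flux
    (up to 3 rows per animal-week).  Output columns: animal_id, week,
    net_flux, relative_flux.
    """
    required = {"animal_id", "week", "roi_flux", "bkg_flux"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")

    rows = []
    for animal_id, animal_df in measurements.groupby("animal_id", sort=True):
        net_by_week: dict[int, float] = {}
        for week, week_df in animal_df.groupby("week", sort=True):
            if len(week_df) > 3:
                raise ValueError(f"animal {animal_id} week {week}: more than 3 measurements")
            nets = [net_flux(r.roi_flux, r.bkg_flux) for r in week_df.itertuples(index=False)]
            net_by_week[int(week)] = best_of_three(nets)
        relative = normalize_series(net_by_week)
        for week in sorted(net_by_week):
            rows.append(
                {
                    "animal_id": animal_id,
                    "week": week,
                    "net_flux": net_by_week[week],
                    "relative_flux": relative[week],
                }
            )
    return pd.DataFrame(rows)
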