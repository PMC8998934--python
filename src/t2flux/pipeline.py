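"""End-to-end orchestration of the synthetic-cohort analysis.

Stage order: phantom generation -> relaxometry (T2 map, T2 average) ->
threshold volumetry (both contrast methods) -> Bland-Altman method
comparison -> BLI photometry -> log-log flux/volume calibration ->
survival analysis.  A single :class:`RunConfig` (loadable from YAML) drives
the run; every stage communicates through the declared file formats, and a
fixed seed yields byte-identical outputs and report checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .comparison import bland_altman
from .correlation import loglog_fit, pair_modalities, predict_flux, residuals
from .phantom import (
    PhantomSpec,
    TISSUE_LABELS,
    build_label_map,
    render_echo_stack,
    simulate_bli_table,
    simulate_survival_cohort,
)
from .photometry import process_bli_table
from .relaxometry import EchoStack, compute_t2_average, compute_t2_map
from .survival import km_curve, logrank, mann_whitney, percent_enhancement
from .volumetry import auto_rois, measure_volume, segment_roi

__all__ = ["RunConfig", "run_pipeline", "validate_stack", "contrast_thresholds"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    The default phantom geometry is scaled down from the full acquisition
    matrix so a complete cohort runs in seconds; the acquisition constants
    (FOV, slice thickness, TE list, tissue T2) keep their defaults.
    """

    out_dir: str = "results/run"
    seed: int = 0
    n_animals: int = 4
    weeks: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    matrix_size: tuple[int, int] = (64, 64)
    n_slices: int = 8
    noise_sd: float = 3.0  # ~3% of tumor S0: typical MSME magnitude-image noise
    method: str = "both"  # t2_average | t2_map | both
    animal_v0_sd: float = 0.10  # lognormal spread of initial tumor volume
    # BLI generator
    flux_log10_intercept: float = 5.81
    flux_slope: float = 1.04
    flux_log_resid_sd: float = 0.10
    # survival
    groups: dict[str, float] = field(default_factory=lambda: {"sham": 44.0, "RT/DEC/ABC": 66.0})
    control_group: str = "sham"
    n_per_group: int = 10
    censor_day: float = 139.0
    correlation_weeks: tuple[int, ...] | None = None
    roi_file: str | None = None
    write_images: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not self.weeks:
            raise ValueError("week range must be non-empty")
        if self.method not in ("t2_average", "t2_map", "both"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.control_group not in self.groups:
            raise ValueError(
                f"control group {self.control_group!r} not among groups {sorted(self.groups)}"
            )
        if self.roi_file is not None and not Path(self.roi_file).exists():
            raise ValueError(f"ROI file does not exist: {self.roi_file}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("weeks", "matrix_size", "correlation_weeks"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def phantom_spec(self, v0_mm3: float | None = None, seed: int = 0) -> PhantomSpec:
        spec = PhantomSpec(
            matrix_size=self.matrix_size,
            n_slices=self.n_slices,
            noise_sd=self.noise_sd,
            seed=seed,
        )
        if v0_mm3 is not None:
            spec = dataclasses.replace(spec, tumor_v0_mm3=v0_mm3)
        return spec


def contrast_thresholds(spec: PhantomSpec) -> dict[str, tuple[float, float]]:
    """Threshold bands separating the tumor class in each contrast.

    Midpoints between the expected class values: fitted T2 for the map
    (brain/tumor and tumor/CSF midpoints) and predicted average-image
    intensity for the T2 average contrast.
    """
    t2 = {name: spec.tissue_params[name].t2_ms for name in ("brain", "tumor", "csf")}
    s0 = {name: spec.tissue_params[name].s0 for name in ("brain", "tumor", "csf")}
    te = np.asarray([45.8, 62.5, 79.2])
    avg = {name: s0[name] * float(np.mean(np.exp(-te / t2[name]))) for name in t2}
    return {
        "t2_map": ((t2["brain"] + t2["tumor"]) / 2.0, (t2["tumor"] + t2["csf"]) / 2.0),
        "t2_average": ((avg["brain"] + avg["tumor"]) / 2.0, (avg["tumor"] + avg["csf"]) / 2.0),
    }


def validate_stack(path: str | Path) -> EchoStack:
    """Read an echo stack and check its invariants; errors name the violation.

    Delegates to the EchoStack validator: echo-count/TE-count match,
    strictly increasing TEs, finite voxels (the error carries coordinates).
    """
    return tio.read_echo_stack(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _roi_box_mask(rois, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for roi in rois:
        mask[roi.slice_index, roi.row0 : roi.row1, roi.col0 : roi.col1] = True
    return mask


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report.

    The report lists per-stage record counts, collected warnings, and
    SHA-256 checksums of all written tables; identical config + seed gives
    identical checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"config_seed": config.seed, "stages": {}, "warnings": []}
    caught: list[str] = []

    methods = ["t2_average", "t2_map"] if config.method == "both" else [config.method]
    bands_by_method: dict[str, tuple[float, float]] = {}

    # --- phantom + relaxometry + volumetry, session by session -------------
    volume_rows = []
    gt_rows = []
    animal_v0: dict[str, float] = {}
    for a in range(config.n_animals):
        animal_id = f"a{a + 1:02d}"
        v0 = 0.5 * float(np.exp(rng.normal(0.0, config.animal_v0_sd)))
        animal_v0[animal_id] = v0
        for week in config.weeks:
            session_seed = int(rng.integers(0, 2**31 - 1))
            spec = config.phantom_spec(v0_mm3=v0, seed=session_seed)
            label_map = build_label_map(spec, week)
            stack = render_echo_stack(label_map, spec)
            if config.write_images:
                tio.write_echo_stack(stack, out / "stacks" / f"{animal_id}_w{week}.nii")
                tio.write_label_map(label_map, out / "labels" / f"{animal_id}_w{week}.nii")
            gt_rows.append(
                {
                    "animal_id": animal_id,
                    "week": week,
                    "volume_mm3": label_map.ground_truth_tumor_volume_mm3,
                }
            )

            bands = contrast_thresholds(spec)
            tumor_mask = label_map.tissue_mask("tumor")
            for method in methods:
                lo, hi = bands[method]
                bands_by_method[method] = (lo, hi)
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    if method == "t2_average":
                        image = compute_t2_average(stack).values
                    else:
                        rois_probe = auto_rois(np.zeros(stack.spatial_shape), tumor_mask, lo, hi)
                        box_mask = _roi_box_mask(rois_probe, stack.spatial_shape)
                        image = compute_t2_map(stack, mask=box_mask).t2_ms
                    rois = auto_rois(image, tumor_mask, lo, hi)
                    masks: dict[int, list[np.ndarray]] = {}
                    for roi in rois:
                        masks.setdefault(roi.slice_index, []).append(
                            segment_roi(image[roi.slice_index], roi)
                        )
                    vm = measure_volume(
                        masks,
                        spec.voxel_volume_mm3,
                        animal_id=animal_id,
                        week=week,
                        method=method,
                    )
                caught.extend(str(w.message) for w in wlist)
                volume_rows.append(
                    {
                        "animal_id": animal_id,
                        "week": week,
                        "method": method,
                        "pixels": vm.total_pixels,
                        "volume_mm3": vm.volume_mm3,
                    }
                )

    volumes = pd.DataFrame(volume_rows)
    ground_truth = pd.DataFrame(gt_rows)
    volumes.to_csv(out / "volumes.csv", index=False)
    ground_truth.to_csv(out / "ground_truth_volumes.csv", index=False)
    report["stages"]["volumetry"] = {
        "n_sessions": len(ground_truth),
        "n_measurements": len(volumes),
    }

    # --- method comparison -------------------------------------------------
    if config.method == "both":
        wide = volumes.pivot_table(
            index=["animal_id", "week"], columns="method", values="volume_mm3"
        ).dropna()
        agreement = bland_altman(wide["t2_map"].to_numpy(), wide["t2_average"].to_numpy())
        agreement_report = {
            "n_pairs": int(len(wide)),
            "mean_difference_mm3": agreement.mean_difference,
            "sd_difference_mm3": agreement.sd_difference,
            "loa_lower_mm3": agreement.loa_lower,
            "loa_upper_mm3": agreement.loa_upper,
            "t": agreement.t,
            "df": agreement.df,
            "p": agreement.p,
        }
        (out / "agreement.json").write_text(json.dumps(agreement_report, indent=2, sort_keys=True) + "\n")
        if config.make_plots:
            tio.bland_altman_plot(agreement, out / "bland_altman.png")
        report["stages"]["comparison"] = agreement_report

    # --- photometry ---------------------------------------------------------
    # BLI is acquired weekly from week 1; when week 1 was not an MRI session,
    # its volume comes from the growth schedule so normalization has a baseline.
    bli_volumes = ground_truth
    if 1 not in config.weeks:
        week1_rows = [
            {"animal_id": aid, "week": 1, "volume_mm3": v0}
            for aid, v0 in animal_v0.items()
        ]
        bli_volumes = pd.concat([pd.DataFrame(week1_rows), ground_truth], ignore_index=True)
        bli_volumes = bli_volumes.sort_values(["animal_id", "week"]).reset_index(drop=True)
    bli_seed = int(rng.integers(0, 2**31 - 1))
    bli_raw = simulate_bli_table(
        bli_volumes,
        log10_intercept=config.flux_log10_intercept,
        slope=config.flux_slope,
        log_resid_sd=config.flux_log_resid_sd,
        seed=bli_seed,
    )
    bli_raw.to_csv(out / "bli_measurements.csv", index=False)
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        flux = process_bli_table(bli_raw)
    caught.extend(str(w.message) for w in wlist)
    flux.to_csv(out / "flux.csv", index=False)
    report["stages"]["photometry"] = {"n_measurements": len(bli_raw), "n_timepoints": len(flux)}

    # --- correlation ---------------------------------------------------------
    corr_method = "t2_average" if config.method in ("both", "t2_average") else "t2_map"
    pairs = pair_modalities(volumes, flux, weeks=config.correlation_weeks, method=corr_method)
    pairs = pairs[pairs["volume_mm3"] > 0].reset_index(drop=True)
    fit = loglog_fit(pairs["volume_mm3"], pairs["net_flux"])
    expected = [predict_flux(v, fit) for v in pairs["volume_mm3"]]
    res = residuals(pairs["net_flux"].tolist(), expected)
    fit_report = {
        "intercept": fit.intercept,
        "slope": fit.slope,
        "a": fit.a,
        "r_squared": fit.r_squared,
        "spearman_rho": fit.spearman_rho,
        "p": fit.p_value,
        "n": fit.n,
        "n_excluded": int(pairs.attrs.get("n_excluded", 0)),
    }
    (out / "fit.json").write_text(json.dumps(fit_report, indent=2, sort_keys=True) + "\n")
    pd.DataFrame(res).to_csv(out / "residuals.csv", index=False)
    if config.make_plots:
        tio.calibration_plot(pairs, fit, res, out / "calibration.png")
    report["stages"]["correlation"] = fit_report

    # --- survival ------------------------------------------------------------
    surv_seed = int(rng.integers(0, 2**31 - 1))
    cohort = simulate_survival_cohort(
        config.groups, config.n_per_group, censor_day=config.censor_day, seed=surv_seed
    )
    cohort.to_csv(out / "survival.csv", index=False)
    summaries = {}
    for group, gdf in cohort.groupby("group", sort=True):
        summaries[group] = km_curve(gdf["day"], gdf["event"], group=group)
    control = summaries[config.control_group]
    surv_report = {"groups": {}, "comparisons": {}}
    for group, s in summaries.items():
        surv_report["groups"][group] = {
            "n": s.n,
            "n_events": s.n_events,
            "km_median_days": None if not s.median_defined else s.median_days,
            "event_time_median_days": None
            if math.isnan(s.event_time_median_days)
            else s.event_time_median_days,
        }
    cdf = cohort[cohort["group"] == config.control_group]
    for group, s in summaries.items():
        if group == config.control_group:
            continue
        gdf = cohort[cohort["group"] == group]
        lr = logrank(gdf["day"], gdf["event"], cdf["day"], cdf["event"])
        mw = mann_whitney(gdf["day"], cdf["day"])
        pct = (
            percent_enhancement(s.median_days, control.median_days)
            if s.median_defined and control.median_defined
            else math.nan
        )
        surv_report["comparisons"][group] = {
            "vs": config.control_group,
            "logrank_chi_square": lr.chi_square if lr.defined else None,
            "logrank_p": lr.p if lr.defined else None,
            "mann_whitney_u": mw.u,
            "mann_whitney_p": mw.p,
            "percent_enhancement": None if math.isnan(pct) else pct,
        }
    (out / "survival_report.json").write_text(
        json.dumps(surv_report, indent=2, sort_keys=True) + "\n"
    )
    if config.make_plots:
        tio.km_plot(summaries.values(), out / "km.png")
    report["stages"]["survival"] = surv_report

    report["warnings"] = caught
    report["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*"))
        if p.suffix in (".csv", ".json")
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
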