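"""Digital-phantom cohort generator with known ground truth.

Emulates a preclinical orthotopic brain-tumor imaging study: a brain
ellipsoid with two CSF-filled ventricles and a growing tumor is voxelized
on the MSME acquisition grid (20 slices x 256x256 over a 20x20 mm FOV,
0.8 mm slices by default), rendered into multi-echo stacks through the
mono-exponential decay model, and paired with simulated bioluminescence
flux values (power-law in volume) and survival tables (log-logistic with
controlled medians).

Ground truth — tissue labels, exact tumor volume, generating T2 values,
flux-law coefficients, survival medians — is recorded so downstream fits
can be checked for recovery.  All randomness flows through explicit integer
seeds; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .relaxometry import EchoStack

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "LabelMap",
    "TISSUE_LABELS",
    "build_label_map",
    "render_echo_stack",
    "simulate_flux",
    "simulate_survival_cohort",
    "simulate_bli_table",
    "default_growth_rate",
]

#: Integer codes used in label volumes.
TISSUE_LABELS = {"background": 0, "brain": 1, "csf": 2, "tumor": 3}

#: Default echo times of the emulated MSME protocol (2 PD- + 8 T2-weighted), ms.
DEFAULT_TE_MS = (12.5, 29.2, 45.8, 62.5, 79.2, 95.8, 112.5, 129.2, 145.8, 162.5)


class TissueParams(tuple):
    """(S0, T2_ms) pair for one tissue class."""

    def __new__(cls, s0: float, t2_ms: float):
        if t2_ms <= 0:
            raise ValueError(f"T2 must be positive, got {t2_ms}")
        if s0 < 0:
            raise ValueError(f"S0 must be non-negative, got {s0}")
        return super().__new__(cls, (float(s0), float(t2_ms)))

    @property
    def s0(self) -> float:
        return self[0]

    @property
    def t2_ms(self) -> float:
        return self[1]


def _default_tissue_params() -> dict[str, TissueParams]:
    # T2: healthy brain ~47 ms, medulloblastoma ~68 ms, CSF ~125 ms.
    # S0 values are arbitrary intensity units; only contrast matters downstream.
    return {
        "background": TissueParams(0.0, 1.0),
        "brain": TissueParams(90.0, 47.0),
        "csf": TissueParams(120.0, 125.0),
        "tumor": TissueParams(100.0, 68.0),
    }


def default_growth_rate(v0_mm3: float = 0.5, v_week8_mm3: float = 38.0) -> float:
    """Weekly exponential growth rate anchoring week-8 volume.

    Solves V(w) = V0 * exp(k*(w-1)) for k with V(8) given; the defaults give
    k = ln(38/0.5)/7 ~ 0.6187 per week.
    """
    if v0_mm3 <= 0 or v_week8_mm3 <= 0:
        raise ValueError("volumes must be positive")
    return math.log(v_week8_mm3 / v0_mm3) / 7.0


@dataclass
class PhantomSpec:
    """Acquisition geometry, tissue parameters and growth model of the phantom.

    Defaults reproduce the emulated protocol: 256x256 matrix over a
    20x20 mm FOV, 20 gapless 0.8 mm slices, the 10-echo TE list from
    12.5 to 162.5 ms, and tissue T2 values of 47 ms (brain), 68 ms (tumor)
    and 125 ms (CSF).
    """

    matrix_size: tuple[int, int] = (256, 256)
    n_slices: int = 20
    fov_mm: tuple[float, float] = (20.0, 20.0)
    slice_thickness_mm: float = 0.8
    te_ms: tuple[float, ...] = DEFAULT_TE_MS
    tissue_params: dict[str, TissueParams] = field(default_factory=_default_tissue_params)
    tumor_v0_mm3: float = 0.5
    tumor_growth_per_week: float = field(default_factory=default_growth_rate)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if not (np.all(np.diff(te) > 0) and np.all(te > 0)):
            raise ValueError("te_ms must be strictly increasing and positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.fov_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("fov and slice_thickness must be positive")
        if self.tumor_v0_mm3 <= 0:
            raise ValueError("initial tumor volume must be positive")
        for name, params in self.tissue_params.items():
            if not isinstance(params, TissueParams):
                self.tissue_params[name] = TissueParams(*params)

    @property
    def voxel_volume_mm3(self) -> float:
        return (
            (self.fov_mm[0] / self.matrix_size[0])
            * (self.fov_mm[1] / self.matrix_size[1])
            * self.slice_thickness_mm
        )

    def tumor_volume_at_week(self, week: int) -> float:
        """Scheduled tumor volume V(w) = V0 * exp(k*(w-1)) in mm^3."""
        return self.tumor_v0_mm3 * math.exp(self.tumor_growth_per_week * (week - 1))


@dataclass
class LabelMap:
    """Per-voxel tissue labels for one imaging session, with exact ground truth.

    ``ground_truth_tumor_volume_mm3`` equals the tumor voxel count times the
    voxel volume exactly, by construction.
    """

    labels: np.ndarray
    session_week: int
    ground_truth_tumor_volume_mm3: float
    voxel_volume_mm3: float

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.labels == TISSUE_LABELS[name]


def _grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinates (z, y, x) in mm, origin at the FOV center."""
    nz = spec.n_slices
    ny, nx = spec.matrix_size
    dz = spec.slice_thickness_mm
    dy = spec.fov_mm[0] / ny
    dx = spec.fov_mm[1] / nx
    z = (np.arange(nz) + 0.5) * dz - nz * dz / 2.0
    y = (np.arange(ny) + 0.5) * dy - spec.fov_mm[0] / 2.0
    x = (np.arange(nx) + 0.5) * dx - spec.fov_mm[1] / 2.0
    return np.meshgrid(z, y, x, indexing="ij")


def build_label_map(spec: PhantomSpec, session_week: int) -> LabelMap:
    """Voxelize brain, ventricles and the week's tumor onto the acquisition grid.

    The brain is an ellipsoid centered in the FOV; two paraboloid-like CSF
    ventricle regions sit para-midline; the tumor occupies exactly
    ``round(V(week)/voxel_volume)`` brain voxels nearest its seed point
    (ellipsoidal metric in mm), so the recorded ground-truth volume lands
    within half a voxel of the scheduled volume.

    Raises
    ------
    ValueError
        If ``session_week < 1`` or the scheduled tumor volume exceeds the
        available brain volume (message names the week and both volumes).
    """
    if session_week < 1:
        raise ValueError(f"session_week must be >= 1, got {session_week}")
    zz, yy, xx = _grid_mm(spec)

    # Brain ellipsoid: semi-axes at 84% of the half-FOV in-plane, 90% through-plane.
    a_y = 0.42 * spec.fov_mm[0]
    a_x = 0.42 * spec.fov_mm[1]
    a_z = 0.45 * spec.n_slices * spec.slice_thickness_mm
    brain = (yy / a_y) ** 2 + (xx / a_x) ** 2 + (zz / a_z) ** 2 <= 1.0

    labels = np.zeros(brain.shape, dtype=np.int8)
    labels[brain] = TISSUE_LABELS["brain"]

    # Two lateral-ventricle CSF regions: small elongated ellipsoids off midline.
    for side in (-1.0, 1.0):
        cy, cx, cz = -0.05 * spec.fov_mm[0], side * 0.09 * spec.fov_mm[1], 0.0
        vent = (
            ((yy - cy) / 2.2) ** 2 + ((xx - cx) / 0.8) ** 2 + ((zz - cz) / 1.8) ** 2
        ) <= 1.0
        labels[vent & brain] = TISSUE_LABELS["csf"]

    # Tumor: exact-count voxel selection around a posterior-lateral seed point.
    target_volume = spec.tumor_volume_at_week(session_week)
    vox = spec.voxel_volume_mm3
    target_n = int(round(target_volume / vox))
    candidates = labels == TISSUE_LABELS["brain"]
    n_avail = int(candidates.sum())
    if target_n > n_avail:
        raise ValueError(
            f"week {session_week}: scheduled tumor volume {target_volume:.2f} mm^3 "
            f"exceeds available brain volume {n_avail * vox:.2f} mm^3"
        )
    if target_n > 0:
        cy, cx, cz = 0.15 * spec.fov_mm[0], -0.10 * spec.fov_mm[1], 0.0
        dist2 = (yy - cy) ** 2 + (xx - cx) ** 2 + (zz - cz) ** 2
        cand_idx = np.flatnonzero(candidates.ravel())
        # Stable ordering: distance, then flat index — deterministic tie-break.
        order = np.lexsort((cand_idx, dist2.ravel()[cand_idx]))
        chosen = cand_idx[order[:target_n]]
        labels.ravel()[chosen] = TISSUE_LABELS["tumor"]

    gt_volume = float((labels == TISSUE_LABELS["tumor"]).sum()) * vox
    return LabelMap(
        labels=labels,
        session_week=session_week,
        ground_truth_tumor_volume_mm3=gt_volume,
        voxel_volume_mm3=vox,
    )


def render_echo_stack(label_map: LabelMap, spec: PhantomSpec, seed: int | None = None) -> EchoStack:
    """Render a label map into a multi-echo stack via S(TE) = S0 exp(-TE/T2).

    Additive Gaussian noise of standard deviation ``spec.noise_sd`` is applied
    per voxel and echo (high-SNR approximation to magnitude-image Rician
    noise).  Deterministic for a fixed seed.
    """
    present = set(np.unique(label_map.labels).tolist())
    code_to_name = {v: k for k, v in TISSUE_LABELS.items()}
    for code in present:
        name = code_to_name.get(int(code))
        if name is None or name not in spec.tissue_params:
            raise ValueError(f"label code {code} has no tissue parameters")

    te = np.asarray(spec.te_ms, dtype=float)
    s0_lut = np.zeros(max(TISSUE_LABELS.values()) + 1)
    t2_lut = np.ones_like(s0_lut)
    for name, code in TISSUE_LABELS.items():
        if name in spec.tissue_params:
            s0_lut[code] = spec.tissue_params[name].s0
            t2_lut[code] = spec.tissue_params[name].t2_ms

    s0 = s0_lut[label_map.labels]
    t2 = t2_lut[label_map.labels]
    signal = s0[..., None] * np.exp(-te[None, None, None, :] / t2[..., None])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    return EchoStack(
        intensities=signal,
        te_ms=te,
        fov_mm=spec.fov_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
    )


def simulate_flux(
    volume_mm3: float,
    log10_intercept: float = 5.81,
    slope: float = 1.04,
    log_resid_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw a BLI total flux (p/s) from the power law flux = a * V^b.

    On the decadic-log scale, log10(flux) = intercept + slope*log10(V) + eps
    with eps ~ Normal(0, log_resid_sd).  The default coefficients are the
    calibration the generator is meant to be recovered against.
    """
    if volume_mm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    if log_resid_sd < 0:
        raise ValueError("log_resid_sd must be >= 0")
    eps = 0.0
    if log_resid_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, log_resid_sd)
    return float(10.0 ** (log10_intercept + slope * math.log10(volume_mm3) + eps))


def simulate_bli_table(
    volumes: pd.DataFrame,
    log10_intercept: float = 5.81,
    slope: float = 1.04,
    log_resid_sd: float = 0.10,
    bkg_flux: float = 2.0e4,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a raw BLI measurement table from per-session tumor volumes.

    ``volumes`` needs columns (animal_id, week, volume_mm3).  Each session
    yields three exposures (60s, 30s, auto) whose ROI fluxes scatter around
    the power-law flux for that volume; the caudal background flux is added
    on so that downstream net-flux subtraction recovers the signal.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in volumes.itertuples(index=False):
        true_flux = simulate_flux(
            rec.volume_mm3, log10_intercept, slope, log_resid_sd, rng=rng
        )
        for label, rel in (("60s", 1.0), ("30s", 0.93), ("auto", 0.97)):
            jitter = rng.normal(1.0, 0.02)
            bkg = bkg_flux * rng.uniform(0.8, 1.2)
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "week": int(rec.week),
                    "exposure_label": label,
                    "roi_flux": max(true_flux * rel * jitter, 0.0) + bkg,
                    "bkg_flux": bkg,
                }
            )
    return pd.DataFrame(rows)


def simulate_survival_cohort(
    group_medians: dict[str, float],
    n_per_group: int,
    censor_day: float = 139.0,
    seed: int = 0,
    shape: float = 8.0,
) -> pd.DataFrame:
    """Simulate a survival table with log-logistic event times per group.

    The log-logistic scale parameter is set to the group median (its median
    is the scale exactly); ``shape`` controls spread, with larger values
    giving tighter times around the median and a heavy right tail resembling
    occasional long-term survivors.  Times beyond ``censor_day`` are recorded
    as censored at that day (event = False).

    Returns a DataFrame with columns (animal_id, group, day, event).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 animals per group")
    for g, m in group_medians.items():
        if m <= 0:
            raise ValueError(f"median for group {g!r} must be positive, got {m}")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 1
    for group, median in group_medians.items():
        u = rng.uniform(size=n_per_group)
        times = median * (u / (1.0 - u)) ** (1.0 / shape)
        for t in times:
            event = t <= censor_day
            rows.append(
                {
                    "animal_id": f"m{counter:04d}",
                    "group": group,
                    "day": float(t if event else censor_day),
                    "event": bool(event),
                }
            )
            counter += 1
    return pd.DataFrame(rows)
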