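"""File formats: NIfTI / multi-page TIFF image stacks with JSON sidecars,
CSV tables, JSON reports and diagnostic plots.

Conventions
-----------
* Echo stacks are stored as 4-D NIfTI (axes slice, row, col, echo) with the
  voxel sizes in the affine, or as multi-page TIFF with the same axis order.
  Either carries a JSON sidecar ``{"te_ms": [...], "fov_mm": [...],
  "slice_thickness_mm": ...}`` next to the image file.
* Label maps are integer NIfTI volumes (slice, row, col).
* All tables are plain CSV with fixed headers (see the writer docstrings).
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .comparison import AgreementResult
from .phantom import LabelMap
from .relaxometry import EchoStack, T2Map

__all__ = [
    "write_echo_stack",
    "read_echo_stack",
    "write_label_map",
    "read_label_map",
    "write_t2_map",
    "write_t2_map_png",
    "bland_altman_plot",
    "km_plot",
    "calibration_plot",
]


def _sidecar_path(image_path: Path) -> Path:
    name = image_path.name
    for suffix in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suffix):
            return image_path.with_name(name[: -len(suffix)] + ".json")
    return image_path.with_suffix(".json")


def _write_sidecar(stack: EchoStack, image_path: Path) -> Path:
    sidecar = _sidecar_path(image_path)
    sidecar.write_text(
        json.dumps(
            {
                "te_ms": [float(t) for t in stack.te_ms],
                "fov_mm": [float(v) for v in stack.fov_mm],
                "slice_thickness_mm": float(stack.slice_thickness_mm),
            },
            indent=2,
        )
        + "\n"
    )
    return sidecar


def _stack_affine(stack: EchoStack) -> np.ndarray:
    ns, nr, nc, _ = stack.intensities.shape
    affine = np.diag(
        [
            stack.slice_thickness_mm,
            stack.fov_mm[0] / nr,
            stack.fov_mm[1] / nc,
            1.0,
        ]
    )
    return affine


def write_echo_stack(stack: EchoStack, path: str | Path) -> Path:
    """Write a multi-echo stack (NIfTI or TIFF by extension) plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, stack.intensities.astype(np.float32))
    else:
        img = nib.Nifti1Image(stack.intensities.astype(np.float32), _stack_affine(stack))
        nib.save(img, path)
    _write_sidecar(stack, path)
    return path


def read_echo_stack(path: str | Path) -> EchoStack:
    """Read a stack written by :func:`write_echo_stack`; validates invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if path.name.endswith((".tif", ".tiff")):
        data = np.asarray(tifffile.imread(path), dtype=float)
    else:
        data = np.asarray(nib.load(path).get_fdata(), dtype=float)
    return EchoStack(
        intensities=data,
        te_ms=np.asarray(meta["te_ms"], dtype=float),
        fov_mm=tuple(meta.get("fov_mm", (20.0, 20.0))),
        slice_thickness_mm=float(meta.get("slice_thickness_mm", 0.8)),
    )


def write_label_map(label_map: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(label_map.labels.astype(np.int16), np.eye(4))
    img.header["descrip"] = f"week={label_map.session_week}".encode()
    nib.save(img, path)
    return path


def read_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(path).get_fdata(), dtype=int)


def write_t2_map(t2map: T2Map, path: str | Path) -> Path:
    """Store fitted T2 (ms, NaN where undefined) as float NIfTI — unclamped."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(t2map.t2_ms.astype(np.float32), np.eye(4)), path)
    return path


def write_t2_map_png(t2map: T2Map, slice_index: int, path: str | Path) -> Path:
    """Render one slice with the display clamp (values above map to top color)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(
        t2map.clamped_for_display()[slice_index],
        cmap="jet",
        vmin=0.0,
        vmax=t2map.display_clamp_ms,
    )
    fig.colorbar(im, ax=ax, label="T2 (ms)")
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path


def bland_altman_plot(result: AgreementResult, path: str | Path) -> Path:
    """Differences vs means with mean and ±1.96 SD reference lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=18, alpha=0.7)
    for y, style in (
        (result.mean_difference, "-"),
        (result.loa_lower, "--"),
        (result.loa_upper, "--"),
    ):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean tumor volume (mm$^3$)")
    ax.set_ylabel("volume difference, map $-$ average (mm$^3$)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def km_plot(summaries, path: str | Path) -> Path:
    """Step plot of the Kaplan-Meier curves of several groups."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in summaries:
        t = np.concatenate([[0.0], s.times])
        y = np.concatenate([[1.0], s.survival])
        ax.step(t, y, where="post", label=f"{s.group} (n={s.n})")
    ax.set_xlabel("days post injection")
    ax.set_ylabel("cumulative survival")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def calibration_plot(pairs: pd.DataFrame, fit, residual_records, path: str | Path) -> Path:
    """Log-log scatter with the fitted line, plus residual panels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    x = np.log10(pairs["volume_mm3"])
    y = np.log10(pairs["net_flux"])
    axes[0].scatter(x, y, s=16, alpha=0.7)
    grid = np.linspace(x.min(), x.max(), 50)
    axes[0].plot(grid, fit.intercept + fit.slope * grid, "k-", linewidth=1)
    axes[0].set_xlabel("log10 volume (mm$^3$)")
    axes[0].set_ylabel("log10 total flux (p/s)")
    axes[0].set_title(
        f"y = {fit.intercept:.2f} + {fit.slope:.2f}x,  R$^2$={fit.r_squared:.3f}", fontsize=9
    )
    absolute = [r.absolute for r in residual_records]
    relative = [r.relative for r in residual_records]
    for ax, vals, label in (
        (axes[1], absolute, "absolute residual (p/s)"),
        (axes[2], relative, "relative residual"),
    ):
        ax.scatter(pairs["volume_mm3"], vals, s=16, alpha=0.7)
        ax.axhline(float(np.mean(vals)), color="k", linewidth=1)
        ax.set_xlabel("tumor volume (mm$^3$)")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
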