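"""Pixel-wise T2 relaxometry from multi-slice multi-echo (MSME) stacks.

A spin-echo signal decays mono-exponentially with echo time,

    S(TE) = S0 * exp(-TE / T2),

where ``S0`` is the extrapolated intensity at TE = 0 and ``T2`` the
transverse relaxation time of the tissue (ms).  Fitting this model to the
echo-time course of every pixel yields a T2 map — an image whose values are
relaxation times rather than raw intensities.  A noise-reduced anatomical
contrast ("T2 average image") is obtained separately by averaging a subset
of echo images pixel by pixel.

The fit minimizes the sum-squared error with a derivative-free simplex
search (Nelder-Mead), initialized from a log-linear regression on the
positive intensities.  Pixels without usable signal — background, nonpositive
intensities, non-decaying time courses — are flagged undefined rather than
silently set to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "EchoStack",
    "T2Map",
    "T2AverageImage",
    "PixelFit",
    "fit_pixel_decay",
    "compute_t2_map",
    "compute_t2_average",
    "estimate_noise_floor",
]

#: T2 validity window for accepted fits, ms.  Fits outside are flagged undefined.
T2_MIN_MS = 1e-6
T2_MAX_MS = 2000.0

#: Default echo subset averaged into the T2 average image, ms.
DEFAULT_AVERAGE_TES = (45.8, 62.5, 79.2)

#: Tolerance for matching a requested echo time against stack metadata, ms.
TE_MATCH_TOL_MS = 1e-6


@dataclass
class EchoStack:
    """Multi-echo image volume with acquisition geometry.

    Attributes
    ----------
    intensities:
        Real array of shape ``(n_slices, n_rows, n_cols, n_echoes)``.
    te_ms:
        Echo times, one per echo index, strictly increasing (ms).
    fov_mm:
        In-plane field of view ``(fov_row, fov_col)`` in mm.
    slice_thickness_mm:
        Slice width in mm (acquired without gap).
    """

    intensities: np.ndarray
    te_ms: np.ndarray
    fov_mm: tuple[float, float] = (20.0, 20.0)
    slice_thickness_mm: float = 0.8

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.intensities.ndim != 4:
            raise ValueError(
                f"intensities must be 4-D (slice, row, col, echo); got shape {self.intensities.shape}"
            )
        if self.te_ms.ndim != 1 or self.te_ms.size != self.intensities.shape[3]:
            raise ValueError(
                f"te_ms has {self.te_ms.size} entries but the stack has "
                f"{self.intensities.shape[3]} echoes"
            )
        if not np.all(np.diff(self.te_ms) > 0):
            raise ValueError(f"te_ms must be strictly increasing; got {self.te_ms.tolist()}")
        if np.any(self.te_ms <= 0):
            raise ValueError("echo times must be positive")
        if not np.all(np.isfinite(self.intensities)):
            bad = np.argwhere(~np.isfinite(self.intensities))[0]
            raise ValueError(f"non-finite intensity at (slice,row,col,echo)={tuple(int(i) for i in bad)}")
        if self.slice_thickness_mm <= 0 or min(self.fov_mm) <= 0:
            raise ValueError("geometry (fov, slice thickness) must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.intensities.shape[3]


@dataclass
class T2Map:
    """Per-pixel fitted relaxation times plus fit diagnostics.

    ``t2_ms`` holds NaN at undefined pixels; ``defined`` is the authoritative
    flag.  ``display_clamp_ms`` caps only renderings (values above map to the
    top color), never the stored values.
    """

    t2_ms: np.ndarray
    s0: np.ndarray
    sse: np.ndarray
    defined: np.ndarray
    display_clamp_ms: float = 120.0

    def __post_init__(self) -> None:
        if np.any(self.t2_ms[self.defined] <= 0):
            raise ValueError("defined T2 values must be positive")
        if np.any(self.sse[self.defined] < 0):
            raise ValueError("sum-squared error must be non-negative")

    def clamped_for_display(self) -> np.ndarray:
        """T2 values clipped to [0, display_clamp_ms] for rendering only."""
        out = np.where(self.defined, self.t2_ms, 0.0)
        return np.clip(out, 0.0, self.display_clamp_ms)


@dataclass
class T2AverageImage:
    """Pixel-wise mean of selected echo images (noise-reduced T2 contrast)."""

    values: np.ndarray
    te_subset_ms: tuple[float, ...]
    window: tuple[float, float] | None = None

    def windowed_for_display(self) -> np.ndarray:
        """Values clipped to the display window; stored values untouched."""
        if self.window is None:
            return self.values.copy()
        lo, hi = self.window
        return np.clip(self.values, lo, hi)


class PixelFit(NamedTuple):
    """Result of a single-pixel decay fit; ``defined=False`` flags a rejected fit."""

    s0: float
    t2_ms: float
    sse: float
    defined: bool


_UNDEFINED = PixelFit(math.nan, math.nan, math.nan, False)


def _loglinear_init(intensities: np.ndarray, te: np.ndarray) -> tuple[float, float] | None:
    """Initial (s0, t2) from a straight-line fit of log(S) against TE.

    Uses only strictly positive samples; returns None when fewer than two
    remain or the time course does not decay.
    """
    pos = intensities > 0
    if pos.sum() < 2:
        return None
    y = np.log(intensities[pos])
    x = te[pos]
    slope, intercept = np.polyfit(x, y, 1)
    s0 = float(np.exp(intercept))
    if slope < 0:
        t2 = -1.0 / slope
    else:
        # Non-decaying course: start from a T2 beyond the sampled TE range.
        t2 = 10.0 * float(te[-1])
    return s0, float(min(t2, T2_MAX_MS))


def fit_pixel_decay(
    intensities: Sequence[float] | np.ndarray,
    te_ms: Sequence[float] | np.ndarray,
    *,
    maxiter: int = 10_000,
    sse_rtol: float = 1e-10,
) -> PixelFit:
    """Fit ``S(TE) = s0 * exp(-TE/t2)`` to one pixel's echo time course.

    Parameters
    ----------
    intensities:
        Observed intensity at each echo.
    te_ms:
        Echo times (ms), strictly increasing, at least 3.
    maxiter:
        Iteration cap for the simplex search (safety bound).
    sse_rtol:
        Relative tolerance on the cost used as the simplex ``fatol``.

    Returns
    -------
    PixelFit
        ``(s0, t2_ms, sse, defined)``; ``defined=False`` when no usable
        signal is present or the minimizer leaves the T2 validity window
        ``(0, 2000]`` ms.

    Raises
    ------
    ValueError
        If fewer than 3 echoes are supplied or te_ms is not increasing.
    """
    s = np.asarray(intensities, dtype=float)
    te = np.asarray(te_ms, dtype=float)
    if s.size < 3 or te.size != s.size:
        raise ValueError(f"need >=3 echoes with matching TEs; got {s.size} intensities, {te.size} TEs")
    if not np.all(np.diff(te) > 0):
        raise ValueError("te_ms must be strictly increasing")

    if not np.any(s > 0):
        return _UNDEFINED
    init = _loglinear_init(s, te)
    if init is None:
        return _UNDEFINED
    s0_init, t2_init = init

    def sse(params: np.ndarray) -> float:
        s0, t2 = params
        if t2 <= 0:
            return np.inf
        r = s - s0 * np.exp(-te / t2)
        return float(r @ r)

    x0 = np.array([s0_init, t2_init])
    f0 = sse(x0)
    res = minimize(
        sse,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "fatol": sse_rtol * max(f0, 1.0),
            "xatol": 1e-10 * max(s0_init, t2_init),
        },
    )
    s0_fit, t2_fit = float(res.x[0]), float(res.x[1])
    if not np.isfinite(res.fun) or not (T2_MIN_MS < t2_fit <= T2_MAX_MS) or s0_fit <= 0:
        return _UNDEFINED
    return PixelFit(s0_fit, t2_fit, float(res.fun), True)


def estimate_noise_floor(stack: EchoStack, border: int | None = None) -> float:
    """Robust signal threshold below which pixels are treated as background.

    The image border (a frame of ``border`` pixels in every slice, default
    1/8 of the smaller in-plane dimension capped at 10) samples air outside
    the head.  The floor is ``median + 3 * 1.4826 * MAD`` of those border
    intensities pooled over all echoes — the usual robust Gaussian sigma
    scaled to a 3-sigma detection limit.
    """
    _, nr, nc, _ = stack.intensities.shape
    if border is None:
        border = max(2, min(10, min(nr, nc) // 8))
    frame = np.zeros((nr, nc), dtype=bool)
    frame[:border, :] = frame[-border:, :] = True
    frame[:, :border] = frame[:, -border:] = True
    vals = stack.intensities[:, frame, :].ravel()
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med + 3.0 * 1.4826 * mad


def compute_t2_map(
    stack: EchoStack,
    mask: np.ndarray | None = None,
    *,
    noise_floor: float | None = None,
    display_clamp_ms: float = 120.0,
) -> T2Map:
    """Fit the decay model at every (masked) pixel of a multi-echo stack.

    Every pixel's full echo time course enters the fit.  Pixels outside the
    mask, or whose maximum echo intensity does not exceed the noise floor,
    are flagged undefined; per-pixel fit failures likewise become undefined
    flags and never abort the map.

    Parameters
    ----------
    stack:
        Validated multi-echo stack.
    mask:
        Optional boolean array matching the spatial shape; True selects
        pixels to fit.
    noise_floor:
        Signal threshold; estimated from the image border when None.
    """
    shape = stack.spatial_shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} does not match stack {shape}")
    if noise_floor is None:
        noise_floor = estimate_noise_floor(stack)

    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    sse = np.full(shape, np.nan)
    defined = np.zeros(shape, dtype=bool)

    peak = stack.intensities.max(axis=3)
    candidates = peak > noise_floor
    if mask is not None:
        candidates &= mask

    te = stack.te_ms
    for idx in np.argwhere(candidates):
        sl, r, c = (int(v) for v in idx)
        fit = fit_pixel_decay(stack.intensities[sl, r, c, :], te)
        if fit.defined:
            t2[sl, r, c] = fit.t2_ms
            s0[sl, r, c] = fit.s0
            sse[sl, r, c] = fit.sse
            defined[sl, r, c] = True
    return T2Map(t2_ms=t2, s0=s0, sse=sse, defined=defined, display_clamp_ms=display_clamp_ms)


def compute_t2_average(
    stack: EchoStack,
    te_subset_ms: Sequence[float] = DEFAULT_AVERAGE_TES,
    window: tuple[float, float] | None = None,
) -> T2AverageImage:
    """Average the echo images at the requested echo times, pixel by pixel.

    Each requested TE must match a stack echo time to within
    ``TE_MATCH_TOL_MS``; otherwise a ValueError lists the available TEs.
    The optional display window is stored for rendering and never applied
    to the stored values.
    """
    indices = []
    for te in te_subset_ms:
        hits = np.nonzero(np.abs(stack.te_ms - te) <= TE_MATCH_TOL_MS)[0]
        if hits.size == 0:
            raise ValueError(
                f"echo time {te} ms not present in stack; available: {stack.te_ms.tolist()}"
            )
        indices.append(int(hits[0]))
    values = stack.intensities[:, :, :, indices].mean(axis=3)
    return T2AverageImage(values=values, te_subset_ms=tuple(float(t) for t in te_subset_ms), window=window)
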