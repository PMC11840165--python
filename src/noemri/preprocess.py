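"""Z-spectrum preprocessing: denoising hook, normalization, B0 and B1 correction.

Pipeline order is fixed as denoise → normalize → B0 correction → fit →
B1 correction → statistics.

* Normalization divides every offset image by the far-off-resonance
  (100 ppm) reference image; voxels with reference signal at or below a
  floor are masked out.
* The B0 map comes from the WASSR series: for each voxel, a second-order
  polynomial is fit locally around the discrete minimum of the narrow
  water-saturation spectrum (5-point window, clipped at grid edges) and the
  parabola's vertex abscissa is the water-center offset.
* B0 correction resamples each spectrum at (nominal offsets + shift) with a
  piecewise-cubic interpolant and regrids onto the nominal axis;
  out-of-range ends are filled with the nearest edge value and flagged.
* B1 correction is first order: fitted pool amplitudes are divided by the
  voxel's relative transmit amplitude (clipped to [0, 1]), mirroring the
  multiplicative saturation-efficiency model of the generator.  Voxels with
  relative B1 below a floor are masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter, map_coordinates

from .zspec import FrequencyAxis, ZSpectrum

__all__ = [
    "B0_FLAG_OK",
    "B0_FLAG_EDGE",
    "B0_FLAG_NONCONVEX",
    "normalize",
    "estimate_b0_wassr",
    "correct_b0",
    "correct_b0_stack",
    "correct_b1",
    "denoise_hook",
    "register_denoiser",
]

logger = logging.getLogger("noemri")

B0_FLAG_OK = 0
B0_FLAG_EDGE = 1  # discrete minimum on the grid edge
B0_FLAG_NONCONVEX = 2  # local parabola opened downward / vertex outside window


def normalize(zstack: np.ndarray, reference: np.ndarray, signal_floor: float = 1e-6):
    """Normalize raw saturation images by the reference image.

    Parameters
    ----------
    zstack
        Raw signals, shape ``(..., n_offsets)``.
    reference
        Raw unsaturated signal S0, shape ``(...)`` matching the stack's
        leading dimensions.
    signal_floor
        Voxels with reference <= floor are masked (excluded) and logged.

    Returns
    -------
    (z, mask) : normalized stack (0 outside mask) and boolean voxel mask.
    """
    zstack = np.asarray(zstack, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if zstack.shape[:-1] != reference.shape:
        raise ValueError(
            f"stack leading shape {zstack.shape[:-1]} does not match reference {reference.shape}"
        )
    mask = np.isfinite(reference) & (reference > signal_floor)
    n_bad = int(mask.size - mask.sum())
    if n_bad:
        logger.info("normalize: masking %d voxels with reference <= %g", n_bad, signal_floor)
    z = np.zeros_like(zstack)
    z[mask] = zstack[mask] / reference[mask, None]
    return z, mask


def _parabola_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares quadratic fit; returns (vertex_x, curvature a)."""
    a, b, _ = np.polyfit(x, y, 2)
    if a <= 0:
        return np.nan, a
    return -b / (2.0 * a), a


def estimate_b0_wassr(wassr: np.ndarray, axis: FrequencyAxis, window: int = 5):
    """Per-voxel water-center offset from a WASSR series.

    Fits a second-order polynomial to the ``window`` points around the
    discrete spectral minimum (window clipped at the grid edges) and returns
    the parabola's vertex.  Degenerate voxels are flagged:

    * minimum on the grid edge → the edge offset is returned, flag 1;
    * downward-opening local fit, or vertex escaping the window → the
      discrete argmin offset is returned, flag 2.

    Parameters
    ----------
    wassr
        Normalized WASSR spectra, shape ``(..., n_wassr)``.
    axis
        WASSR frequency axis (default −1..+1 ppm in 0.1 ppm steps).

    Returns
    -------
    (b0, flags) : arrays of shape ``(...)``, b0 in ppm.
    """
    w = np.atleast_2d(np.asarray(wassr, dtype=float))
    lead_shape = w.shape[:-1]
    noff = w.shape[-1]
    if noff != axis.n:
        raise ValueError(f"wassr has {noff} offsets but axis has {axis.n}")
    if noff < 3:
        raise ValueError("need at least 3 WASSR points")
    window = min(window, noff)
    flat = w.reshape(-1, noff)
    offs = axis.offsets

    imin = np.argmin(flat, axis=1)
    b0 = np.empty(flat.shape[0])
    flags = np.zeros(flat.shape[0], dtype=np.int8)

    start = np.clip(imin - window // 2, 0, noff - window)
    cols = start[:, None] + np.arange(window)[None, :]
    xw = offs[cols]  # (nvox, window)
    yw = np.take_along_axis(flat, cols, axis=1)

    # vectorized quadratic LS fit per voxel: design centred per-window
    x0 = xw.mean(axis=1, keepdims=True)
    xc = xw - x0
    # normal equations for y = a x^2 + b x + c on centred x
    s1 = xc.sum(axis=1)
    s2 = (xc**2).sum(axis=1)
    s3 = (xc**3).sum(axis=1)
    s4 = (xc**4).sum(axis=1)
    n = float(window)
    sy = yw.sum(axis=1)
    sxy = (xc * yw).sum(axis=1)
    sx2y = (xc**2 * yw).sum(axis=1)
    A = np.stack(
        [
            np.stack([s4, s3, s2], axis=1),
            np.stack([s3, s2, s1], axis=1),
            np.stack([s2, s1, np.full_like(s1, n)], axis=1),
        ],
        axis=1,
    )
    rhs = np.stack([sx2y, sxy, sy], axis=1)
    coef = np.linalg.solve(A, rhs[..., None])[..., 0]  # (nvox, 3): a, b, c
    a, b = coef[:, 0], coef[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = x0[:, 0] - b / (2.0 * a)

    lo = xw[:, 0]
    hi = xw[:, -1]
    edge = (imin == 0) | (imin == noff - 1)
    bad_fit = (a <= 0) | ~np.isfinite(vertex) | (vertex < lo) | (vertex > hi)

    b0 = vertex
    b0[bad_fit] = offs[imin[bad_fit]]
    flags[bad_fit] = B0_FLAG_NONCONVEX
    b0[edge] = offs[imin[edge]]
    flags[edge] = B0_FLAG_EDGE

    if np.asarray(wassr).ndim == 1:
        return float(b0[0]), int(flags[0])
    return b0.reshape(lead_shape), flags.reshape(lead_shape)


def correct_b0(z: ZSpectrum, shift: float) -> tuple[ZSpectrum, np.ndarray]:
    """Shift one spectrum's frequency axis back to nominal.

    Resamples ``Z`` at ``offsets + shift`` with a cubic spline and returns
    the corrected spectrum on the nominal grid, plus a boolean flag vector
    marking offsets that fell outside the sampled range (filled with the
    nearest edge value).
    """
    offs = z.axis.offsets
    half_range = (offs[-1] - offs[0]) / 2.0
    if not np.isfinite(shift) or abs(shift) >= half_range:
        raise ValueError(f"|shift| must be < half the grid range ({half_range} ppm)")
    spline = CubicSpline(offs, z.values, extrapolate=False)
    target = offs + shift
    vals = spline(target)
    out_of_range = ~np.isfinite(vals)
    vals[target < offs[0]] = z.values[0]
    vals[target > offs[-1]] = z.values[-1]
    return ZSpectrum(z.axis, vals, z.reference_signal), out_of_range


def correct_b0_stack(
    zstack: np.ndarray, axis: FrequencyAxis, b0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise B0 correction of a whole stack (uniform grid required).

    Uses cubic-spline resampling along the offset axis (one fractional index
    shift per voxel, constant across offsets on the uniform grid).  Returns
    the corrected stack and a boolean flag array marking edge-filled
    samples.
    """
    zstack = np.asarray(zstack, dtype=float)
    step = np.diff(axis.offsets)
    if not np.allclose(step, step[0]):
        raise ValueError("correct_b0_stack requires a uniform offset grid")
    step = step[0]
    lead_shape = zstack.shape[:-1]
    noff = zstack.shape[-1]
    flat = zstack.reshape(-1, noff)
    shift_idx = (np.asarray(b0, dtype=float).ravel() / step)[:, None]
    rows = np.broadcast_to(np.arange(flat.shape[0])[:, None], flat.shape)
    cols = np.arange(noff)[None, :] + shift_idx
    vals = map_coordinates(flat, [rows, cols], order=3, mode="nearest")
    flagged = (cols < 0) | (cols > noff - 1)
    return vals.reshape(zstack.shape), flagged.reshape(lead_shape + (noff,))


def correct_b1(
    amplitudes: np.ndarray, b1: np.ndarray, nominal: float = 1.0, b1_floor: float = 0.3
):
    """First-order B1 correction of fitted pool amplitudes.

    corrected = measured × nominal / relative_B1, clipped to [0, 1].
    Applied after fitting, not to raw spectra.  Voxels with relative B1
    below ``b1_floor`` are masked (returned mask False) and logged.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    if np.any(~np.isfinite(b1)) or np.any(b1 <= 0):
        raise ValueError("relative B1 must be positive and finite")
    mask = b1 >= b1_floor
    n_bad = int(mask.size - mask.sum())
    if n_bad:
        logger.info("correct_b1: masking %d voxels with B1 < %g", n_bad, b1_floor)
    corrected = np.clip(amplitudes * nominal / b1, 0.0, 1.0)
    return corrected, mask


# ---------------------------------------------------------------------------
# denoising hook

def _denoise_none(zstack: np.ndarray, **_: float) -> np.ndarray:
    return zstack


def _denoise_gaussian(zstack: np.ndarray, sigma_vox: float = 1.0, **_: float) -> np.ndarray:
    """Separable spatial Gaussian smoothing of each offset image."""
    zstack = np.asarray(zstack, dtype=float)
    sig = [sigma_vox] * (zstack.ndim - 1) + [0.0]  # never smooth across offsets
    return gaussian_filter(zstack, sigma=sig)


_DENOISERS = {"none": _denoise_none, "gaussian": _denoise_gaussian}


def register_denoiser(name: str, func) -> None:
    """Register an external denoising plugin (``func(zstack, **kw) -> zstack``)."""
    _DENOISERS[name] = func


def denoise_hook(zstack: np.ndarray, method: str = "none", **kwargs) -> np.ndarray:
    """Apply a named denoiser to a 4D stack prior to normalization.

    Built-ins: ``none`` (identity) and ``gaussian`` (separable spatial
    smoothing per offset image).  More elaborate spatio-spectral filters can
    be plugged in with :func:`register_denoiser`.
    """
    if method not in _DENOISERS:
        raise ValueError(f"unknown denoise method {method!r}; known: {sorted(_DENOISERS)}")
    return _DENOISERS[method](np.asarray(zstack, dtype=float), **kwargs)
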