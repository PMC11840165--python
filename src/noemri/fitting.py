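"""Voxel-wise five-pool Lorentzian decomposition and NOE_MTR.

Each B0-corrected, normalized Z-spectrum is decomposed by bounded nonlinear
least squares into DS, MT, amide, amine and rNOE Lorentzian pools with the
baseline fixed at 1:

    min_θ Σ_Δω [ Z_obs(Δω) − (1 − Σ_i L_i(Δω; θ)) ]²

The classic unconstrained Levenberg–Marquardt update does not honor bounds,
so the bounded analogue (trust-region reflective least squares with an
analytic Jacobian) is used on the identical objective.  Pool centers may
float inside narrow windows around their nominal chemical shifts (MT is
held at −2 ppm); all bounds and initial values live in :class:`FitConfig`
and are recorded with the outputs for provenance.

The far-off-resonance reference point is never part of the residual — it
only normalizes the spectrum.

NOE_MTR is the model-free companion metric
``(S0 − S(−3.5 ppm)) / S0 × 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .zspec import (
    FrequencyAxis,
    FivePoolParams,
    LorentzianPool,
    POOL_NAMES,
    NOMINAL_CENTERS,
    ZSpectrum,
)

__all__ = [
    "PoolFitSpec",
    "FitConfig",
    "FitResult",
    "PoolMaps",
    "fit_voxel",
    "fit_volume",
    "noe_mtr",
    "noe_mtr_map",
]

NOE_OFFSET_PPM = -3.5


@dataclass(frozen=True)
class PoolFitSpec:
    """Initial value and box bounds for one pool's (A, Γ, δ).

    ``a_init=None`` requests the data-driven DS heuristic
    ``0.8 × (1 − min Z)``.  ``d_fixed`` pins the center (removes it from the
    free parameters), used for the broad MT pool whose center is not
    identifiable from a ±5 ppm window.
    """

    a_init: float | None
    a_bounds: tuple[float, float]
    g_init: float
    g_bounds: tuple[float, float]
    d_init: float
    d_bounds: tuple[float, float]
    d_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.a_init is not None and not (
            self.a_bounds[0] <= self.a_init <= self.a_bounds[1]
        ):
            raise ValueError("amplitude init outside bounds")
        if not (self.g_bounds[0] <= self.g_init <= self.g_bounds[1]):
            raise ValueError("width init outside bounds")
        if self.d_fixed is None and not (
            self.d_bounds[0] <= self.d_init <= self.d_bounds[1]
        ):
            raise ValueError("center init outside bounds")


def _default_pools() -> dict[str, PoolFitSpec]:
    return {
        "DS": PoolFitSpec(None, (0.0, 1.0), 2.0, (0.3, 10.0), 0.0, (-0.2, 0.2)),
        "MT": PoolFitSpec(0.1, (0.0, 0.5), 25.0, (10.0, 60.0), -2.0, (-2.0, -2.0), d_fixed=-2.0),
        "amide": PoolFitSpec(0.05, (0.0, 0.3), 1.0, (0.4, 3.0), 3.5, (3.4, 3.6)),
        "amine": PoolFitSpec(0.03, (0.0, 0.3), 1.5, (0.4, 4.0), 2.2, (2.1, 2.3)),
        "rNOE": PoolFitSpec(0.10, (0.0, 0.5), 3.0, (1.0, 5.0), -3.5, (-3.7, -3.3)),
    }


@dataclass(frozen=True)
class FitConfig:
    """Bounds, initial values and solver tolerances for the five-pool fit."""

    pools: dict[str, PoolFitSpec] = field(default_factory=_default_pools)
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 400
    residual_fail_factor: float = 5.0  # QC: fail if residual > factor × median

    def __post_init__(self) -> None:
        if set(self.pools) != set(POOL_NAMES):
            raise ValueError(f"FitConfig must configure exactly pools {POOL_NAMES}")

    def to_dict(self) -> dict:
        return {
            "pools": {k: asdict(v) for k, v in self.pools.items()},
            "ftol": self.ftol,
            "xtol": self.xtol,
            "gtol": self.gtol,
            "max_nfev": self.max_nfev,
            "residual_fail_factor": self.residual_fail_factor,
        }


@dataclass
class FitResult:
    params: FivePoolParams
    residual_norm: float  # sqrt(sum of squared residuals)
    converged: bool
    n_evaluations: int
    initial_residual_norm: float


@dataclass
class PoolMaps:
    """Per-voxel fitted parameters and diagnostics for a volume."""

    amplitudes: dict[str, np.ndarray]
    fwhms: dict[str, np.ndarray]
    centers: dict[str, np.ndarray]
    residual_norm: np.ndarray
    converged: np.ndarray  # bool
    qc_pass: np.ndarray  # bool: converged and residual below threshold
    noe_mtr: np.ndarray  # percent
    mask: np.ndarray
    config: FitConfig


# ---------------------------------------------------------------------------
# parameter packing

def _pack_layout(cfg: FitConfig):
    """Flatten the per-pool specs into (x0 template, bounds, slices)."""
    x0, lo, hi = [], [], []
    layout = []  # (pool, has_free_center, base index)
    for name in POOL_NAMES:
        p = cfg.pools[name]
        base = len(x0)
        x0 += [p.a_init if p.a_init is not None else 0.5, p.g_init]
        lo += [p.a_bounds[0], p.g_bounds[0]]
        hi += [p.a_bounds[1], p.g_bounds[1]]
        free_center = p.d_fixed is None
        if free_center:
            x0.append(p.d_init)
            lo.append(p.d_bounds[0])
            hi.append(p.d_bounds[1])
        layout.append((name, free_center, base))
    return np.array(x0), (np.array(lo), np.array(hi)), layout


def _unpack(x: np.ndarray, layout, cfg: FitConfig) -> FivePoolParams:
    pools = []
    for name, free_center, base in layout:
        a, g = x[base], x[base + 1]
        d = x[base + 2] if free_center else cfg.pools[name].d_fixed
        pools.append(LorentzianPool(name, float(min(max(a, 0.0), 1.0)), float(g), float(d)))
    return FivePoolParams(tuple(pools))


def _residual_and_jac(offsets: np.ndarray, z_obs: np.ndarray, layout, cfg: FitConfig):
    n_par = sum(3 if free else 2 for _, free, _ in layout)

    def residual(x):
        model = np.ones_like(offsets)
        for name, free, base in layout:
            a, g = x[base], x[base + 1]
            d = x[base + 2] if free else cfg.pools[name].d_fixed
            u = g * g / 4.0
            model -= a * u / (u + (offsets - d) ** 2)
        return model - z_obs

    def jac(x):
        J = np.empty((offsets.size, n_par))
        for name, free, base in layout:
            a, g = x[base], x[base + 1]
            d = x[base + 2] if free else cfg.pools[name].d_fixed
            u = g * g / 4.0
            s = (offsets - d) ** 2
            denom = u + s
            J[:, base] = -u / denom  # ∂r/∂A
            J[:, base + 1] = -a * s * (g / 2.0) / denom**2  # ∂r/∂Γ
            if free:
                J[:, base + 2] = -a * u * 2.0 * (offsets - d) / denom**2  # ∂r/∂δ
        return J

    return residual, jac


# ---------------------------------------------------------------------------
# fitting

def fit_voxel(
    z: ZSpectrum | np.ndarray,
    cfg: FitConfig | None = None,
    axis: FrequencyAxis | None = None,
    x0_override: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> FitResult | None:
    """Fit the five-pool model to one normalized, B0-corrected spectrum.

    Returns ``None`` for an all-NaN spectrum (masked voxel).  On solver
    non-convergence the best iterate is still returned, flagged
    ``converged=False``.  ``x0_override`` replaces the packed initial vector
    (expert use: warm starts, truth-initialized fixed-point checks).
    ``exclude`` is a boolean per-offset mask of samples to drop from the
    residual — typically the edge samples flagged by the B0 correction,
    whose values are nearest-edge fills rather than measurements.
    """
    cfg = cfg or FitConfig()
    if isinstance(z, ZSpectrum):
        values, offsets = z.values, z.axis.offsets
    else:
        values = np.asarray(z, dtype=float)
        if axis is None:
            raise ValueError("axis is required when passing a bare array")
        offsets = axis.offsets
    if np.all(np.isnan(values)):
        return None
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        values, offsets = values[keep], offsets[keep]
    if np.any(~np.isfinite(values)):
        raise ValueError("spectrum contains non-finite values (partial NaN)")

    x0, bounds, layout = _pack_layout(cfg)
    if x0_override is not None:
        x0 = np.clip(np.asarray(x0_override, dtype=float), bounds[0], bounds[1])
    elif cfg.pools["DS"].a_init is None:
        # data-driven DS start: most of the deepest dip is direct saturation
        ds_base = layout[0][2]
        lo, hi = cfg.pools["DS"].a_bounds
        x0[ds_base] = np.clip(0.8 * (1.0 - values.min()), lo, hi)

    residual, jac = _residual_and_jac(offsets, values, layout, cfg)
    init_norm = float(np.linalg.norm(residual(x0)))
    sol = least_squares(
        residual,
        x0,
        jac=jac,
        bounds=bounds,
        method="trf",
        ftol=cfg.ftol,
        xtol=cfg.xtol,
        gtol=cfg.gtol,
        max_nfev=cfg.max_nfev,
    )
    return FitResult(
        params=_unpack(sol.x, layout, cfg),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        n_evaluations=int(sol.nfev),
        initial_residual_norm=init_norm,
    )


def fit_volume(
    zstack: np.ndarray,
    axis: FrequencyAxis,
    cfg: FitConfig | None = None,
    mask: np.ndarray | None = None,
    n_jobs: int = 1,
    offset_flags: np.ndarray | None = None,
) -> PoolMaps:
    """Apply :func:`fit_voxel` to every masked voxel of a normalized stack.

    The result is deterministic and independent of ``n_jobs`` — voxels are
    independent problems and outputs are written back in voxel order.
    ``offset_flags`` (same shape as the stack) marks per-voxel samples to
    exclude from the residual (e.g. B0-correction edge fills).  Voxels
    whose residual norm exceeds ``residual_fail_factor`` times the in-mask
    median, or that did not converge, fail QC (``qc_pass`` False) and
    should be excluded from ROI statistics.
    """
    cfg = cfg or FitConfig()
    zstack = np.asarray(zstack, dtype=float)
    lead_shape = zstack.shape[:-1]
    if mask is None:
        mask = np.ones(lead_shape, dtype=bool)
    if mask.shape != lead_shape:
        raise ValueError(f"mask shape {mask.shape} does not match stack {lead_shape}")
    if offset_flags is not None and offset_flags.shape != zstack.shape:
        raise ValueError("offset_flags must match the stack shape")

    flat = zstack.reshape(-1, zstack.shape[-1])
    flags_flat = (
        offset_flags.reshape(-1, zstack.shape[-1]) if offset_flags is not None else None
    )
    idx = np.flatnonzero(mask.ravel())

    def _one(i: int):
        exclude = flags_flat[i] if flags_flat is not None else None
        return fit_voxel(flat[i], cfg, axis=axis, exclude=exclude)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(_one)(i) for i in idx)
    else:
        results = [_one(i) for i in idx]

    amplitudes = {p: np.zeros(lead_shape) for p in POOL_NAMES}
    fwhms = {p: np.zeros(lead_shape) for p in POOL_NAMES}
    centers = {p: np.zeros(lead_shape) for p in POOL_NAMES}
    residual = np.full(lead_shape, np.nan)
    converged = np.zeros(lead_shape, dtype=bool)
    fitted_mask = np.zeros(lead_shape, dtype=bool)

    flat_idx = np.unravel_index(idx, lead_shape)
    for k, res in enumerate(results):
        at = tuple(ax[k] for ax in flat_idx)
        if res is None:
            continue
        fitted_mask[at] = True
        for pool in res.params.pools:
            amplitudes[pool.name][at] = pool.amplitude
            fwhms[pool.name][at] = pool.fwhm
            centers[pool.name][at] = pool.center
        residual[at] = res.residual_norm
        converged[at] = res.converged

    med = np.nanmedian(residual[fitted_mask]) if fitted_mask.any() else np.nan
    qc = fitted_mask & converged
    if np.isfinite(med) and med > 0:
        qc &= residual <= cfg.residual_fail_factor * med

    return PoolMaps(
        amplitudes=amplitudes,
        fwhms=fwhms,
        centers=centers,
        residual_norm=residual,
        converged=converged,
        qc_pass=qc,
        noe_mtr=noe_mtr_map(zstack, axis, mask=fitted_mask),
        mask=fitted_mask,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# NOE_MTR

def noe_mtr(s0, s_m35):
    """Magnetization-transfer-ratio metric (S0 − S(−3.5 ppm)) / S0 × 100.

    ``s0`` is the far-off-resonance (100 ppm) signal.  Vectorized; voxels
    with s0 ≤ 0 come back NaN (masked).
    """
    s0 = np.asarray(s0, dtype=float)
    s_m35 = np.asarray(s_m35, dtype=float)
    out = np.full(np.broadcast_shapes(s0.shape, s_m35.shape), np.nan)
    valid = s0 > 0
    out[valid] = (np.broadcast_to(s0, out.shape)[valid] - np.broadcast_to(s_m35, out.shape)[valid]) / np.broadcast_to(s0, out.shape)[valid] * 100.0
    return out if out.ndim else float(out)


def noe_mtr_map(
    zstack: np.ndarray, axis: FrequencyAxis, mask: np.ndarray | None = None
) -> np.ndarray:
    """NOE_MTR from a normalized stack (S0 ≡ 1 after normalization).

    The −3.5 ppm sample is taken directly when the offset is on the grid
    and by cubic interpolation otherwise (the default 0.2 ppm grid brackets
    −3.5 between −3.6 and −3.4).
    """
    zstack = np.asarray(zstack, dtype=float)
    offs = axis.offsets
    hit = np.flatnonzero(np.isclose(offs, NOE_OFFSET_PPM))
    if hit.size:
        z35 = zstack[..., int(hit[0])]
    else:
        flat = zstack.reshape(-1, offs.size)
        z35 = CubicSpline(offs, flat, axis=1)(NOE_OFFSET_PPM).reshape(zstack.shape[:-1])
    out = noe_mtr(np.ones_like(z35), z35)
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out
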