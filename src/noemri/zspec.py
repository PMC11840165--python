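"""Z-spectrum data model and the five-pool Lorentzian forward model.

A Z-spectrum is the normalized water signal ``Z(Δω) = M_Z(Δω) / M_Z0`` as a
function of the saturation offset Δω (ppm from water).  Saturation-transfer
effects — direct water saturation (DS), semi-solid magnetization transfer
(MT), amide (APT) and amine proton exchange, and the relayed nuclear
Overhauser effect (rNOE) — each carve a Lorentzian-shaped dip out of the
spectrum.  The forward model used throughout this package is

    Z(Δω) = Z_Base − Σ_i L_i(Δω),      Z_Base ≡ 1
    L_i(Δω) = A_i · (Γ_i²/4) / (Γ_i²/4 + (Δω − δ_i)²)

with amplitude ``A_i`` (dimensionless fraction of Z), full width at half
maximum ``Γ_i`` (ppm) and center ``δ_i`` (ppm).  The baseline is held fixed
at 1; normalization against a far-off-resonance (100 ppm) reference
acquisition is what puts measured spectra on this scale.

Spectra are represented as dense vectors on the exact acquisition grid;
there is no continuous-function abstraction, because both the B0 correction
and the fitter operate on the sampled grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POOL_NAMES",
    "NOMINAL_CENTERS",
    "FrequencyAxis",
    "LorentzianPool",
    "FivePoolParams",
    "ZSpectrum",
    "lorentzian",
    "zspectrum_eval",
    "zspectrum_forward",
    "main_axis",
    "wassr_axis",
]

#: canonical pool ordering used everywhere (maps, fitting vectors, tables)
POOL_NAMES: tuple[str, ...] = ("DS", "MT", "amide", "amine", "rNOE")

#: nominal chemical displacements relative to water, ppm
NOMINAL_CENTERS: dict[str, float] = {
    "DS": 0.0,
    "MT": -2.0,
    "amide": 3.5,
    "amine": 2.2,
    "rNOE": -3.5,
}


@dataclass(frozen=True)
class FrequencyAxis:
    """Saturation-offset grid plus the far-off-resonance reference offset.

    Parameters
    ----------
    offsets
        Strictly increasing saturation offsets Δω in ppm relative to water.
    reference_offset
        Offset of the normalization acquisition (default 100 ppm); must not
        be a member of the main grid.
    """

    offsets: np.ndarray
    reference_offset: float = 100.0

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        if offsets.ndim != 1 or offsets.size < 2:
            raise ValueError("offsets must be a 1-D array with >= 2 points")
        if not np.all(np.isfinite(offsets)):
            raise ValueError("offsets must be finite")
        if not np.all(np.diff(offsets) > 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(np.isclose(offsets, self.reference_offset)):
            raise ValueError("reference_offset must not be on the main grid")
        object.__setattr__(self, "offsets", offsets)

    @property
    def n(self) -> int:
        return self.offsets.size

    def index_of(self, offset: float, atol: float = 1e-9) -> int:
        """Index of an offset that lies exactly on the grid."""
        hits = np.flatnonzero(np.isclose(self.offsets, offset, atol=atol))
        if hits.size != 1:
            raise KeyError(f"offset {offset} ppm is not on the grid")
        return int(hits[0])

    def __eq__(self, other: object) -> bool:  # value semantics for tests/IO
        if not isinstance(other, FrequencyAxis):
            return NotImplemented
        return (
            self.offsets.shape == other.offsets.shape
            and np.allclose(self.offsets, other.offsets)
            and np.isclose(self.reference_offset, other.reference_offset)
        )


def main_axis() -> FrequencyAxis:
    """Default acquisition grid: −5..+5 ppm in 0.2 ppm steps (51 points)."""
    return FrequencyAxis(np.round(np.arange(-25, 26) * 0.2, 10), 100.0)


def wassr_axis() -> FrequencyAxis:
    """Default WASSR grid: −1..+1 ppm in 0.1 ppm steps (21 points)."""
    return FrequencyAxis(np.round(np.arange(-10, 11) * 0.1, 10), 100.0)


@dataclass(frozen=True)
class LorentzianPool:
    """One saturation-transfer pool: a single Lorentzian line."""

    name: str
    amplitude: float
    fwhm: float
    center: float

    def __post_init__(self) -> None:
        if self.name not in POOL_NAMES:
            raise ValueError(f"unknown pool name {self.name!r}; expected one of {POOL_NAMES}")
        if not np.all(np.isfinite([self.amplitude, self.fwhm, self.center])):
            raise ValueError("pool parameters must be finite")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"amplitude must be in [0, 1], got {self.amplitude}")
        if self.fwhm <= 0.0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")


@dataclass(frozen=True)
class FivePoolParams:
    """Exactly five pools, one per name, with the baseline fixed at 1.

    ``z_base`` is not a free parameter of the model; it exists as a field
    only so serialized parameter sets are explicit about the convention.
    """

    pools: tuple[LorentzianPool, ...]
    z_base: float = 1.0

    def __post_init__(self) -> None:
        names = tuple(p.name for p in self.pools)
        if sorted(names) != sorted(POOL_NAMES):
            raise ValueError(f"need exactly one pool per name {POOL_NAMES}, got {names}")
        if self.z_base != 1.0:
            raise ValueError("z_base is fixed at 1 in this model")
        # canonical order
        by_name = {p.name: p for p in self.pools}
        object.__setattr__(self, "pools", tuple(by_name[n] for n in POOL_NAMES))

    def __getitem__(self, name: str) -> LorentzianPool:
        return self.pools[POOL_NAMES.index(name)]

    @property
    def amplitudes(self) -> dict[str, float]:
        return {p.name: p.amplitude for p in self.pools}

    @classmethod
    def from_dicts(
        cls,
        amplitudes: dict[str, float],
        fwhms: dict[str, float],
        centers: dict[str, float] | None = None,
    ) -> "FivePoolParams":
        centers = {**NOMINAL_CENTERS, **(centers or {})}
        return cls(
            tuple(
                LorentzianPool(n, amplitudes[n], fwhms[n], centers[n])
                for n in POOL_NAMES
            )
        )


@dataclass
class ZSpectrum:
    """A sampled (normalized) Z-spectrum on a fixed offset grid."""

    axis: FrequencyAxis
    values: np.ndarray
    reference_signal: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.axis.n,):
            raise ValueError(
                f"values shape {values.shape} does not match axis ({self.axis.n},)"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("Z-spectrum values must be finite")
        self.values = values


def lorentzian(delta_omega, pool: LorentzianPool):
    """Evaluate a single Lorentzian line L_i(Δω).

    Peak value equals the amplitude at Δω = δ_i; half maximum is reached at
    Δω = δ_i ± Γ_i/2.  Vectorized over ``delta_omega``.
    """
    x = np.asarray(delta_omega, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("delta_omega must be finite")
    u = pool.fwhm**2 / 4.0
    out = pool.amplitude * u / (u + (x - pool.center) ** 2)
    return out if out.ndim else float(out)


def zspectrum_eval(delta_omega, params: FivePoolParams):
    """Evaluate Z(Δω) = 1 − Σ_i L_i(Δω) at arbitrary offsets."""
    x = np.asarray(delta_omega, dtype=float)
    deficit = np.zeros_like(x)
    for pool in params.pools:
        deficit += lorentzian(x, pool)
    out = params.z_base - deficit
    return out if out.ndim else float(out)


def zspectrum_forward(axis: FrequencyAxis, params: FivePoolParams) -> ZSpectrum:
    """Forward-model a Z-spectrum on an acquisition grid.

    The 100 ppm reference is treated as fully unsaturated (model value 1):
    the MT tail at the reference offset is ignored because the reference is
    used purely for normalization.  Warns (does not fail) if the summed pool
    deficit exceeds the baseline anywhere — a nonphysical parameter set.
    """
    deficit = np.zeros(axis.n)
    for pool in params.pools:
        deficit += lorentzian(axis.offsets, pool)
    if np.any(deficit > params.z_base):
        warnings.warn(
            "summed Lorentzian deficit exceeds the baseline at some offsets "
            "(nonphysical parameter set)",
            stacklevel=2,
        )
    return ZSpectrum(axis, params.z_base - deficit, reference_signal=1.0)
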