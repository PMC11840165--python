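"""Digital brain phantom: multi-subject volumetric Z-spectrum simulation.

The generator produces the kind of dataset the analysis pipeline expects
from a 7T NOE/CEST exam of a multiple-sclerosis (MS) cohort and healthy
controls: a thin 3D slab of Z-spectra on the −5..+5 ppm grid plus a 100 ppm
reference image, a low-power WASSR series (−1..+1 ppm) for B0 mapping,
smooth B0 and relative-B1 field maps, a T1 map, tissue labels
(WM / GM / CSF plus manually-segmented-style lesion masks), and per-subject
demographics (group, age, sex, disease duration, lesion volume).

Ground truth — per-voxel pool parameters, field maps, labels — is stored
losslessly alongside the simulated data so parameter-recovery tests can use
the generator as their oracle.

Statistical structure
---------------------
Tissue pool amplitudes are drawn hierarchically: a subject-level tissue mean
from a group×tissue prior, then small voxel-level jitter.  The priors encode
the published group means/SDs for the pools where they are reported
(rNOE, amine, DS amplitudes and T1 for control WM, MS normal-appearing WM,
and lesions; rNOE for GM).  MT and amide amplitudes are not reported
numerically anywhere and their priors are this package's own choices,
tunable through :class:`TissueParamPrior`.

Field and noise model
---------------------
* B0: smooth low-order polynomial field, bounded by ``b0_max_ppm``; a
  voxel's spectrum is the forward model evaluated at ``Δω − B0`` (the water
  dip sits at +B0 on the nominal grid).
* B1: smooth relative transmit-field map in ``b1_range``; pool amplitudes
  are multiplied by the voxel's relative B1 before spectrum synthesis
  (first-order saturation-efficiency model).
* Noise: additive Gaussian on the normalized Z values (high-SNR regime),
  default SD 0.002; truncated-normal draws use resampling, not clipping,
  so the configured means are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .zspec import (
    FrequencyAxis,
    FivePoolParams,
    POOL_NAMES,
    NOMINAL_CENTERS,
    main_axis,
    wassr_axis,
)

__all__ = [
    "TISSUES",
    "LABEL_CODES",
    "POOL_FWHMS",
    "TissueParamPrior",
    "DEFAULT_PRIORS",
    "SubjectRecord",
    "PhantomSpec",
    "PhantomVolume",
    "draw_subject",
    "draw_tissue_means",
    "apply_duration_coupling",
    "build_volume",
    "simulate_cohort",
]

TISSUES = ("WM", "GM", "CSF", "lesion")

#: integer label codes shared with the segmentation stage
LABEL_CODES = {"background": 0, "GM": 1, "WM": 2, "CSF": 3, "lesion": 4}

#: generative pool linewidths, ppm (fixed within a phantom)
POOL_FWHMS = {"DS": 2.0, "MT": 25.0, "amide": 1.0, "amine": 1.5, "rNOE": 3.0}

#: unsaturated signal level per tissue, arbitrary units (reference image)
_S0_LEVELS = {"background": 0.0, "GM": 1000.0, "WM": 900.0, "CSF": 1200.0, "lesion": 950.0}


@dataclass(frozen=True)
class TissueParamPrior:
    """Group-specific prior for one tissue: pool amplitude means/SDs and T1."""

    tissue: str
    group: str
    amp_mean: dict[str, float]
    amp_sd: dict[str, float]
    t1_mean: float  # ms
    t1_sd: float  # ms

    def __post_init__(self) -> None:
        for d in (self.amp_mean, self.amp_sd):
            if set(d) != set(POOL_NAMES):
                raise ValueError(f"priors must cover pools {POOL_NAMES}")
            if any(v < 0 for v in d.values()):
                raise ValueError("prior means/SDs must be nonnegative")
        if self.t1_mean < 0 or self.t1_sd < 0:
            raise ValueError("T1 prior must be nonnegative")


def _prior(tissue, group, ds, mt, amide, amine, rnoe, t1):
    return TissueParamPrior(
        tissue,
        group,
        amp_mean={"DS": ds[0], "MT": mt[0], "amide": amide[0], "amine": amine[0], "rNOE": rnoe[0]},
        amp_sd={"DS": ds[1], "MT": mt[1], "amide": amide[1], "amine": amine[1], "rNOE": rnoe[1]},
        t1_mean=t1[0],
        t1_sd=t1[1],
    )


# Published group means ± SD where available (rNOE/amine/DS amplitudes and
# T1 for WM, NAWM and lesions; GM rNOE).  MT and amide amplitudes, GM DS/T1
# and all CSF values are package choices (documented in docs/methods.md).
DEFAULT_PRIORS: dict[tuple[str, str], TissueParamPrior] = {
    ("control", "WM"): _prior(
        "WM", "control",
        ds=(0.655, 0.021), mt=(0.10, 0.02), amide=(0.05, 0.01),
        amine=(0.039, 0.007), rnoe=(0.114, 0.014), t1=(1154.6, 31.7),
    ),
    ("MS", "WM"): _prior(  # normal-appearing white matter
        "WM", "MS",
        ds=(0.660, 0.009), mt=(0.10, 0.02), amide=(0.05, 0.01),
        amine=(0.033, 0.006), rnoe=(0.101, 0.007), t1=(1197.3, 31.8),
    ),
    ("control", "GM"): _prior(
        "GM", "control",
        ds=(0.620, 0.020), mt=(0.07, 0.015), amide=(0.05, 0.01),
        amine=(0.037, 0.006), rnoe=(0.094, 0.012), t1=(1950.0, 60.0),
    ),
    ("MS", "GM"): _prior(  # normal-appearing grey matter
        "GM", "MS",
        ds=(0.622, 0.020), mt=(0.07, 0.015), amide=(0.05, 0.01),
        amine=(0.035, 0.006), rnoe=(0.085, 0.012), t1=(1960.0, 60.0),
    ),
    ("MS", "lesion"): _prior(
        "lesion", "MS",
        ds=(0.703, 0.040), mt=(0.08, 0.02), amide=(0.05, 0.01),
        amine=(0.032, 0.007), rnoe=(0.076, 0.019), t1=(1600.7, 269.7),
    ),
    ("control", "CSF"): _prior(
        "CSF", "control",
        ds=(0.850, 0.030), mt=(0.005, 0.003), amide=(0.003, 0.002),
        amine=(0.005, 0.003), rnoe=(0.005, 0.003), t1=(3500.0, 250.0),
    ),
    ("MS", "CSF"): _prior(
        "CSF", "MS",
        ds=(0.850, 0.030), mt=(0.005, 0.003), amide=(0.003, 0.002),
        amine=(0.005, 0.003), rnoe=(0.005, 0.003), t1=(3500.0, 250.0),
    ),
}


#: Published cohort group means ± SD that the phantom priors emulate,
#: keyed (tissue, contrast) → {group: (mean, sd)}.  Amplitudes are
#: dimensionless, T1 in ms, NOE_MTR in percent.  These printed summaries
#: are inputs to worked percent-change examples and benchmarks.
STUDY_GROUP_MEANS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("whole_brain", "rNOE"): {"control": (0.099, 0.012), "MS": (0.083, 0.009)},
    ("whole_brain", "amine"): {"control": (0.037, 0.006), "MS": (0.031, 0.004)},
    ("GM", "rNOE"): {"control": (0.094, 0.012), "MS": (0.085, 0.012)},
    ("WM", "rNOE"): {"control WM": (0.114, 0.014), "NAWM": (0.101, 0.007), "lesion": (0.076, 0.019)},
    ("WM", "amine"): {"control WM": (0.039, 0.007), "NAWM": (0.033, 0.006), "lesion": (0.032, 0.007)},
    ("WM", "DS"): {"control WM": (0.655, 0.021), "NAWM": (0.660, 0.009), "lesion": (0.703, 0.040)},
    ("WM", "T1"): {"control WM": (1154.6, 31.7), "NAWM": (1197.3, 31.8), "lesion": (1600.7, 269.7)},
    ("WM", "NOE_MTR"): {"control WM": (35.93, 1.43), "NAWM": (35.49, 1.25), "lesion": (28.97, 3.33)},
}


@dataclass(frozen=True)
class SubjectRecord:
    """Demographic/clinical covariates for one subject."""

    subject_id: str
    group: str  # "control" or "MS"
    age: float  # years
    sex: str  # "F" or "M"
    disease_duration: float = 0.0  # years; 0 for controls
    lesion_volume: float = 0.0  # cm^3 within the slab; 0 for controls

    def __post_init__(self) -> None:
        if self.group not in ("control", "MS"):
            raise ValueError(f"group must be 'control' or 'MS', got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.group == "control" and (self.disease_duration != 0 or self.lesion_volume != 0):
            raise ValueError("controls must have zero duration and lesion volume")


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that determines a simulated cohort, including the seed.

    Defaults encode the emulated study: 15 MS / 10 control subjects; MS age
    43.7 ± 14.7 y on 21–70, control 40.9 ± 16.9 y on 23–71; MS sex ratio
    10F:5M (controls 5F:5M); disease duration 6.5 ± 6.6 y (truncated at 0);
    in-slab lesion volume 1.2 ± 1.4 cm³ (truncated at 0).  The acquisition
    slab is emulated at desk scale, default 64×64×10 voxels of 1×1×2 mm.
    """

    shape: tuple[int, int, int] = (64, 64, 10)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_ms: int = 15
    n_control: int = 10
    # (mean, sd, low, high) in years
    age_prior: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {"MS": (43.7, 14.7, 21.0, 70.0), "control": (40.9, 16.9, 23.0, 71.0)}
    )
    sex_p_female: dict[str, float] = field(
        default_factory=lambda: {"MS": 10.0 / 15.0, "control": 0.5}
    )
    duration_prior: tuple[float, float] = (6.5, 6.6)  # years, truncated >= 0
    lesion_volume_prior: tuple[float, float] = (1.2, 1.4)  # cm^3, truncated >= 0
    max_lesions: int = 3
    b0_max_ppm: float = 0.3
    b1_range: tuple[float, float] = (0.7, 1.15)
    noise_sd: float = 0.002  # additive Gaussian on normalized Z
    jitter_sd: float = 0.003  # voxel-level pool-amplitude jitter
    t1_noise_sd: float = 30.0  # ms, voxel-level T1 noise
    wassr_amplitude: float = 0.85
    wassr_fwhm: float = 0.5  # ppm, low-power direct-saturation linewidth
    duration_coupling: bool = False
    lesion_t1_slope: float = 24.34  # ms per year of disease duration
    priors: dict[tuple[str, str], TissueParamPrior] = field(
        default_factory=lambda: dict(DEFAULT_PRIORS)
    )
    seed: int = 0

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class PhantomVolume:
    """One subject's simulated acquisition plus its lossless ground truth."""

    subject: SubjectRecord
    axis: FrequencyAxis
    wassr_axis: FrequencyAxis
    labels: np.ndarray  # (nx, ny, nz) int, LABEL_CODES
    true_amplitudes: dict[str, np.ndarray]  # pool -> (nx, ny, nz), pre-B1
    pool_fwhms: dict[str, float]
    pool_centers: dict[str, float]
    true_b0: np.ndarray  # ppm
    true_b1: np.ndarray  # relative
    t1: np.ndarray  # ms
    zstack: np.ndarray  # (nx, ny, nz, n_offsets) raw signal
    reference: np.ndarray  # (nx, ny, nz) raw S0
    wassr: np.ndarray  # (nx, ny, nz, n_wassr) normalized
    tissue_means: dict[str, dict[str, float]]  # tissue -> pool/t1 subject means

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def true_params_at(self, idx: tuple[int, int, int]) -> FivePoolParams:
        amps = {p: float(self.true_amplitudes[p][idx]) for p in POOL_NAMES}
        return FivePoolParams.from_dicts(amps, self.pool_fwhms, self.pool_centers)


# ---------------------------------------------------------------------------
# random draws

def _trunc_normal(rng: np.random.Generator, mean, sd, low=-np.inf, high=np.inf, size=None):
    """Truncated normal by resampling (keeps the configured mean shape)."""
    if sd == 0:
        out = np.full(size if size is not None else (), float(mean))
        return float(out) if size is None else out
    n = 1 if size is None else int(np.prod(size))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        ok = draw[(draw >= low) & (draw <= high)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return float(out[0]) if size is None else out.reshape(size)


def draw_subject(
    spec: PhantomSpec, group: str, rng: np.random.Generator, subject_id: str | None = None
) -> SubjectRecord:
    """Draw one subject's demographics from the cohort priors.

    Ages are truncated-normal inside the group's reported range; disease
    duration and in-slab lesion volume are truncated at zero and identically
    zero for controls.
    """
    mean, sd, lo, hi = spec.age_prior[group]
    age = _trunc_normal(rng, mean, sd, lo, hi)
    sex = "F" if rng.random() < spec.sex_p_female[group] else "M"
    if group == "MS":
        duration = _trunc_normal(rng, *spec.duration_prior, low=0.0)
        lesion_volume = _trunc_normal(rng, *spec.lesion_volume_prior, low=0.0)
    else:
        duration = 0.0
        lesion_volume = 0.0
    return SubjectRecord(
        subject_id=subject_id or f"{group}-anon",
        group=group,
        age=age,
        sex=sex,
        disease_duration=duration,
        lesion_volume=lesion_volume,
    )


def apply_duration_coupling(
    spec: PhantomSpec, subject: SubjectRecord
) -> dict[tuple[str, str], TissueParamPrior]:
    """Optionally couple lesion T1 to disease duration.

    When ``spec.duration_coupling`` is enabled, the lesion T1 prior mean is
    raised by ``lesion_t1_slope × disease_duration`` (ms), emulating the
    observed positive lesion-T1/duration relationship.  Off by default; the
    priors are returned unchanged then, or for zero duration.
    """
    priors = dict(spec.priors)
    if not spec.duration_coupling or subject.disease_duration == 0:
        return priors
    key = (subject.group, "lesion")
    if key in priors:
        p = priors[key]
        priors[key] = replace(
            p, t1_mean=p.t1_mean + spec.lesion_t1_slope * subject.disease_duration
        )
    return priors


def draw_tissue_means(
    spec: PhantomSpec, subject: SubjectRecord, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Subject-level tissue means: one draw per tissue from the group prior.

    Returns ``{tissue: {"DS": ..., ..., "rNOE": ..., "T1": ...}}``.
    Amplitudes are truncated to [0, 1], T1 to nonnegative.
    """
    priors = apply_duration_coupling(spec, subject)
    means: dict[str, dict[str, float]] = {}
    for tissue in TISSUES:
        key = (subject.group, tissue)
        if key not in priors:
            continue  # e.g. no lesion prior for controls
        prior = priors[key]
        draw = {
            pool: _trunc_normal(rng, prior.amp_mean[pool], prior.amp_sd[pool], 0.0, 1.0)
            for pool in POOL_NAMES
        }
        draw["T1"] = _trunc_normal(rng, prior.t1_mean, prior.t1_sd, 0.0)
        means[tissue] = draw
    return means


# ---------------------------------------------------------------------------
# geometry

def _label_geometry(spec: PhantomSpec) -> np.ndarray:
    """Concentric slab anatomy: WM core, GM ring, CSF ring, background."""
    nx, ny, nz = spec.shape
    r = min(nx, ny)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    rho = np.hypot(xx - (nx - 1) / 2.0, yy - (ny - 1) / 2.0)
    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[rho < 0.44 * r] = LABEL_CODES["CSF"]
    plane[rho < 0.38 * r] = LABEL_CODES["GM"]
    plane[rho < 0.28 * r] = LABEL_CODES["WM"]
    return np.repeat(plane[:, :, None], nz, axis=2)


def _place_lesions(
    labels: np.ndarray, spec: PhantomSpec, subject: SubjectRecord, rng: np.random.Generator
) -> np.ndarray:
    """Carve quasi-spherical lesions into WM matching the drawn volume.

    The lesion voxel count is exactly ``round(volume / voxel_volume)``:
    up to ``max_lesions`` seeds are placed uniformly inside WM and each
    lesion takes the WM voxels nearest (in mm) to its seed.
    """
    n_target = int(round(subject.lesion_volume / spec.voxel_volume_cm3))
    if n_target == 0:
        return labels
    wm = np.argwhere(labels == LABEL_CODES["WM"])
    if n_target > wm.shape[0]:
        need = math.ceil(n_target / max(labels.shape[2], 1))
        raise ValueError(
            f"grid too small: lesion of {subject.lesion_volume:.2f} cm^3 needs "
            f"{n_target} voxels but WM has only {wm.shape[0]}; increase the grid "
            f"(>= {need} WM voxels per slice) or voxel size"
        )
    labels = labels.copy()
    n_lesions = int(rng.integers(1, spec.max_lesions + 1))
    # random composition of the target count over lesions
    splits = np.sort(rng.choice(np.arange(1, n_target), size=n_lesions - 1, replace=False)) if n_lesions > 1 and n_target > n_lesions else np.array([], dtype=int)
    counts = np.diff(np.concatenate(([0], splits, [n_target])))
    scale = np.asarray(spec.voxel_size_mm)
    for count in counts:
        if count <= 0:
            continue
        wm_now = np.argwhere(labels == LABEL_CODES["WM"])
        if count > wm_now.shape[0]:
            count = wm_now.shape[0]
        seed_vox = wm_now[rng.integers(wm_now.shape[0])]
        d = np.linalg.norm((wm_now - seed_vox) * scale, axis=1)
        take = wm_now[np.argsort(d, kind="stable")[:count]]
        labels[take[:, 0], take[:, 1], take[:, 2]] = LABEL_CODES["lesion"]
    return labels


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """Random smooth low-order polynomial field, scaled to max |value| = 1."""
    nx, ny, nz = shape
    ax = [np.linspace(-1, 1, n) if n > 1 else np.zeros(1) for n in (nx, ny, nz)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    c = rng.normal(size=10)
    f = (
        c[0] + c[1] * X + c[2] * Y + c[3] * Z
        + c[4] * X * Y + c[5] * X * Z + c[6] * Y * Z
        + c[7] * X**2 + c[8] * Y**2 + c[9] * Z**2
    )
    m = np.max(np.abs(f))
    return f / m if m > 0 else f


# ---------------------------------------------------------------------------
# volume synthesis

def build_volume(
    spec: PhantomSpec, subject: SubjectRecord, rng: np.random.Generator
) -> PhantomVolume:
    """Simulate one subject's full acquisition with stored ground truth.

    Per-voxel pool amplitudes are the subject's tissue draw plus Gaussian
    voxel jitter (clipped to [0, 1]).  The raw Z-stack is the five-pool
    forward model evaluated at ``Δω − B0(voxel)`` with amplitudes scaled by
    the voxel's relative B1, plus additive Gaussian noise on normalized Z,
    then multiplied by the tissue's unsaturated signal level (the reference
    image).  The WASSR stack is a narrow direct-saturation line with the
    same B0 shift, already normalized.
    """
    axis = main_axis()
    waxis = wassr_axis()
    nx, ny, nz = spec.shape

    labels = _label_geometry(spec)
    if subject.group == "MS":
        labels = _place_lesions(labels, spec, subject, rng)
    brain = labels > 0

    tissue_means = draw_tissue_means(spec, subject, rng)

    # per-voxel ground-truth amplitude and T1 maps
    amps = {p: np.zeros(spec.shape) for p in POOL_NAMES}
    t1 = np.zeros(spec.shape)
    s0 = np.zeros(spec.shape)
    code_to_tissue = {LABEL_CODES[t]: t for t in ("GM", "WM", "CSF", "lesion")}
    for code, tissue in code_to_tissue.items():
        mask = labels == code
        n_vox = int(mask.sum())
        if n_vox == 0 or tissue not in tissue_means:
            continue
        mm = tissue_means[tissue]
        for p in POOL_NAMES:
            jitter = rng.normal(0.0, spec.jitter_sd, size=n_vox) if spec.jitter_sd > 0 else 0.0
            amps[p][mask] = np.clip(mm[p] + jitter, 0.0, 1.0)
        t1_noise = rng.normal(0.0, spec.t1_noise_sd, size=n_vox) if spec.t1_noise_sd > 0 else 0.0
        t1[mask] = np.maximum(mm["T1"] + t1_noise, 0.0)
        s0[mask] = _S0_LEVELS[tissue]

    b0 = _smooth_field(rng, spec.shape) * spec.b0_max_ppm
    lo, hi = spec.b1_range
    b1 = lo + (hi - lo) * (_smooth_field(rng, spec.shape) + 1.0) / 2.0

    # spectrum synthesis, vectorized over brain voxels
    flat = brain.ravel()
    idx = np.flatnonzero(flat)
    b0f = b0.ravel()[idx]
    b1f = b1.ravel()[idx]
    off = axis.offsets[None, :]  # (1, n_off)
    zvals = np.ones((idx.size, axis.n))
    for p in POOL_NAMES:
        a = amps[p].ravel()[idx] * b1f
        u = POOL_FWHMS[p] ** 2 / 4.0
        zvals -= a[:, None] * u / (u + (off - b0f[:, None] - NOMINAL_CENTERS[p]) ** 2)
    if spec.noise_sd > 0:
        zvals += rng.normal(0.0, spec.noise_sd, size=zvals.shape)

    zstack = np.zeros(spec.shape + (axis.n,))
    zstack.reshape(-1, axis.n)[idx] = zvals * s0.ravel()[idx, None]

    # WASSR: low-power narrow DS line at the voxel's water center
    woff = waxis.offsets[None, :]
    uw = spec.wassr_fwhm**2 / 4.0
    wvals = 1.0 - spec.wassr_amplitude * uw / (uw + (woff - b0f[:, None]) ** 2)
    if spec.noise_sd > 0:
        wvals += rng.normal(0.0, spec.noise_sd, size=wvals.shape)
    wassr = np.zeros(spec.shape + (waxis.n,))
    wassr.reshape(-1, waxis.n)[idx] = wvals

    return PhantomVolume(
        subject=subject,
        axis=axis,
        wassr_axis=waxis,
        labels=labels,
        true_amplitudes=amps,
        pool_fwhms=dict(POOL_FWHMS),
        pool_centers=dict(NOMINAL_CENTERS),
        true_b0=b0,
        true_b1=b1,
        t1=t1,
        zstack=zstack,
        reference=s0,
        wassr=wassr,
        tissue_means=tissue_means,
    )


def simulate_cohort(spec: PhantomSpec) -> Iterator[PhantomVolume]:
    """Yield one :class:`PhantomVolume` per subject, fully seed-determined.

    Each subject gets an independent child stream of ``spec.seed`` so the
    cohort is reproducible subject-by-subject and as a whole.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_ms + spec.n_control)
    groups = ["MS"] * spec.n_ms + ["control"] * spec.n_control
    counters = {"MS": 0, "control": 0}
    for child, group in zip(children, groups):
        rng = np.random.default_rng(child)
        counters[group] += 1
        subject = draw_subject(spec, group, rng, subject_id=f"{group}-{counters[group]:02d}")
        yield build_volume(spec, subject, rng)
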