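"""Shared fixtures: parameter sets and small phantoms built at test time."""

import numpy as np
import pytest

from noemri.phantom import POOL_FWHMS, PhantomSpec, build_volume, draw_subject
from noemri.zspec import FivePoolParams


def wm_amplitudes() -> dict[str, float]:
    """Healthy-WM default pool amplitudes (the control-WM prior means)."""
    return {"DS": 0.655, "MT": 0.10, "amide": 0.05, "amine": 0.039, "rNOE": 0.114}


@pytest.fixture(scope="session")
def wm_params() -> FivePoolParams:
    return FivePoolParams.from_dicts(wm_amplitudes(), POOL_FWHMS)


def desk_spec(**overrides) -> PhantomSpec:
    """Desk-scale slab: 24×24×4 voxels of 2.5×2.5×5 mm (20 mm effective slab)."""
    defaults = dict(shape=(24, 24, 4), voxel_size_mm=(2.5, 2.5, 5.0), seed=7)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def noiseless_vol():
    """One MS subject, B0/B1 fields on, zero noise/jitter — recovery oracle."""
    spec = desk_spec(noise_sd=0.0, jitter_sd=0.0, t1_noise_sd=0.0)
    rng = np.random.default_rng(11)
    subject = draw_subject(spec, "MS", rng, "MS-01")
    return spec, build_volume(spec, subject, rng)


@pytest.fixture(scope="session")
def noisy_flat_field_vol():
    """One MS subject with default noise/jitter but flat B0/B1 (fit-stage oracle)."""
    spec = desk_spec(b0_max_ppm=0.0, b1_range=(1.0, 1.0))
    rng = np.random.default_rng(13)
    subject = draw_subject(spec, "MS", rng, "MS-02")
    return spec, build_volume(spec, subject, rng)
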