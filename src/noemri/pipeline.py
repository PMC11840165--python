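"""In-memory pipeline tying the stages together.

Order of operations is fixed: denoise → normalize → B0 estimation and
correction → five-pool fit → B1 correction of fitted amplitudes →
segmentation → ROI aggregation → group statistics.  The CLI is a thin shell
over these functions; tests and the phantom-recovery checks call them
directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FitConfig, PoolMaps, fit_volume
from .phantom import PhantomSpec, PhantomVolume, SubjectRecord, simulate_cohort
from .preprocess import (
    correct_b0_stack,
    correct_b1,
    denoise_hook,
    estimate_b0_wassr,
    normalize,
)
from .roi_stats import TissueMask, cohort_stats, segment_from_t1, subject_roi_table
from .zspec import FrequencyAxis, POOL_NAMES

__all__ = [
    "PreprocessOptions",
    "SubjectAnalysis",
    "analyze_subject",
    "analyze_phantom_volume",
    "run_cohort",
]

logger = logging.getLogger("noemri")


@dataclass(frozen=True)
class PreprocessOptions:
    denoise: str = "none"
    denoise_sigma_vox: float = 1.0
    b1_floor: float = 0.3
    t1_thresholds: tuple[float, float] = (1450.0, 2600.0)


@dataclass
class SubjectAnalysis:
    """Everything the pipeline derives for one subject."""

    subject: SubjectRecord
    pool_maps: PoolMaps
    corrected_amplitudes: dict[str, np.ndarray]
    b0: np.ndarray
    b0_flags: np.ndarray
    tissue_mask: TissueMask
    qc_mask: np.ndarray
    roi_table: pd.DataFrame


def analyze_subject(
    subject: SubjectRecord,
    zstack_raw: np.ndarray,
    reference: np.ndarray,
    axis: FrequencyAxis,
    wassr: np.ndarray,
    wassr_axis: FrequencyAxis,
    b1: np.ndarray,
    t1: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    fit_config: FitConfig | None = None,
    options: PreprocessOptions = PreprocessOptions(),
    n_jobs: int = 1,
) -> SubjectAnalysis:
    """Run the per-subject chain from raw stack to ROI table."""
    stack = denoise_hook(zstack_raw, options.denoise, sigma_vox=options.denoise_sigma_vox)
    z, valid = normalize(stack, reference)
    b0, b0_flags = estimate_b0_wassr(wassr, wassr_axis)
    b0 = np.where(valid, b0, 0.0)
    z_corr, edge_flags = correct_b0_stack(z, axis, b0)

    maps = fit_volume(
        z_corr, axis, fit_config, mask=valid, n_jobs=n_jobs, offset_flags=edge_flags
    )

    corrected = {}
    b1_mask = None
    for pool in POOL_NAMES:
        corrected[pool], b1_mask = correct_b1(
            maps.amplitudes[pool], b1, b1_floor=options.b1_floor
        )

    tissue_mask = segment_from_t1(
        t1, thresholds=options.t1_thresholds, brain_mask=valid, lesion_mask=lesion_mask
    )
    qc = maps.qc_pass & b1_mask

    contrast_maps = {**corrected, "T1": np.asarray(t1, float), "NOE_MTR": maps.noe_mtr}
    roi = subject_roi_table(subject, contrast_maps, tissue_mask, qc_mask=qc)

    return SubjectAnalysis(
        subject=subject,
        pool_maps=maps,
        corrected_amplitudes=corrected,
        b0=b0,
        b0_flags=b0_flags,
        tissue_mask=tissue_mask,
        qc_mask=qc,
        roi_table=roi,
    )


def analyze_phantom_volume(
    vol: PhantomVolume,
    fit_config: FitConfig | None = None,
    options: PreprocessOptions = PreprocessOptions(),
    n_jobs: int = 1,
) -> SubjectAnalysis:
    """Analyze a simulated subject, using its lesion labels as the manual mask."""
    lesion = vol.labels == 4  # LABEL_CODES["lesion"]
    return analyze_subject(
        vol.subject,
        vol.zstack,
        vol.reference,
        vol.axis,
        vol.wassr,
        vol.wassr_axis,
        vol.true_b1,  # B1 maps are pipeline inputs (separately acquired)
        vol.t1,
        lesion_mask=lesion if lesion.any() else None,
        fit_config=fit_config,
        options=options,
        n_jobs=n_jobs,
    )


def run_cohort(
    spec: PhantomSpec,
    fit_config: FitConfig | None = None,
    options: PreprocessOptions = PreprocessOptions(),
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort, analyze every subject, run the group statistics.

    Returns ``(roi_table, stats_table)``.
    """
    tables = []
    for vol in simulate_cohort(spec):
        logger.info("analyzing subject %s", vol.subject.subject_id)
        tables.append(analyze_phantom_volume(vol, fit_config, options, n_jobs).roi_table)
    roi = pd.concat(tables, ignore_index=True)
    return roi, cohort_stats(roi)
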