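"""End-to-end processing: traces in, annotated profiles and traits out.

:func:`process_sample` runs the full measurement chain on one sample/ladder
channel pair; :func:`process_cohort` composes, renders and measures a whole
synthetic cohort, appending measured traits next to the generator's ground
truth so recovery can be assessed per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import egram as eg
from .reference import ReferenceTable, build_reference_table
from .synth import CompositionModel, MigrationModel, compose_profile, render_electropherogram
from .traits import GlycoProfile, TraitVector, compute_traits, TRAIT_COLUMNS

__all__ = ["PipelineConfig", "ProcessedSample", "process_sample", "process_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    min_snr: float = 5.0
    min_height_fraction: float = 0.002
    dp_range: tuple[int, int] = (2, 15)
    reference_maltose_time: float = eg.REFERENCE_MALTOSE_TIME
    # raw-time window in which the maltose internal standard is expected
    maltose_window: tuple[float, float] = (9.0, 12.5)
    include_unassigned: bool = False
    baseline_window_min: float = 0.75


@dataclass
class ProcessedSample:
    peaks: list[eg.DetectedPeak]
    calibration: eg.CalibrationModel
    profile: GlycoProfile
    traits: TraitVector


def _find_maltose(peaks: list[eg.DetectedPeak], window: tuple[float, float]) -> eg.DetectedPeak:
    cands = [p for p in peaks if window[0] <= p.apex_time <= window[1]]
    if not cands:
        raise ValueError(
            f"no maltose internal-standard peak found in window {window} min"
        )
    return max(cands, key=lambda p: p.height)


def process_sample(
    sample: eg.Electropherogram,
    ladder: eg.Electropherogram,
    ref: Optional[ReferenceTable] = None,
    config: PipelineConfig = PipelineConfig(),
) -> ProcessedSample:
    """Detect, normalize, calibrate, annotate and quantify one sample."""
    if ref is None:
        ref = build_reference_table()
    lo, hi = config.dp_range
    expected = hi - lo + 1

    lad_peaks = eg.detect_peaks(
        ladder,
        min_snr=config.min_snr,
        min_height_fraction=config.min_height_fraction,
        baseline_window_min=config.baseline_window_min,
    )
    if len(lad_peaks) > expected:
        # spurious noise peaks: keep the expected number of tallest peaks
        lad_peaks = sorted(
            sorted(lad_peaks, key=lambda p: p.height, reverse=True)[:expected],
            key=lambda p: p.apex_time,
        )
    lad_maltose = _find_maltose(lad_peaks, config.maltose_window)
    lad_norm = eg.normalize_migration_time(
        lad_peaks, lad_maltose.apex_time, config.reference_maltose_time
    )
    cal = eg.fit_gu_calibration(
        lad_norm, config.dp_range, maltose_time=config.reference_maltose_time
    )

    peaks = eg.detect_peaks(
        sample,
        min_snr=config.min_snr,
        min_height_fraction=config.min_height_fraction,
        baseline_window_min=config.baseline_window_min,
    )
    maltose = _find_maltose(peaks, config.maltose_window)
    norm = eg.normalize_migration_time(
        peaks, maltose.apex_time, config.reference_maltose_time
    )
    # drop the internal standard before profiling
    norm = [
        p
        for p in norm
        if abs(p.apex_time - config.reference_maltose_time) > 0.5
    ]
    annotated = eg.annotate_peaks(norm, cal, ref)
    profile = eg.relative_intensities(annotated, include_unassigned=config.include_unassigned)
    traits = compute_traits(profile, ref)
    return ProcessedSample(peaks=annotated, calibration=cal, profile=profile, traits=traits)


def process_cohort(
    cohort: pd.DataFrame,
    seed: int,
    target_min_snr: float = 50.0,
    drift_factor_sd: float = 0.01,
    composition: Optional[CompositionModel] = None,
    migration: Optional[MigrationModel] = None,
    ref: Optional[ReferenceTable] = None,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Render and measure every subject of a generated cohort table.

    For each subject the true (ratio, G0%) pair is realized as a peak-area
    vector, rendered to sample+ladder traces, and pushed through
    :func:`process_sample`.  Returns the cohort table with ``measured_``
    trait columns appended.
    """
    if composition is None:
        composition = CompositionModel()
    if migration is None:
        migration = MigrationModel()
    if ref is None:
        ref = build_reference_table(gu_tolerance=composition.gu_tolerance)
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(cohort))]
    rows = []
    for (idx, subj), sseed in zip(cohort.iterrows(), subject_seeds):
        areas = compose_profile(
            float(subj["g0_g1_ratio"]), float(subj["g0_percent"]), composition
        )
        sample, ladder = render_electropherogram(
            areas,
            migration=migration,
            seed=sseed,
            target_min_snr=target_min_snr,
            drift_factor_sd=drift_factor_sd,
            ref=ref,
        )
        res = process_sample(sample, ladder, ref=ref, config=config)
        rows.append({f"measured_{k}": v for k, v in res.traits.as_dict().items()})
    out = cohort.reset_index(drop=True).join(pd.DataFrame(rows))
    return out
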