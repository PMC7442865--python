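"""Recording-to-feature-table orchestration.

Glues preprocessing, per-pulse estimation, the validity gate, and the
measurement summary together, and assembles the calibration feature table
(nine inputs + reference IOP) from a simulated or recorded cohort.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import pandas as pd

from . import quality, sigproc
from .types import (
    BiometricRecord,
    GroundTruth,
    MeasurementCategory,
    MeasurementFeatures,
    PulseFeatures,
    RawMeasurement,
)

__all__ = ["process_recording", "build_feature_table", "FEATURE_COLUMNS"]

#: the nine calibration inputs: three acoustic features + six biometrics
FEATURE_COLUMNS = [
    "mean_damping",
    "mean_frequency",
    "mean_amplitude",
    "age",
    "visual_acuity",
    "cornea_radius",
    "central_corneal_thickness",
    "axial_length",
    "anterior_chamber_depth",
]


def process_recording(
    raw: RawMeasurement,
    rules: Optional[quality.ValidityRules] = None,
    touchdown_threshold: float = 50.0,
    pressure_dev_threshold: float = 300.0,
    self_administered: bool = True,
) -> Tuple[MeasurementFeatures, List[PulseFeatures], MeasurementCategory]:
    """One recording end to end: preprocess, estimate, gate, summarize, classify."""
    rules = rules or quality.ValidityRules()
    prep = sigproc.prepare_recording(
        raw,
        touchdown_threshold=touchdown_threshold,
        pressure_dev_threshold=pressure_dev_threshold,
    )
    pulses = [
        quality.validate_pulse(
            sigproc.extract_pulse_features(seg, noise_floor=prep.noise_floor), rules
        )
        for seg in prep.segments
    ]
    mf = sigproc.summarize_measurement(
        pulses, prep.touchdown, prep.pressure_flag, measurement_id=raw.measurement_id
    )
    category = quality.classify_measurement(mf, rules, self_administered=self_administered)
    return mf, pulses, category


def build_feature_table(
    eyes: Sequence[Tuple[BiometricRecord, GroundTruth]],
    recordings: Sequence[Tuple[RawMeasurement, GroundTruth]],
    rules: Optional[quality.ValidityRules] = None,
) -> Tuple[pd.DataFrame, List[MeasurementCategory]]:
    """Process every recording and keep the expectancy-compliant ones.

    Returns the calibration table (one row per usable measurement: the nine
    feature columns, ``reference_iop``, and identifiers) together with the
    category verdicts for *all* measurements.
    """
    bio_by_key = {(b.subject_id, b.eye_side): (b, t) for b, t in eyes}
    rows = []
    categories: List[MeasurementCategory] = []
    for raw, truth in recordings:
        mf, _, category = process_recording(raw, rules)
        categories.append(category)
        if category.category != "expectancy_compliant":
            continue
        bio, _ = bio_by_key[(raw.subject_id, raw.eye_side)]
        if mf.mean_damping is None or mf.mean_frequency is None:
            continue
        rows.append(
            {
                "subject_id": raw.subject_id,
                "eye_side": raw.eye_side,
                "measurement_id": raw.measurement_id,
                "mean_damping": mf.mean_damping,
                "mean_frequency": mf.mean_frequency,
                "mean_amplitude": mf.mean_amplitude,
                "cv_damping_percent": mf.cv_damping_percent,
                "age": bio.age,
                "visual_acuity": bio.visual_acuity,
                "cornea_radius": bio.cornea_radius,
                "central_corneal_thickness": bio.central_corneal_thickness,
                "axial_length": bio.axial_length,
                "anterior_chamber_depth": bio.anterior_chamber_depth,
                "reference_iop": truth.true_iop,
            }
        )
    return pd.DataFrame(rows), categories
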