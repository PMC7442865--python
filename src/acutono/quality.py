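"""Validity gating and the success-rate taxonomy.

A pulse is usable when it shows at least seven zero crossings, a frequency
inside the closed 350-570 Hz band, and no sensor clipping.  A measurement is
expectancy-compliant when it started (touchdown seen, pulses present),
showed no unusual chamber-pressure swing, and retained at least three valid
pulses.  Category precedence when defects co-occur: no-start, then pressure
deviation, then quality failure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import pandas as pd

from .types import CATEGORIES, CohortSummary, MeasurementCategory, MeasurementFeatures, PulseFeatures

__all__ = ["ValidityRules", "validate_pulse", "classify_measurement", "summarize_cohort"]


@dataclass(frozen=True)
class ValidityRules:
    """The expectation ranges defining a usable pulse / measurement."""

    min_zero_crossings: int = 7
    band_low_hz: float = 350.0  # closed interval: endpoints are valid
    band_high_hz: float = 570.0
    min_valid_pulses: int = 3

    def __post_init__(self) -> None:
        if self.min_zero_crossings < 0 or self.min_valid_pulses < 1:
            raise ValueError("validity thresholds must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("frequency band must satisfy 0 < low < high")


def validate_pulse(features: PulseFeatures, rules: Optional[ValidityRules] = None) -> PulseFeatures:
    """Return the pulse with its validity verdict and failure reasons filled in.

    A pulse with an undefined frequency cannot be shown to lie in the band
    and is rejected as out-of-band.
    """
    rules = rules or ValidityRules()
    reasons = set()
    if features.n_zero_crossings < rules.min_zero_crossings:
        reasons.add("too_few_crossings")
    if features.frequency is None or not (
        rules.band_low_hz <= features.frequency <= rules.band_high_hz
    ):
        reasons.add("out_of_band")
    if features.clipped:
        reasons.add("clipped")
    return replace(features, valid=not reasons, invalid_reasons=frozenset(reasons))


def classify_measurement(
    features: MeasurementFeatures,
    rules: Optional[ValidityRules] = None,
    self_administered: bool = True,
) -> MeasurementCategory:
    """Assign one Table-2 category to a summarized measurement.

    ``no_start`` when the touchdown pattern is absent or no pulses were
    detected at all; else ``pressure_deviation`` on an unusual chamber
    swing; else ``quality_fail`` with fewer than three valid pulses; else
    ``expectancy_compliant``.
    """
    rules = rules or ValidityRules()
    if not features.touchdown_detected or features.n_pulses_total == 0:
        category = "no_start"
    elif features.pressure_deviation_flag:
        category = "pressure_deviation"
    elif features.n_pulses_valid < rules.min_valid_pulses:
        category = "quality_fail"
    else:
        category = "expectancy_compliant"
    return MeasurementCategory(
        measurement_id=features.measurement_id,
        category=category,
        self_administered=self_administered,
    )


def summarize_cohort(categories: Sequence[MeasurementCategory]) -> CohortSummary:
    """Counts and one-decimal percentage shares per category.

    Also reports the self-administered success rate: the fraction of
    self-administered measurements that at least started (i.e. were not
    classified ``no_start``).
    """
    if not categories:
        raise ValueError("summarize_cohort requires a non-empty category list")
    total = len(categories)
    counts = {c: 0 for c in CATEGORIES}
    for cat in categories:
        counts[cat.category] += 1
    shares = {c: round(100.0 * counts[c] / total, 1) for c in CATEGORIES}
    self_runs = [c for c in categories if c.self_administered]
    n_self = len(self_runs)
    success = None
    if n_self:
        started = sum(1 for c in self_runs if c.category != "no_start")
        success = started / n_self
    return CohortSummary(
        counts=counts,
        shares=shares,
        total=total,
        n_self=n_self,
        n_assisted=total - n_self,
        self_administered_success_rate=success,
    )


def summary_to_frame(summary: CohortSummary) -> pd.DataFrame:
    """Success-rate table: one row per category plus the total."""
    rows = [{"category": "total", "count": summary.total, "share_percent": 100.0}]
    for c in CATEGORIES:
        rows.append(
            {"category": c, "count": summary.counts[c], "share_percent": summary.shares[c]}
        )
    return pd.DataFrame(rows)


def categories_from_counts(counts: Sequence[int]) -> List[MeasurementCategory]:
    """Expand per-category counts (in CATEGORIES order) into category records.

    Convenience for share arithmetic on published count tables.
    """
    cats: List[MeasurementCategory] = []
    i = 0
    for c, n in zip(CATEGORIES, counts):
        for _ in range(n):
            cats.append(MeasurementCategory(measurement_id=f"R{i:04d}", category=c))
            i += 1
    return cats
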