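"""Domain types for the acoustic-tonometer pipeline.

The pipeline turns a raw two-channel device recording (loudspeaker-membrane
displacement + chamber pressure) into per-pulse damped-oscillation features,
gates them through validity rules, and calibrates the surviving features plus
ocular biometrics against a reference tonometer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "ConfigurationError",
    "BiometricRecord",
    "GroundTruth",
    "RawMeasurement",
    "ForwardModelCoefficients",
    "SimulationConfig",
    "PulseSegment",
    "PulseFeatures",
    "MeasurementFeatures",
    "MeasurementCategory",
    "CohortSummary",
    "AgreementReport",
    "FAILURE_MODES",
    "CATEGORIES",
]

FAILURE_MODES = ("none", "no_start", "movement", "leakage", "pressure_deviation")
CATEGORIES = ("expectancy_compliant", "no_start", "quality_fail", "pressure_deviation")


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class BiometricRecord:
    """One eye's biometric covariates.

    Units: age in years, cornea_radius in mm, central_corneal_thickness in µm,
    axial_length in mm, anterior_chamber_depth in mm; visual_acuity is decimal
    acuity (dimensionless).
    """

    subject_id: str
    eye_side: str  # "OD" (right) or "OS" (left)
    age: float
    visual_acuity: float
    cornea_radius: float
    central_corneal_thickness: float
    axial_length: float
    anterior_chamber_depth: float

    def __post_init__(self) -> None:
        if self.eye_side not in ("OD", "OS"):
            raise ConfigurationError(f"eye_side must be OD or OS, got {self.eye_side!r}")
        for name in (
            "age",
            "visual_acuity",
            "cornea_radius",
            "central_corneal_thickness",
            "axial_length",
            "anterior_chamber_depth",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")


@dataclass
class GroundTruth:
    """Latent values a simulated measurement was generated from."""

    true_iop: float  # mm Hg
    true_damping: float  # exponential decay rate, 1/s
    true_frequency: float  # Hz
    failure_mode: str = "none"

    def __post_init__(self) -> None:
        if self.failure_mode not in FAILURE_MODES:
            raise ConfigurationError(f"failure_mode must be one of {FAILURE_MODES}")
        if not self.true_frequency > 0:
            raise ConfigurationError("true_frequency must be positive")


@dataclass
class RawMeasurement:
    """One device recording: displacement + chamber-pressure traces.

    ``displacement`` is in sensor units, ``pressure`` in Pa relative to
    ambient.  The first ``t_start_evaluation`` seconds are the pre-evaluation
    phase (device placement, touchdown); excitation pulses follow.
    """

    subject_id: str
    eye_side: str
    measurement_id: str
    sample_rate: float
    displacement: np.ndarray
    pressure: np.ndarray
    t_start_evaluation: float = 5.0
    excitation_times: Optional[np.ndarray] = None  # simulator-known pulse onsets, s
    sensor_range: Optional[float] = None  # rail magnitude in sensor units

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.displacement.shape != self.pressure.shape:
            raise ConfigurationError("displacement and pressure must have equal length")
        if self.duration <= self.t_start_evaluation:
            raise ConfigurationError("recording must extend past t_start_evaluation")

    @property
    def n_samples(self) -> int:
        return self.displacement.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class ForwardModelCoefficients:
    """Map (IOP, biometrics) -> (damping, frequency) of the coupled system.

    frequency = f0 + a_f*(iop - 16) + b_f*(axial_length - 24)
    damping   = d0 * exp(-a_d*(iop - 16)) * (1 + b_d*(cct - 545)/545)

    Defaults keep frequency inside the device's 350-570 Hz band for IOP in
    [8, 35] mm Hg at nominal biometrics.
    """

    f0: float = 450.0  # Hz at IOP 16, nominal eye
    a_f: float = 4.0  # Hz per mm Hg
    b_f: float = 6.0  # Hz per mm axial length
    d0: float = 150.0  # 1/s at IOP 16, nominal eye
    a_d: float = 0.03  # 1/mm Hg
    b_d: float = 0.3  # dimensionless, per relative CCT deviation


@dataclass
class SimulationConfig:
    """Study conditions for the virtual cohort and recordings."""

    n_subjects: int = 96
    measurements_per_eye: int = 4
    pulses_per_measurement: int = 20
    sample_rate: float = 10_000.0  # Hz
    t_start_evaluation: float = 5.0  # s, end of pre-evaluation phase
    first_pulse_time: float = 5.5  # s
    pulse_interval: float = 0.5  # s
    pulse_amplitude: float = 1.0  # sensor units
    noise_sd: float = 0.02  # fraction of pulse amplitude
    drift_amplitude: float = 0.3  # fraction of pulse amplitude
    # between-measurement chamber-coupling variability: relative SD of the
    # multiplicative jitter applied to (damping, frequency) per measurement.
    # Device placement and seal quality differ between measurements, so the
    # realized oscillation parameters scatter around the eye's latent values
    # far more than the within-measurement pulse CV suggests.
    coupling_jitter_damping: float = 0.05
    coupling_jitter_frequency: float = 0.01
    sensor_range_factor: float = 1.2  # rail at +-factor * amplitude
    touchdown_time: float = 2.8  # s
    touchdown_pressure: float = 100.0  # Pa overpressure step
    touchdown_tau: float = 1.0  # s relaxation constant
    touchdown_plateau: float = 30.0  # Pa residual seal pressure
    pressure_noise_sd: float = 2.0  # Pa
    inter_eye_correlation: float = 0.8
    failure_probabilities: dict = field(
        default_factory=lambda: {
            "no_start": 0.068,
            "movement": 0.30,
            "leakage": 0.0,
            "pressure_deviation": 0.005,
        }
    )
    coefficients: ForwardModelCoefficients = field(default_factory=ForwardModelCoefficients)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.pulses_per_measurement < 1:
            raise ConfigurationError("pulses_per_measurement must be >= 1")
        if self.measurements_per_eye < 1:
            raise ConfigurationError("measurements_per_eye must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        # Nyquist with margin for the 570 Hz band edge
        if self.sample_rate < 4 * 570.0:
            raise ConfigurationError("sample_rate must be >= 2280 Hz")
        for mode, p in self.failure_probabilities.items():
            if mode not in FAILURE_MODES[1:]:
                raise ConfigurationError(f"unknown failure mode {mode!r} in failure_probabilities")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"failure_probabilities[{mode!r}] must be in [0, 1]")
        if sum(self.failure_probabilities.values()) > 1.0:
            raise ConfigurationError("failure_probabilities must sum to <= 1")
        if not 0.0 <= self.inter_eye_correlation <= 1.0:
            raise ConfigurationError("inter_eye_correlation must be in [0, 1]")

    @property
    def duration(self) -> float:
        """Recording length: pre-evaluation phase + pulse train + tail margin."""
        return (
            self.first_pulse_time
            + (self.pulses_per_measurement - 1) * self.pulse_interval
            + 0.25
        )

    @property
    def sensor_range(self) -> float:
        return self.sensor_range_factor * self.pulse_amplitude


@dataclass
class PulseSegment:
    """A detrended displacement window holding one excitation response."""

    measurement_id: str
    pulse_index: int
    samples: np.ndarray
    t0: float  # onset within the recording, s
    sample_rate: float
    clipped: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 8:
            raise ValueError("pulse segment must hold at least 8 samples")


@dataclass
class PulseFeatures:
    """Per-pulse oscillation features and validity verdict."""

    pulse_index: int
    n_zero_crossings: int
    frequency: Optional[float]  # Hz; None when undefined
    damping: Optional[float]  # 1/s; None when undefined
    amplitude: float  # peak magnitude, sensor units
    clipped: bool = False
    valid: Optional[bool] = None  # set by the quality gate
    invalid_reasons: frozenset = frozenset()


@dataclass
class MeasurementFeatures:
    """Per-measurement summary over the valid pulses."""

    measurement_id: str
    n_pulses_total: int
    n_pulses_valid: int
    mean_damping: Optional[float]
    sd_damping: Optional[float]
    cv_damping_percent: Optional[float]  # SD as % of mean
    mean_frequency: Optional[float]
    sd_frequency: Optional[float]
    mean_amplitude: Optional[float]
    touchdown_detected: bool
    pressure_deviation_flag: bool


@dataclass
class MeasurementCategory:
    """Success-rate taxonomy verdict for one measurement."""

    measurement_id: str
    category: str
    self_administered: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"category must be one of {CATEGORIES}")


@dataclass
class CohortSummary:
    """Counts and one-decimal percentage shares per category."""

    counts: dict
    shares: dict  # percent, rounded to one decimal
    total: int
    n_self: int
    n_assisted: int
    self_administered_success_rate: Optional[float]  # fraction of self runs that started


@dataclass
class AgreementReport:
    """Regression sensitivity + Bland-Altman expanded uncertainty.

    Differences are oriented prediction - reference; the expanded uncertainty
    is U = k_p * SD(differences) with coverage factor k_p (default 2, ~95%).
    """

    n: int
    slope: float
    intercept: float
    r: float
    bias: float
    sd_diff: float
    k_p: float
    expanded_uncertainty: float
    loa_lower: float
    loa_upper: float
    meets_iso_limit: bool  # U < 5 mm Hg, the approval threshold

    def to_dict(self) -> dict:
        return asdict(self)
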