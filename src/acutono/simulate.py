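"""Virtual cohort and raw-recording generator.

Emulates the structure of clinical acoustic-tonometer recordings: a 0-5 s
pre-evaluation phase with a chamber-seal ("touchdown") overpressure near
2.8 s, then a train of ~20 damped-sinusoid excitation responses in the
350-570 Hz band whose damping and frequency depend on the eye's IOP and
biometrics, plus sensor noise, slow baseline drift from subject movement,
rail clipping, and configurable failure modes (no-start, movement, chamber
leakage, pressure deviation).

Biometric covariates are drawn from Gaussian priors matching the published
per-eye cohort statistics, clipped to physiological ranges, with an
inter-eye correlation of 0.8.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    BiometricRecord,
    ConfigurationError,
    ForwardModelCoefficients,
    GroundTruth,
    RawMeasurement,
    SimulationConfig,
)

__all__ = [
    "TABLE1_PRIORS",
    "CLIP_RANGES",
    "draw_cohort",
    "forward_model",
    "synthesize_recording",
    "simulate_cohort",
    "cohort_to_frame",
    "write_recording",
    "read_recording",
]

# Per-eye priors (mean, SD) for the simulated cohort: (OD, OS).
TABLE1_PRIORS = {
    "age": ((61.7, 17.1), (61.7, 17.1)),  # shared between eyes
    "iop": ((16.4, 4.4), (17.0, 5.7)),
    "visual_acuity": ((0.7, 0.3), (0.7, 0.3)),
    "cornea_radius": ((7.8, 0.3), (7.8, 0.3)),
    "central_corneal_thickness": ((546.9, 36.4), (544.0, 37.6)),
    "axial_length": ((24.0, 3.1), (24.2, 1.7)),
    "anterior_chamber_depth": ((3.1, 0.7), (3.1, 0.7)),
}

CLIP_RANGES = {
    "age": (18.0, 105.0),
    "iop": (5.0, 60.0),
    "visual_acuity": (0.05, 2.0),
    "cornea_radius": (6.0, 10.0),
    "central_corneal_thickness": (400.0, 700.0),
    "axial_length": (19.0, 32.0),
    "anterior_chamber_depth": (1.5, 5.0),
}


def _eye_pair(rng: np.random.Generator, od: Tuple[float, float], os_: Tuple[float, float],
              rho: float) -> Tuple[float, float]:
    """Draw a correlated (OD, OS) pair from per-eye Gaussian marginals."""
    z1, z2 = rng.standard_normal(2)
    z_os = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2
    return od[0] + od[1] * z1, os_[0] + os_[1] * z_os


def draw_cohort(config: SimulationConfig) -> List[Tuple[BiometricRecord, GroundTruth]]:
    """Draw a virtual cohort: two eyes per subject with correlated covariates.

    Returns one ``(BiometricRecord, GroundTruth)`` pair per eye (OD then OS
    per subject), deterministic given ``config.rng_seed``.  Latent damping
    and frequency come from :func:`forward_model`; the per-eye
    ``failure_mode`` is left at ``"none"`` — failure modes belong to
    individual measurements and are drawn at recording time.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 1]))
    rho = config.inter_eye_correlation
    eyes: List[Tuple[BiometricRecord, GroundTruth]] = []
    for i in range(config.n_subjects):
        sid = f"S{i:04d}"
        draws = {}
        for name, (od_prior, os_prior) in TABLE1_PRIORS.items():
            lo, hi = CLIP_RANGES[name]
            vod, vos = _eye_pair(rng, od_prior, os_prior, rho)
            draws[name] = (float(np.clip(vod, lo, hi)), float(np.clip(vos, lo, hi)))
        # age is a subject-level quantity
        age = draws["age"][0]
        for k, side in enumerate(("OD", "OS")):
            bio = BiometricRecord(
                subject_id=sid,
                eye_side=side,
                age=age,
                visual_acuity=draws["visual_acuity"][k],
                cornea_radius=draws["cornea_radius"][k],
                central_corneal_thickness=draws["central_corneal_thickness"][k],
                axial_length=draws["axial_length"][k],
                anterior_chamber_depth=draws["anterior_chamber_depth"][k],
            )
            iop = draws["iop"][k]
            damping, frequency = forward_model(bio, iop, config.coefficients)
            eyes.append((bio, GroundTruth(true_iop=iop, true_damping=damping,
                                          true_frequency=frequency)))
    return eyes


def forward_model(
    biometrics: BiometricRecord,
    iop: float,
    coefficients: Optional[ForwardModelCoefficients] = None,
    sample_rate: Optional[float] = None,
) -> Tuple[float, float]:
    """Latent (damping 1/s, frequency Hz) of the coupled eye-air-speaker system.

    Frequency rises linearly with IOP and axial length; damping falls
    exponentially with IOP and scales with relative corneal thickness.  With
    the default coefficients the frequency stays inside the 350-570 Hz device
    band for IOP in [8, 35] mm Hg at nominal biometrics.
    """
    c = coefficients or ForwardModelCoefficients()
    if not iop > 0:
        raise ValueError("iop must be positive")
    vals = [c.f0, c.a_f, c.b_f, c.d0, c.a_d, c.b_d]
    if not all(np.isfinite(vals)):
        raise ValueError("forward-model coefficients must be finite")
    frequency = c.f0 + c.a_f * (iop - 16.0) + c.b_f * (biometrics.axial_length - 24.0)
    damping = (
        c.d0
        * np.exp(-c.a_d * (iop - 16.0))
        * (1.0 + c.b_d * (biometrics.central_corneal_thickness - 545.0) / 545.0)
    )
    nyquist = (sample_rate / 2.0) if sample_rate is not None else None
    if frequency <= 0 or (nyquist is not None and frequency >= nyquist):
        raise ValueError(
            f"model-range error: frequency {frequency:.1f} Hz outside (0, "
            f"{nyquist if nyquist is not None else 'inf'})"
        )
    if damping <= 0:
        raise ValueError(f"model-range error: damping {damping:.3f} not positive")
    return float(damping), float(frequency)


def sample_failure_mode(rng: np.random.Generator, config: SimulationConfig) -> str:
    """Draw a failure mode for one measurement from the configured rates."""
    modes = list(config.failure_probabilities)
    probs = [config.failure_probabilities[m] for m in modes]
    u = rng.uniform()
    acc = 0.0
    for mode, p in zip(modes, probs):
        acc += p
        if u < acc:
            return mode
    return "none"


def _smooth_drift(rng: np.random.Generator, t: np.ndarray, amplitude: float) -> np.ndarray:
    """Slow baseline wander: a few sinusoids below 0.5 Hz, bounded by amplitude."""
    if amplitude <= 0:
        return np.zeros_like(t)
    freqs = rng.uniform(0.1, 0.5, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    weights = rng.uniform(0.2, 1.0, size=3)
    weights = weights / weights.sum()
    drift = np.zeros_like(t)
    for f, ph, w in zip(freqs, phases, weights):
        drift += w * np.sin(2 * np.pi * f * t + ph)
    return amplitude * drift


def synthesize_recording(
    biometrics: BiometricRecord,
    truth: GroundTruth,
    config: SimulationConfig,
    measurement_id: str = "M0000",
    rng: Optional[np.random.Generator] = None,
) -> RawMeasurement:
    """Render one raw two-channel recording for the given latent state.

    Normal mode: touchdown overpressure step at 2.8 s relaxing toward a seal
    plateau, then ``pulses_per_measurement`` damped sinusoids
    ``A exp(-lambda t) sin(2 pi f t)`` every ``pulse_interval`` seconds from
    ``first_pulse_time``, plus Gaussian sensor noise and slow drift; the
    trace is clipped at the sensor rail.

    Failure modes: ``no_start`` suppresses touchdown and pulses; ``movement``
    adds large slow excursions and drives most pulses into the rail;
    ``leakage`` raises damping and lowers frequency (chamber not airtight);
    ``pressure_deviation`` injects an out-of-band chamber-pressure swing.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), 2]))
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    mode = truth.failure_mode
    A = config.pulse_amplitude

    # --- pressure channel ---
    pressure = rng.normal(0.0, config.pressure_noise_sd, size=n)
    if mode != "no_start":
        td = t >= config.touchdown_time
        pressure[td] += config.touchdown_plateau + (
            config.touchdown_pressure - config.touchdown_plateau
        ) * np.exp(-(t[td] - config.touchdown_time) / config.touchdown_tau)
    if mode == "pressure_deviation":
        t_dev = rng.uniform(config.t_start_evaluation + 0.5, config.duration - 0.5)
        pressure += 4.0 * config.touchdown_pressure * np.exp(-0.5 * ((t - t_dev) / 0.05) ** 2)

    # --- displacement channel ---
    displacement = _smooth_drift(rng, t, config.drift_amplitude * A)
    if mode == "movement":
        displacement += _smooth_drift(rng, t, 0.5 * A)

    lam, freq = truth.true_damping, truth.true_frequency
    if mode == "leakage":
        lam *= 1.6
        freq *= 0.92
    # chamber-coupling variability: each placement realizes slightly
    # different oscillation parameters around the eye's latent values
    if config.coupling_jitter_damping > 0:
        lam *= float(np.exp(config.coupling_jitter_damping * rng.standard_normal()))
    if config.coupling_jitter_frequency > 0:
        freq *= float(1.0 + config.coupling_jitter_frequency * rng.standard_normal())

    excitation_times = np.array([])
    if mode != "no_start":
        excitation_times = (
            config.first_pulse_time + config.pulse_interval * np.arange(config.pulses_per_measurement)
        )
        if mode == "movement":
            # most pulses overdriven into the sensor rail -> too few valid
            n_clip = int(rng.integers(config.pulses_per_measurement - 2,
                                      config.pulses_per_measurement + 1))
            clip_idx = set(rng.choice(config.pulses_per_measurement, size=n_clip,
                                      replace=False).tolist())
        else:
            clip_idx = set()
        # render each response over the full inter-pulse span so the tail
        # decays smoothly instead of being truncated
        window = int(round(config.pulse_interval * fs))
        for k, t0 in enumerate(excitation_times):
            i0 = int(round(t0 * fs))
            i1 = min(i0 + window, n)
            tau = (np.arange(i1 - i0)) / fs
            amp = 2.0 * A if k in clip_idx else A
            displacement[i0:i1] += amp * np.exp(-lam * tau) * np.sin(2 * np.pi * freq * tau)

    if config.noise_sd > 0:
        displacement += rng.normal(0.0, config.noise_sd * A, size=n)
    rail = config.sensor_range
    displacement = np.clip(displacement, -rail, rail)

    return RawMeasurement(
        subject_id=biometrics.subject_id,
        eye_side=biometrics.eye_side,
        measurement_id=measurement_id,
        sample_rate=fs,
        displacement=displacement,
        pressure=pressure,
        t_start_evaluation=config.t_start_evaluation,
        excitation_times=excitation_times,
        sensor_range=rail,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[List[Tuple[BiometricRecord, GroundTruth]], List[Tuple[RawMeasurement, GroundTruth]]]:
    """Full study simulation: cohort draw + all raw recordings.

    Returns the per-eye cohort and a flat list of (recording, per-measurement
    truth) pairs; each measurement re-draws its failure mode.  Fully
    deterministic given ``config.rng_seed``: every measurement gets its own
    child seed, so the outcome does not depend on iteration order.
    """
    eyes = draw_cohort(config)
    recordings: List[Tuple[RawMeasurement, GroundTruth]] = []
    for e_idx, (bio, truth) in enumerate(eyes):
        for m in range(config.measurements_per_eye):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.rng_seed), 2, e_idx, m])
            )
            mode = sample_failure_mode(rng, config)
            m_truth = replace(truth, failure_mode=mode)
            mid = f"{bio.subject_id}-{bio.eye_side}-{m:02d}"
            raw = synthesize_recording(bio, m_truth, config, measurement_id=mid, rng=rng)
            recordings.append((raw, m_truth))
    return eyes, recordings


def cohort_to_frame(eyes: List[Tuple[BiometricRecord, GroundTruth]]) -> pd.DataFrame:
    """Cohort as a tidy table, one row per eye."""
    rows = []
    for bio, truth in eyes:
        rows.append(
            {
                "subject_id": bio.subject_id,
                "eye_side": bio.eye_side,
                "age": bio.age,
                "visual_acuity": bio.visual_acuity,
                "cornea_radius": bio.cornea_radius,
                "central_corneal_thickness": bio.central_corneal_thickness,
                "axial_length": bio.axial_length,
                "anterior_chamber_depth": bio.anterior_chamber_depth,
                "true_iop": truth.true_iop,
                "true_damping": truth.true_damping,
                "true_frequency": truth.true_frequency,
            }
        )
    return pd.DataFrame(rows)


def write_recording(raw: RawMeasurement, csv_path) -> None:
    """Write a recording as two-channel CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {"time_s": raw.time, "displacement": raw.displacement, "pressure_pa": raw.pressure}
    )
    df.to_csv(csv_path, index=False)
    sidecar = {
        "subject_id": raw.subject_id,
        "eye_side": raw.eye_side,
        "measurement_id": raw.measurement_id,
        "sample_rate": raw.sample_rate,
        "t_start_evaluation": raw.t_start_evaluation,
        "sensor_range": raw.sensor_range,
        "excitation_times": None
        if raw.excitation_times is None
        else list(map(float, raw.excitation_times)),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_recording(csv_path) -> RawMeasurement:
    """Read a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    exc = meta.get("excitation_times")
    return RawMeasurement(
        subject_id=meta["subject_id"],
        eye_side=meta["eye_side"],
        measurement_id=meta["measurement_id"],
        sample_rate=float(meta["sample_rate"]),
        displacement=df["displacement"].to_numpy(),
        pressure=df["pressure_pa"].to_numpy(),
        t_start_evaluation=float(meta["t_start_evaluation"]),
        excitation_times=None if exc is None else np.asarray(exc, dtype=float),
        sensor_range=meta.get("sensor_range"),
    )
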