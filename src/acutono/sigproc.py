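"""Raw-recording preprocessing and damped-sinusoid feature extraction.

A recording is reduced to per-pulse features in five steps: touchdown
detection on the pressure channel, baseline balancing of the displacement
channel with piecewise third-order polynomials through quiet-segment
medians, envelope-threshold pulse segmentation after the 5 s pre-evaluation
phase, zero-crossing frequency estimation, and log-envelope damping
estimation.  Frequency deliberately comes from interpolated zero crossings
(the same primitive the validity rules are written in terms of) rather than
an FFT peak; an FFT estimate is kept as an internal cross-check only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .types import MeasurementFeatures, PulseFeatures, PulseSegment, RawMeasurement

__all__ = [
    "detect_touchdown",
    "pressure_deviation_flag",
    "noise_floor_mad",
    "detrend_offset",
    "coarse_baseline",
    "find_pulse_onsets",
    "segment_pulses",
    "count_zero_crossings",
    "zero_crossing_times",
    "analysis_region",
    "estimate_frequency",
    "estimate_frequency_fft",
    "estimate_damping",
    "extract_pulse_features",
    "summarize_measurement",
    "prepare_recording",
]

logger = logging.getLogger(__name__)

#: fixed evaluation window per excitation response, s
PULSE_WINDOW_S = 0.040
#: onset threshold as a multiple of the noise floor
ONSET_THRESHOLD_FACTOR = 5.0


class UndefinedFeatureError(ValueError):
    """A pulse does not support the requested estimate (too little signal)."""


# ---------------------------------------------------------------------------
# pressure channel
# ---------------------------------------------------------------------------

def detect_touchdown(
    pressure: np.ndarray,
    sample_rate: float,
    t_end: float = 5.0,
    threshold: float = 50.0,
    min_duration: float = 0.2,
) -> bool:
    """True iff a sustained chamber overpressure occurs in the pre-evaluation phase.

    The device sealing against the orbit compresses the chamber volume and
    raises the pressure; a measurement without this pattern never started.
    "Sustained" means >= ``threshold`` Pa for at least ``min_duration`` s
    anywhere in [0, t_end].
    """
    pressure = np.asarray(pressure, dtype=float)
    n_end = int(round(t_end * sample_rate))
    if pressure.size < n_end:
        raise ValueError(f"pressure trace shorter than t_end={t_end} s")
    seg = pressure[:n_end]
    above = seg >= threshold
    if not above.any():
        return False
    # longest run of consecutive above-threshold samples
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    longest = int((ends - starts).max())
    return longest >= int(round(min_duration * sample_rate))


def pressure_deviation_flag(
    pressure: np.ndarray,
    sample_rate: float,
    t_start: float = 5.0,
    threshold: float = 300.0,
) -> bool:
    """True iff the evaluation-window pressure swings unusually far from baseline.

    Baseline is the median over the evaluation window; the default threshold
    is three times the nominal touchdown overpressure.
    """
    pressure = np.asarray(pressure, dtype=float)
    i0 = int(round(t_start * sample_rate))
    window = pressure[i0:]
    if window.size == 0:
        return False
    baseline = np.median(window)
    return bool(np.max(np.abs(window - baseline)) > threshold)


# ---------------------------------------------------------------------------
# baseline balancing
# ---------------------------------------------------------------------------

def noise_floor_mad(x: np.ndarray) -> float:
    """Robust noise-floor estimate: 1.4826 x median absolute deviation."""
    x = np.asarray(x, dtype=float)
    mad = np.median(np.abs(x - np.median(x)))
    floor = 1.4826 * mad
    scale = float(np.max(np.abs(x))) if x.size else 0.0
    return max(float(floor), 1e-12 * scale, 1e-300)


def coarse_baseline(trace: np.ndarray, sample_rate: float, bin_s: float = 0.1) -> np.ndarray:
    """Rough baseline: cubic spline through medians of uniform time bins.

    Bin medians are robust to the pulses, which occupy well under half of any
    bin at the default cadence.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    bin_n = max(2, int(round(bin_s * sample_rate)))
    n_bins = max(4, n // bin_n)
    centers = np.empty(n_bins)
    medians = np.empty(n_bins)
    for b in range(n_bins):
        i0 = b * bin_n
        i1 = n if b == n_bins - 1 else (b + 1) * bin_n
        centers[b] = 0.5 * (i0 + i1 - 1) / sample_rate
        medians[b] = np.median(trace[i0:i1])
    t = np.arange(n) / sample_rate
    spline = CubicSpline(centers, medians)
    tc = np.clip(t, centers[0], centers[-1])  # hold endpoint values outside the knot span
    return spline(tc)


def detrend_offset(
    trace: np.ndarray,
    sample_rate: float,
    anchors: Sequence[Tuple[int, int]],
) -> np.ndarray:
    """Balance a varying signal offset with piecewise third-order polynomials.

    ``anchors`` are (start, stop) sample windows over quiet inter-pulse
    segments; a cubic spline is drawn through the (window-center, median)
    points and subtracted.  Outside the anchored span the baseline is held at
    the endpoint value rather than extrapolated.  With fewer than four
    anchors the method falls back to a single cubic fit over the whole trace
    (logged), which still removes constant and polynomial offsets.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    t = np.arange(n) / sample_rate
    usable = [(i0, i1) for i0, i1 in anchors if i1 - i0 >= 1 and 0 <= i0 < i1 <= n]
    if len(usable) < 4:
        logger.warning(
            "detrend_offset: only %d quiet anchors, falling back to a single cubic fit",
            len(usable),
        )
        coeffs = np.polyfit(t, trace, deg=3)
        return trace - np.polyval(coeffs, t)
    centers = np.array([0.5 * (i0 + i1 - 1) / sample_rate for i0, i1 in usable])
    medians = np.array([np.median(trace[i0:i1]) for i0, i1 in usable])
    order = np.argsort(centers)
    spline = CubicSpline(centers[order], medians[order])
    tc = np.clip(t, centers.min(), centers.max())
    return trace - spline(tc)


# ---------------------------------------------------------------------------
# pulse segmentation
# ---------------------------------------------------------------------------

def find_pulse_onsets(
    trace: np.ndarray,
    sample_rate: float,
    t_start: float = 5.0,
    noise_floor: Optional[float] = None,
    threshold_factor: float = ONSET_THRESHOLD_FACTOR,
    min_gap_s: float = 0.1,
) -> np.ndarray:
    """Sample indices where excitation responses begin (evaluation phase only).

    An onset is where the 2 ms smoothed magnitude envelope first exceeds
    ``threshold_factor`` times the noise floor; threshold excursions closer
    than ``min_gap_s`` are merged into one response.
    """
    trace = np.asarray(trace, dtype=float)
    i_start = int(round(t_start * sample_rate))
    x = trace[i_start:]
    if x.size == 0:
        return np.array([], dtype=int)
    if noise_floor is None:
        noise_floor = noise_floor_mad(x)
    smooth_n = max(3, int(round(0.002 * sample_rate)))
    envelope = uniform_filter1d(np.abs(x), size=smooth_n)
    above = envelope > threshold_factor * noise_floor
    if not above.any():
        return np.array([], dtype=int)
    idx = np.flatnonzero(above)
    gaps = np.diff(idx)
    breaks = np.flatnonzero(gaps > int(min_gap_s * sample_rate))
    starts = np.r_[idx[0], idx[breaks + 1]]
    # back the onset up over the smoother's half-width, then forward to the
    # first sample actually rising out of the floor
    half = smooth_n // 2 + 1
    onsets = []
    for s in starts:
        lo = max(0, s - half)
        seg = np.abs(x[lo : s + half])
        rising = np.flatnonzero(seg > noise_floor)
        onset = lo + (int(rising[0]) if rising.size else 0)
        onsets.append(i_start + onset)
    return np.asarray(sorted(set(onsets)), dtype=int)


def segment_pulses(
    trace: np.ndarray,
    sample_rate: float,
    t_start: float = 5.0,
    raw_trace: Optional[np.ndarray] = None,
    sensor_range: Optional[float] = None,
    measurement_id: str = "",
    noise_floor: Optional[float] = None,
    window_s: float = PULSE_WINDOW_S,
    onsets: Optional[np.ndarray] = None,
) -> List[PulseSegment]:
    """Cut the detrended trace into fixed windows, one per excitation response.

    Each window runs ``window_s`` (default 40 ms) from its onset, or to the
    next onset if that comes first.  The ``clipped`` flag is decided on the
    *raw* trace (clipping happens at the sensor, before baseline removal):
    any sample at the rail marks the pulse as clipped.  Without a known rail
    a run of >= 3 identical samples at the window maximum is treated as rail
    contact.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size <= int(round(t_start * sample_rate)):
        raise ValueError("trace must extend past t_start")
    if onsets is None:
        onsets = find_pulse_onsets(trace, sample_rate, t_start, noise_floor=noise_floor)
    onsets = np.asarray(onsets, dtype=int)
    window_n = int(round(window_s * sample_rate))
    segments: List[PulseSegment] = []
    for k, i0 in enumerate(onsets):
        i1 = min(i0 + window_n, trace.size)
        if k + 1 < onsets.size:
            i1 = min(i1, int(onsets[k + 1]))
        if i1 - i0 < 8:
            continue
        clipped = False
        if raw_trace is not None:
            raw_win = np.asarray(raw_trace, dtype=float)[i0:i1]
            if sensor_range is not None:
                clipped = bool(np.any(np.abs(raw_win) >= sensor_range * (1 - 1e-9)))
            else:
                peak = np.max(np.abs(raw_win))
                at_peak = np.abs(np.abs(raw_win) - peak) < 1e-12 * max(peak, 1.0)
                runs = np.diff(np.flatnonzero(np.r_[True, ~at_peak, True]))
                clipped = bool(at_peak.sum() >= 3 and np.any(runs >= 3))
        segments.append(
            PulseSegment(
                measurement_id=measurement_id,
                pulse_index=k,
                samples=trace[i0:i1].copy(),
                t0=i0 / sample_rate,
                sample_rate=sample_rate,
                clipped=clipped,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# per-pulse estimators
# ---------------------------------------------------------------------------

def count_zero_crossings(samples: np.ndarray) -> int:
    """Number of strict sign changes; invariant under positive rescaling.

    Samples that are exactly zero inherit the preceding sign, so a crossing
    is registered once when the signal next takes the opposite sign.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    sgn = np.sign(x)
    nz = np.flatnonzero(sgn)
    if nz.size == 0:
        logger.warning("count_zero_crossings: all-zero segment")
        return 0
    s = sgn[nz]
    return int(np.sum(s[1:] != s[:-1]))


def zero_crossing_times(
    samples: np.ndarray, sample_rate: float, min_separation_s: float = 0.0
) -> np.ndarray:
    """Crossing times (s, relative to the segment start) by linear interpolation.

    ``min_separation_s`` debounces noise wiggles around a genuine crossing:
    crossings closer than that to the previous accepted one are dropped.
    Half a period at the top of the device band is ~0.88 ms, so a debounce
    around 0.5 ms cannot remove genuine crossings.
    """
    x = np.asarray(samples, dtype=float)
    times = []
    prev_i = None
    prev_s = 0.0
    for i in range(x.size):
        s = np.sign(x[i])
        if s == 0:
            continue
        if prev_i is not None and s != prev_s:
            x0, x1 = x[prev_i], x[i]
            # linear interpolation between the bracketing nonzero samples
            frac = x0 / (x0 - x1)
            t = (prev_i + frac * (i - prev_i)) / sample_rate
            if times and t - times[-1] < min_separation_s:
                prev_i, prev_s = i, s
                continue
            times.append(t)
        prev_i, prev_s = i, s
    return np.asarray(times)


def analysis_region(
    samples: np.ndarray,
    noise_floor: Optional[float] = None,
    threshold_factor: float = ONSET_THRESHOLD_FACTOR,
    rel_floor: float = 0.01,
) -> np.ndarray:
    """The above-noise portion of a pulse, from the start to the last sample
    exceeding max(threshold_factor x noise floor, rel_floor x peak).

    Restricting the estimators (and the zero-crossing count used by the
    validity rules) to this region keeps tail noise from contaminating them.
    """
    x = np.asarray(samples, dtype=float)
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    thr = rel_floor * peak
    if noise_floor is not None:
        thr = max(thr, threshold_factor * noise_floor)
    # cut on a short smoothed envelope so an isolated tail-noise spike cannot
    # drag the region into pure noise
    smooth_n = min(max(3, x.size // 20), 21)
    envelope = uniform_filter1d(np.abs(x), size=smooth_n)
    above = np.flatnonzero((np.abs(x) >= thr) & (envelope >= 0.5 * thr))
    if above.size == 0:
        return x[:0]
    # trim both ends: leading samples are pre-onset noise from the onset
    # backtrack, trailing ones are the decayed tail
    return x[int(above[0]) : int(above[-1]) + 1]


def estimate_frequency(
    samples: np.ndarray,
    sample_rate: float,
    min_separation_s: float = 0.0005,
) -> float:
    """Oscillation frequency from interpolated zero crossings.

    f = (n_crossings - 1) / (2 * (t_last - t_first)); exact for a sampled
    sinusoid up to interpolation error (< 0.5% at >= 10 kHz for the device
    band) and unaffected by exponential amplitude decay, which does not move
    the zeros.  Crossings are debounced at 0.5 ms, well under the band's
    shortest half-period.
    """
    tc = zero_crossing_times(samples, sample_rate, min_separation_s=min_separation_s)
    if tc.size < 3:
        raise UndefinedFeatureError("frequency undefined: fewer than 3 zero crossings")
    return float((tc.size - 1) / (2.0 * (tc[-1] - tc[0])))


def estimate_frequency_fft(samples: np.ndarray, sample_rate: float) -> float:
    """FFT-peak frequency with parabolic bin interpolation (internal cross-check)."""
    x = np.asarray(samples, dtype=float)
    n = int(2 ** np.ceil(np.log2(max(x.size * 4, 64))))
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size), n=n))
    k = int(np.argmax(spec[1:])) + 1
    if 1 <= k < spec.size - 1:
        y0, y1, y2 = spec[k - 1 : k + 2]
        denom = y0 - 2 * y1 + y2
        d = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        d = 0.0
    return float((k + d) * sample_rate / n)


def _refined_peaks(
    x_abs: np.ndarray, sample_rate: float, height: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Local-extremum times and magnitudes with parabolic sub-sample refinement."""
    idx, _ = find_peaks(x_abs, height=height)
    times, amps = [], []
    for p in idx:
        if 1 <= p < x_abs.size - 1:
            y0, y1, y2 = x_abs[p - 1], x_abs[p], x_abs[p + 1]
            denom = y0 - 2 * y1 + y2
            d = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            d = float(np.clip(d, -0.5, 0.5))
            amp = y1 - 0.25 * (y0 - y2) * d
        else:
            d, amp = 0.0, x_abs[p]
        times.append((p + d) / sample_rate)
        amps.append(amp)
    return np.asarray(times), np.asarray(amps)


def estimate_damping(
    samples: np.ndarray,
    sample_rate: float,
    noise_floor: Optional[float] = None,
) -> float:
    """Exponential decay rate (1/s) from a log-envelope regression.

    The envelope A*exp(-lambda t) is sampled once per half-cycle between
    consecutive zero crossings as a noise-compensated RMS magnitude,
    A_i^2 = 2 * (mean(x^2) - noise_floor^2); subtracting the noise variance
    makes the magnitude unbiased, unlike raw extremum heights, which noise
    inflates preferentially at the decayed end of the pulse.  The per-half-
    cycle decay factor is the same for every half-cycle, so it shifts the
    intercept of the least-squares line through (t_i, ln A_i) but not its
    slope, which is exactly -lambda for a noiseless damped sinusoid.
    Scale-invariant for a proportionally scaled noise floor (exactly so when
    ``noise_floor`` is None).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0 or not np.any(x):
        raise UndefinedFeatureError("damping undefined: silent segment")
    var_noise = float(noise_floor) ** 2 if noise_floor is not None else 0.0
    tc = zero_crossing_times(x, sample_rate, min_separation_s=0.0005)
    times, log_amps = [], []
    for t0, t1 in zip(tc[:-1], tc[1:]):
        i0 = int(np.ceil(t0 * sample_rate))
        i1 = int(np.floor(t1 * sample_rate)) + 1
        if i1 - i0 < 3:
            continue
        mean_sq = float(np.mean(x[i0:i1] ** 2)) - var_noise
        if mean_sq <= 0:
            continue
        times.append(0.5 * (t0 + t1))
        log_amps.append(0.5 * np.log(2.0 * mean_sq))
    if len(times) < 3:
        raise UndefinedFeatureError("damping undefined: fewer than 3 usable half-cycles")
    slope, _ = np.polyfit(times, log_amps, deg=1)
    return float(-slope)


def extract_pulse_features(
    segment: PulseSegment,
    noise_floor: Optional[float] = None,
) -> PulseFeatures:
    """All per-pulse features; validity is decided later by the quality gate.

    The zero-crossing count and both estimators run on the above-noise
    analysis region of the window.  Undefined estimates (too little signal)
    yield ``None`` rather than raising.
    """
    region = analysis_region(segment.samples, noise_floor=noise_floor)
    if region.size == 0:
        region = segment.samples
    # the validity count uses the same debounced crossings as the estimator;
    # a raw sign-change count would let tail noise inflate it
    n_cross = zero_crossing_times(region, segment.sample_rate, min_separation_s=0.0005).size
    amplitude = float(np.max(np.abs(segment.samples)))
    try:
        frequency: Optional[float] = estimate_frequency(region, segment.sample_rate)
    except UndefinedFeatureError:
        frequency = None
    try:
        damping: Optional[float] = estimate_damping(
            region, segment.sample_rate, noise_floor=noise_floor
        )
    except UndefinedFeatureError:
        damping = None
    return PulseFeatures(
        pulse_index=segment.pulse_index,
        n_zero_crossings=n_cross,
        frequency=frequency,
        damping=damping,
        amplitude=amplitude,
        clipped=segment.clipped,
    )


# ---------------------------------------------------------------------------
# measurement-level summary
# ---------------------------------------------------------------------------

def summarize_measurement(
    pulse_features: Sequence[PulseFeatures],
    touchdown_detected: bool,
    pressure_deviation: bool,
    measurement_id: str = "",
) -> MeasurementFeatures:
    """Means and SDs of the per-pulse features over the *valid* pulses only.

    The damping spread is additionally reported as a coefficient of
    variation (SD as percent of the mean).  With zero valid pulses the
    feature fields are ``None`` but the counts are still filled.
    """
    valid = [f for f in pulse_features if f.valid]
    n_total, n_valid = len(pulse_features), len(valid)

    def _stats(values: List[float]) -> Tuple[Optional[float], Optional[float]]:
        if not values:
            return None, None
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    mean_d, sd_d = _stats([f.damping for f in valid if f.damping is not None])
    mean_f, sd_f = _stats([f.frequency for f in valid if f.frequency is not None])
    mean_a, _ = _stats([f.amplitude for f in valid])
    cv = None
    if mean_d is not None and sd_d is not None and mean_d != 0:
        cv = 100.0 * sd_d / abs(mean_d)
    return MeasurementFeatures(
        measurement_id=measurement_id,
        n_pulses_total=n_total,
        n_pulses_valid=n_valid,
        mean_damping=mean_d,
        sd_damping=sd_d,
        cv_damping_percent=cv,
        mean_frequency=mean_f,
        sd_frequency=sd_f,
        mean_amplitude=mean_a,
        touchdown_detected=touchdown_detected,
        pressure_deviation_flag=pressure_deviation,
    )


# ---------------------------------------------------------------------------
# whole-recording preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedRecording:
    """Intermediate products of recording preprocessing."""

    detrended: np.ndarray
    segments: List[PulseSegment]
    noise_floor: float
    touchdown: bool
    pressure_flag: bool


def prepare_recording(
    raw: RawMeasurement,
    touchdown_threshold: float = 50.0,
    pressure_dev_threshold: float = 300.0,
) -> PreparedRecording:
    """Run preprocessing end to end: touchdown check, two-stage baseline
    balancing, and pulse segmentation.

    Stage one subtracts a coarse bin-median baseline so onsets can be found
    on a drift-free trace; stage two rebuilds the baseline as a cubic spline
    through the medians of the quiet inter-pulse segments (plus leading and
    trailing quiet windows) and subtracts it from the raw trace.
    """
    fs = raw.sample_rate
    touchdown = detect_touchdown(
        raw.pressure, fs, t_end=raw.t_start_evaluation, threshold=touchdown_threshold
    )
    p_flag = pressure_deviation_flag(
        raw.pressure, fs, t_start=raw.t_start_evaluation, threshold=pressure_dev_threshold
    )

    coarse = raw.displacement - coarse_baseline(raw.displacement, fs)
    i_start = int(round(raw.t_start_evaluation * fs))
    floor = noise_floor_mad(coarse[i_start:])
    onsets = find_pulse_onsets(coarse, fs, raw.t_start_evaluation, noise_floor=floor)

    # quiet anchors: 20 ms windows centred between consecutive responses,
    # plus one before the first and one after the last
    anchor_n = int(round(0.020 * fs))
    window_n = int(round(PULSE_WINDOW_S * fs))
    quiet_centers = []
    if onsets.size:
        quiet_centers.append(max(i_start + anchor_n, int(onsets[0]) - 3 * anchor_n))
        for a, b in zip(onsets[:-1], onsets[1:]):
            quiet_centers.append((int(a) + window_n + int(b)) // 2)
        quiet_centers.append(min(raw.n_samples - anchor_n, int(onsets[-1]) + 2 * window_n))
    anchors = [
        (max(0, c - anchor_n // 2), min(raw.n_samples, c + anchor_n // 2))
        for c in quiet_centers
    ]
    if len(anchors) >= 4:
        detrended = detrend_offset(raw.displacement, fs, anchors)
    else:
        # nothing to anchor on (silent or near-silent recording)
        detrended = coarse

    segments = segment_pulses(
        detrended,
        fs,
        t_start=raw.t_start_evaluation,
        raw_trace=raw.displacement,
        sensor_range=raw.sensor_range,
        measurement_id=raw.measurement_id,
        noise_floor=floor,
        onsets=onsets,  # detected once, on the coarse-detrended trace
    )
    return PreparedRecording(
        detrended=detrended,
        segments=segments,
        noise_floor=floor,
        touchdown=touchdown,
        pressure_flag=p_flag,
    )
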