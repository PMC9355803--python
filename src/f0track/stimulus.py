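"""Stimulus representations of continuous speech for f0-band EEG modeling.

Two features drive the models downstream:

* ``f1`` — the *fundamental waveform*: the speech signal band-pass
  filtered to the speaker's pitch range (5th..95th percentile of the
  voiced f0 distribution), so it oscillates at the instantaneous
  fundamental frequency.
* ``f2`` — the *high-frequency envelope modulation*: auditory-spectrogram
  channels with center frequencies above 300 Hz, each band-pass filtered
  in the same pitch range and averaged.  It carries the periodicity of
  the envelope of the higher harmonics.

Both are produced at the EEG sampling rate (1 kHz by default).

The auditory spectrogram here is a log-spaced band-pass filterbank with
half-wave rectification, 8 ms leaky integration and cube-root
compression, evaluated at 1 ms steps.  It is deliberately a simple,
fully documented front end exposing the only properties the pipeline
relies on (tonotopy and envelope extraction at millisecond resolution);
any cochlear model producing an (time, channel) energy array can be
substituted through the ``AuditorySpectrogram`` container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class NoPitchError(ValueError):
    """Raised when a pitch track contains no voiced frames."""


@dataclass
class PitchTrack:
    """Frame-wise fundamental-frequency estimates; NaN marks unvoiced frames."""

    times: np.ndarray
    f0: np.ndarray
    frame_step: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.times.shape != self.f0.shape:
            raise ValueError("times and f0 must have the same shape")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        voiced = self.f0[np.isfinite(self.f0)]
        if np.any(voiced <= 0):
            raise ValueError("defined f0 values must be positive")

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]


@dataclass(frozen=True)
class BandSpec:
    """Band-pass specification with explicit transition bandwidths."""

    f_lo: float
    f_hi: float
    lower_transition: float = 18.7
    upper_transition: float = 38.12
    window: str = "hamming"
    phase: str = "zero"

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"degenerate band ({self.f_lo}, {self.f_hi}) Hz")
        if self.lower_transition <= 0 or self.upper_transition <= 0:
            raise ValueError("transition bandwidths must be positive")
        if self.window != "hamming" or self.phase != "zero":
            raise ValueError("only hamming-window zero-phase design is supported")


DEFAULT_PITCH_BAND = BandSpec(75.0, 150.0)


@dataclass
class StimulusFeatures:
    """The two stimulus features, sampled at the EEG rate."""

    f1: np.ndarray
    f2: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        if self.f1.shape != self.f2.shape or self.f1.ndim != 1:
            raise ValueError("f1 and f2 must be 1-D and equally long")
        if not (np.all(np.isfinite(self.f1)) and np.all(np.isfinite(self.f2))):
            raise ValueError("stimulus features must be finite")

    @property
    def n_samples(self) -> int:
        return self.f1.size

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.f1, self.f2])


@dataclass
class AuditorySpectrogram:
    """Nonnegative energy per (time, channel) at millisecond resolution."""

    channel_cf: np.ndarray
    values: np.ndarray
    time_step: float = 0.001

    def __post_init__(self) -> None:
        self.channel_cf = np.asarray(self.channel_cf, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.channel_cf) <= 0):
            raise ValueError("channel center frequencies must be increasing")
        if self.values.shape[1] != self.channel_cf.size:
            raise ValueError("values must be (time, channel)")
        if np.any(self.values < -1e-12):
            raise ValueError("spectrogram energies must be nonnegative")


def pitch_band_from_percentiles(
    pitch: PitchTrack,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
    lower_transition: float = 18.7,
    upper_transition: float = 38.12,
) -> BandSpec:
    """Corner frequencies from percentiles of the voiced pitch distribution.

    Percentiles interpolate linearly between order statistics and are
    rounded to the nearest Hz.  A track with no voiced frames raises
    :class:`NoPitchError`; a zero-width band raises ``ValueError``.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    voiced = pitch.voiced_f0
    if voiced.size < 2:
        raise NoPitchError("pitch track has fewer than 2 voiced frames")
    f_lo, f_hi = np.percentile(voiced, [lo_pct, hi_pct], method="linear")
    f_lo, f_hi = round(float(f_lo)), round(float(f_hi))
    return BandSpec(f_lo, f_hi, lower_transition, upper_transition)


def design_bandpass_fir(band: BandSpec, fs: float) -> np.ndarray:
    """Linear-phase Hamming-window FIR band-pass kernel.

    The length follows the Hamming-window transition rule
    ``numtaps ~= 3.3 * fs / transition`` using the narrower (lower)
    transition band, rounded up to an odd count so the group delay is an
    integer number of samples.
    """
    if band.f_hi >= fs / 2:
        raise ValueError(f"band ({band.f_lo}, {band.f_hi}) invalid for fs={fs}")
    trans = min(band.lower_transition, band.upper_transition)
    numtaps = int(np.ceil(3.3 * fs / trans))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(
        numtaps, [band.f_lo, band.f_hi], window="hamming", pass_zero=False, fs=fs
    )


def apply_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR forward once, compensating the group delay."""
    x = np.asarray(x, dtype=float)
    delay = (taps.size - 1) // 2
    full = signal.oaconvolve(x, taps, mode="full")
    return full[delay : delay + x.size]


def extract_fundamental_waveform(
    audio: np.ndarray, fs_in: float, band: BandSpec, fs_out: float = 1000.0
) -> np.ndarray:
    """Band-pass the speech signal to the pitch range and resample.

    Zero-phase FIR filtering at the source rate, then polyphase
    anti-aliased resampling to ``fs_out``.  Output length is
    ``round(duration * fs_out)``.
    """
    audio = np.asarray(audio, dtype=float)
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio must be finite")
    if fs_in < 2 * band.f_hi:
        raise ValueError("source rate below twice the upper band edge")
    taps = design_bandpass_fir(band, fs_in)
    filtered = apply_zero_phase(audio, taps)
    n_out = int(round(audio.size / fs_in * fs_out))
    if fs_out == fs_in:
        return filtered[:n_out]
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    out = signal.resample_poly(filtered, frac.numerator, frac.denominator)
    if out.size < n_out:
        out = np.pad(out, (0, n_out - out.size))
    return out[:n_out]


def auditory_spectrogram(
    audio: np.ndarray,
    fs: float,
    n_channels: int = 128,
    cf_range: tuple[float, float] = (180.0, 7000.0),
    time_step: float = 0.001,
    integration_tau: float = 0.008,
) -> AuditorySpectrogram:
    """Filterbank approximation of the auditory periphery.

    Log-spaced 4th-order Butterworth band-pass channels with ERB-scale
    bandwidths (so closely spaced harmonics beat at the fundamental, as
    on the basilar membrane), half-wave rectification, single-pole leaky
    integration (8 ms) and cube-root compression, sampled every
    ``time_step`` seconds.
    """
    audio = np.asarray(audio, dtype=float)
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio must be finite")
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    lo, hi = cf_range
    if not (0 < lo < hi < fs / 2):
        raise ValueError("cf_range must lie within (0, Nyquist)")
    step = int(round(fs * time_step))
    if step < 1:
        raise ValueError("time_step below one sample")

    cfs = np.geomspace(lo, hi, n_channels)
    a_int = float(np.exp(-1.0 / (fs * integration_tau)))
    n_frames = audio.size // step
    values = np.empty((n_frames, n_channels))
    for k, cf in enumerate(cfs):
        # ERB-like bandwidth so unresolved harmonics beat at f0
        bw = 24.7 * (4.37 * cf / 1000.0 + 1.0)
        f1 = max(cf - bw / 2, 1.0)
        f2 = min(cf + bw / 2, 0.999 * fs / 2)
        sos = signal.butter(4, [f1, f2], btype="bandpass", fs=fs, output="sos")
        y = signal.sosfiltfilt(sos, audio)
        y = np.maximum(y, 0.0)
        y = signal.lfilter([1 - a_int], [1, -a_int], y)
        values[:, k] = np.cbrt(y[: n_frames * step : step])
    values = np.maximum(values, 0.0)
    return AuditorySpectrogram(cfs, values, time_step)


def extract_hf_envelope_modulation(
    spec: AuditorySpectrogram, band: BandSpec, cf_min: float = 300.0
) -> np.ndarray:
    """Average pitch-band-filtered spectrogram channels above ``cf_min``.

    Each qualifying channel is band-pass filtered with the same FIR
    design as the fundamental waveform (at the spectrogram frame rate)
    and the filtered channels are averaged.
    """
    keep = spec.channel_cf > cf_min
    if not np.any(keep):
        raise ValueError(f"no spectrogram channel above {cf_min} Hz")
    fs = 1.0 / spec.time_step
    taps = design_bandpass_fir(band, fs)
    # demean channels first: the FIR's tiny residual DC gain would
    # otherwise leak the large rectified-energy offset into the output
    sub = spec.values[:, keep]
    sub = sub - sub.mean(axis=0, keepdims=True)
    filtered = signal.fftconvolve(sub, taps[:, None], mode="full", axes=0)
    delay = (taps.size - 1) // 2
    filtered = filtered[delay : delay + sub.shape[0]]
    return filtered.mean(axis=1)


def compute_stimulus_features(
    audio: np.ndarray,
    fs_in: float,
    band: BandSpec,
    fs_out: float = 1000.0,
    n_channels: int = 128,
    cf_min: float = 300.0,
    cf_range: tuple[float, float] = (180.0, 7000.0),
) -> StimulusFeatures:
    """Full audio -> (f1, f2) front end at the EEG rate."""
    if cf_range[1] >= fs_in / 2:  # keep the filterbank below Nyquist
        cf_range = (cf_range[0], 0.45 * fs_in)
    f1 = extract_fundamental_waveform(audio, fs_in, band, fs_out)
    spec = auditory_spectrogram(
        audio, fs_in, n_channels=n_channels, cf_range=cf_range, time_step=1.0 / fs_out
    )
    f2 = extract_hf_envelope_modulation(spec, band, cf_min=cf_min)
    n = min(f1.size, f2.size)
    if abs(f1.size - f2.size) > 2:
        warnings.warn(f"f1/f2 length mismatch ({f1.size} vs {f2.size}); truncating")
    meta = {
        "band": (band.f_lo, band.f_hi),
        "fir": "hamming zero-phase",
        "resampling": "scipy.signal.resample_poly (polyphase, anti-aliased)",
        "spectrogram": f"{n_channels} log-spaced Butterworth channels, "
        f"cf {cf_range[0]}-{cf_range[1]} Hz, 8 ms leaky integration, cube-root",
    }
    return StimulusFeatures(f1[:n], f2[:n], fs_out, meta)


def track_pitch(
    audio: np.ndarray,
    fs: float,
    fmin: float = 60.0,
    fmax: float = 300.0,
    frame_step: float = 0.010,
    frame_len: float = 0.040,
    voicing_threshold: float = 0.45,
) -> PitchTrack:
    """Plain autocorrelation pitch tracker.

    Per frame, the normalized autocorrelation is searched for its
    maximum in the candidate lag range; a frame is voiced when that
    maximum exceeds ``voicing_threshold``.  Peak lag is refined by
    parabolic interpolation.  Precomputed tracks (e.g. from a dedicated
    pitch tool) can be supplied instead wherever a PitchTrack is needed.
    """
    audio = np.asarray(audio, dtype=float)
    step = int(round(fs * frame_step))
    win = int(round(fs * frame_len))
    lag_min = int(np.floor(fs / fmax))
    lag_max = int(np.ceil(fs / fmin))
    if lag_max >= win:
        raise ValueError("frame too short for fmin")
    times, f0s = [], []
    for start in range(0, audio.size - win, step):
        frame = audio[start : start + win]
        frame = frame - frame.mean()
        energy = float(frame @ frame)
        t = (start + win / 2) / fs
        times.append(t)
        if energy <= 0:
            f0s.append(np.nan)
            continue
        ac = signal.correlate(frame, frame, mode="full")[win - 1 :]
        ac = ac / ac[0]
        seg = ac[lag_min : lag_max + 1]
        k = int(np.argmax(seg))
        if seg[k] < voicing_threshold:
            f0s.append(np.nan)
            continue
        lag = lag_min + k
        if 0 < lag < ac.size - 1:  # parabolic refinement
            y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                lag = lag + 0.5 * (y0 - y2) / denom
        f0s.append(fs / lag)
    return PitchTrack(np.asarray(times), np.asarray(f0s), frame_step)
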