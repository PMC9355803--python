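"""Synthetic speech-like stimuli, word streams and EEG with planted truth.

Everything the pipeline consumes can be generated here with exact ground
truth: a voiced/unvoiced stimulus whose per-word fundamental frequency,
voicing and linguistic statistics are known; multichannel EEG built as a
lagged linear response to the stimulus features through known kernels;
and a planted linear modulation of the per-word response gain by the
(correlated) word features.

Word features are drawn through a Gaussian copula: correlated normal
scores (empirically recolored so the Gaussian correlation matches the
target exactly) are pushed through monotone marginal transforms whose
induced Pearson correlations are corrected analytically for normal and
lognormal marginals.  The interaction feature is by default derived as
precision * surprisal, as its definition requires; sampling it as a
seventh copula coordinate is available for correlation-structure checks.

EEG generation: channel c = sum_j w_c * conv(gain(t) * f_j(t), k_j) +
noise, with Gaussian-windowed band-limited-pulse kernels (defaults peak
at 11 ms for the fundamental waveform and 18 ms, double amplitude, for
the envelope modulation, matching the latencies and magnitude ratio the
models are meant to recover; the pulse band is flat across the f0 range
so response gain does not depend on a word's pitch), zero-sum channel
weights and Gaussian noise filtered to the 50-280 Hz analysis band so
the SNR is meaningful post-filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .stimulus import BandSpec, PitchTrack, StimulusFeatures, apply_zero_phase, design_bandpass_fir
from .words import ENTROPY_CLAMP, FEATURE_ORDER, TabularProbabilitySource

EEG_BAND = BandSpec(50.0, 280.0, lower_transition=12.5, upper_transition=70.0)


# ------------------------------------------------------------------ toy LM

@dataclass
class ToyLanguageModel:
    """First-order Markov chain over a small vocabulary.

    The conditional next-word distribution is the transition row of the
    previous word, so per-position surprisal and entropy have closed
    forms — exact ground truth for the information features.
    """

    vocabulary: list[str]
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        K = len(self.vocabulary)
        if self.transition.shape != (K, K):
            raise ValueError("transition must be KxK")
        if np.any(self.transition < 0) or not np.allclose(self.transition.sum(1), 1, atol=1e-9):
            raise ValueError("rows must be probability distributions")

    @property
    def stationary(self) -> np.ndarray:
        """pi with pi P = pi (left Perron eigenvector, normalized)."""
        w, V = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(w - 1)))
        pi = np.real(V[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def row_entropy(self, state: int) -> float:
        p = self.transition[state]
        nz = p[p > 0]
        return float(-(nz * np.log(nz)).sum())

    @property
    def entropy_rate(self) -> float:
        pi = self.stationary
        return float(sum(pi[i] * self.row_entropy(i) for i in range(len(pi))))

    @classmethod
    def uniform(cls, k: int) -> "ToyLanguageModel":
        vocab = [f"w{i}" for i in range(k)]
        return cls(vocab, np.full((k, k), 1.0 / k))

    @classmethod
    def random(cls, k: int, seed: int, concentration: float = 1.0) -> "ToyLanguageModel":
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.full(k, concentration), size=k)
        return cls([f"w{i}" for i in range(k)], P)


def generate_word_stream(lm: ToyLanguageModel, n_words: int, seed: int) -> pd.DataFrame:
    """Sample a token sequence with exact per-word information values.

    The first word is drawn from the stationary distribution (surprisal
    and entropy from it); later words from the previous word's
    transition row.  Precision is 1/entropy with the standard clamp, and
    the clamp is flagged.
    """
    rng = np.random.default_rng(seed)
    pi = lm.stationary
    K = len(lm.vocabulary)
    states = np.empty(n_words, dtype=int)
    surprisal = np.empty(n_words)
    entropy = np.empty(n_words)
    p_cond = np.empty(n_words)
    nz = pi[pi > 0]
    ent0 = float(-(nz * np.log(nz)).sum())
    states[0] = rng.choice(K, p=pi)
    p_cond[0] = pi[states[0]]
    entropy[0] = ent0
    for i in range(1, n_words):
        row = lm.transition[states[i - 1]]
        states[i] = rng.choice(K, p=row)
        p_cond[i] = row[states[i]]
        entropy[i] = lm.row_entropy(states[i - 1])
    surprisal = -np.log(p_cond)
    clamped = entropy < ENTROPY_CLAMP
    precision = 1.0 / np.maximum(entropy, ENTROPY_CLAMP)
    p_uni = pi[states]
    return pd.DataFrame(
        {
            "token": [lm.vocabulary[s] for s in states],
            "state": states,
            "p_conditional": p_cond,
            "p_unigram": p_uni,
            "surprisal": surprisal,
            "entropy": entropy,
            "precision": precision,
            "entropy_clamped": clamped,
            "inv_freq": -np.log(p_uni),
            "interaction": precision * surprisal,
        }
    )


# ------------------------------------------------- correlated word features

#: Target pairwise Pearson correlations of the seven features, in
#: FEATURE_ORDER.  The large entries reproduce the structure observed in
#: natural story material (surprisal with its interaction and with
#: inverted frequency and voiced duration; inverted frequency with
#: voiced duration); the rate of f0 change is nearly uncorrelated with
#: everything except a weak link to inverted frequency.
DEFAULT_FEATURE_CORRELATION = np.array(
    [
        # f0    rate   vdur   ifrq   prec   surp   inter
        [1.000, 0.050, 0.050, 0.000, 0.000, 0.050, 0.050],
        [0.050, 1.000, 0.050, 0.129, 0.000, 0.050, 0.050],
        [0.050, 0.050, 1.000, 0.632, -0.050, 0.406, 0.300],
        [0.000, 0.129, 0.632, 1.000, -0.050, 0.431, 0.300],
        [0.000, 0.000, -0.050, -0.050, 1.000, -0.157, 0.274],
        [0.050, 0.050, 0.406, 0.431, -0.157, 1.000, 0.632],
        [0.050, 0.050, 0.300, 0.300, 0.274, 0.632, 1.000],
    ]
)

#: Marginal distributions: ("normal", mean, sd) or ("lognormal", mu, sigma)
#: with mu/sigma on the log scale.
DEFAULT_MARGINALS = {
    "mean_f0": ("normal", 107.2, 24.8),
    "f0_rate": ("lognormal", np.log(40.0), 0.5),
    "voiced_duration": ("lognormal", np.log(0.19) - 0.4**2 / 2, 0.4),
    "inv_freq": ("normal", 5.0, 1.5),
    "precision": ("lognormal", np.log(0.5), 0.4),
    "surprisal": ("lognormal", np.log(5.0), 0.5),
    "interaction": ("lognormal", np.log(2.5), 0.6),
}


def _nearest_psd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, 1e-6)
    M2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(M2))
    return M2 / np.outer(d, d)


def _gauss_rho_for_pearson(r: float, m1, m2) -> float:
    """Gaussian-copula correlation producing Pearson r after transforms."""
    k1, _, s1 = m1
    k2, _, s2 = m2
    if k1 == "normal" and k2 == "normal":
        rho = r
    elif k1 == "lognormal" and k2 == "lognormal":
        v1, v2 = np.expm1(s1**2), np.expm1(s2**2)
        arg = 1.0 + r * np.sqrt(v1 * v2)
        rho = np.log(max(arg, 1e-12)) / (s1 * s2)
    else:  # one normal, one lognormal
        s = s1 if k1 == "lognormal" else s2
        rho = r * np.sqrt(np.expm1(s**2)) / s
    return float(np.clip(rho, -0.999, 0.999))


def _transform_marginal(z: np.ndarray, m) -> np.ndarray:
    kind, a, b = m
    if kind == "normal":
        return a + b * z
    if kind == "lognormal":
        return np.exp(a + b * z)
    raise ValueError(f"unknown marginal {kind}")


def correlated_word_features(
    n_words: int,
    target_corr: np.ndarray | None = None,
    seed: int = 0,
    sample_all: bool = False,
    marginals: dict | None = None,
) -> pd.DataFrame:
    """Gaussian-copula sample of the seven word features.

    The empirical correlation of the underlying Gaussian scores is
    forced to the (Pearson-corrected) target by whitening and
    recoloring, so large samples reproduce ``target_corr`` closely.
    With ``sample_all=False`` (default) the interaction column is
    computed as precision * surprisal; with ``sample_all=True`` all
    seven coordinates are sampled from the copula.
    """
    if target_corr is None:
        target_corr = DEFAULT_FEATURE_CORRELATION
    marginals = marginals or DEFAULT_MARGINALS
    names = list(FEATURE_ORDER) if sample_all else list(FEATURE_ORDER[:-1])
    d = len(names)
    idx = [FEATURE_ORDER.index(nm) for nm in names]
    R = np.asarray(target_corr, dtype=float)[np.ix_(idx, idx)]
    # convert target Pearson to Gaussian-score correlations
    rho = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            rho[i, j] = rho[j, i] = _gauss_rho_for_pearson(
                R[i, j], marginals[names[i]], marginals[names[j]]
            )
    rho = _nearest_psd(rho)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_words, d))
    z = (z - z.mean(0)) / z.std(0)
    emp = np.corrcoef(z, rowvar=False)
    z = z @ np.linalg.inv(np.linalg.cholesky(emp)).T
    z = z @ np.linalg.cholesky(rho).T
    data = {
        nm: _transform_marginal(z[:, k], marginals[nm]) for k, nm in enumerate(names)
    }
    df = pd.DataFrame(data)
    if not sample_all:
        df["interaction"] = df["precision"] * df["surprisal"]
    df["mean_f0"] = np.clip(df["mean_f0"], 60.0, 180.0)
    df["voiced_duration"] = np.clip(df["voiced_duration"], 0.04, 2.0)
    return df[list(FEATURE_ORDER)]


def probability_source_from_features(features: pd.DataFrame) -> TabularProbabilitySource:
    """Back out a per-position probability table from planted features.

    ``p_cond = exp(-surprisal)``, ``entropy = 1/precision``,
    ``p_unigram = exp(-inv_freq)`` — so the information features
    recomputed through the standard interface reproduce the planted
    values exactly.
    """
    return TabularProbabilitySource(
        np.exp(-features["inv_freq"].to_numpy()),
        np.exp(-features["surprisal"].to_numpy()),
        1.0 / features["precision"].to_numpy(),
    )


# ------------------------------------------------------------ spec & stimulus

@dataclass(frozen=True)
class KernelSpec:
    """Planted response kernel: a Gaussian-windowed band-limited pulse.

    The pulse's pass band is chosen much wider than the f0 range so the
    response gain is flat across word pitches — a word's reconstruction
    quality then depends on its planted gain, not incidentally on its
    fundamental frequency.  ``width_ms`` is the Gaussian envelope sigma;
    with the default 6 ms the gain varies by < 2% over 60-180 Hz.
    """

    peak_ms: float
    width_ms: float
    amplitude: float
    band: tuple[float, float] = (10.0, 480.0)


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic twin of the experiment.

    Defaults mirror the recorded material: f0 around 107.2 Hz with
    24.8 Hz spread across words (5th..95th percentiles near 75/150 Hz),
    mean word duration 0.26 s, response kernels peaking at 11 ms
    (fundamental waveform) and 18 ms with twice the amplitude (envelope
    modulation), and EEG noise confined to the 50-280 Hz analysis band.
    """

    n_words: int = 500
    n_parts: int = 5
    n_subjects: int = 5
    n_channels: int = 8
    fs: float = 1000.0
    f0_base: float = 107.2
    f0_jitter: float = 24.8
    harmonics: tuple[int, ...] = (1, 3, 4, 5, 6, 7, 8)
    word_pad: float = 0.07     # unvoiced padding inside a word, seconds
    word_gap: float = 0.06     # silent gap between words, seconds
    lead_in: float = 0.5       # silence at each part boundary, seconds
    kernels: tuple[KernelSpec, KernelSpec] = (
        KernelSpec(11.0, 6.0, 1.0),
        KernelSpec(18.0, 6.0, 2.0),
    )
    modulation_betas: np.ndarray = field(default_factory=lambda: np.zeros(7))
    feature_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_FEATURE_CORRELATION.copy()
    )
    snr_db: float = 0.0
    background_level: float = 0.05  # unvoiced background RMS re voiced amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        self.modulation_betas = np.asarray(self.modulation_betas, dtype=float)
        if self.modulation_betas.size != 7:
            raise ValueError("modulation_betas must have 7 entries")
        for k in self.kernels:
            if k.peak_ms < 0:
                raise ValueError("kernel peaks must be causal")


def _layout_words(features: pd.DataFrame, spec: SyntheticSpec, rng) -> pd.DataFrame:
    """Assign parts, onsets, offsets and voiced intervals (part-relative)."""
    n = len(features)
    words = features.copy()
    words["word_index"] = np.arange(n)
    part_of = np.minimum((np.arange(n) * spec.n_parts) // n, spec.n_parts - 1)
    words["part"] = part_of
    pads = spec.word_pad * rng.lognormal(0.0, 0.3, size=n)
    gaps = spec.word_gap * rng.lognormal(0.0, 0.3, size=n)
    onsets = np.empty(n)
    offsets = np.empty(n)
    voiced = []
    t = spec.lead_in
    prev_part = 0
    for i in range(n):
        if part_of[i] != prev_part:
            t = spec.lead_in
            prev_part = part_of[i]
        vdur = float(words["voiced_duration"].iloc[i])
        onsets[i] = t
        v0 = t + pads[i] / 2
        voiced.append([(v0, v0 + vdur)])
        offsets[i] = t + vdur + pads[i]
        t = offsets[i] + gaps[i]
    words["onset"] = onsets
    words["offset"] = offsets
    words["voiced_intervals"] = voiced
    words["voiceless"] = False
    return words


def _f0_course(words_part: pd.DataFrame, n: int, fs: float, rng) -> np.ndarray:
    """Instantaneous f0 (NaN where unvoiced) over one part."""
    f0 = np.full(n, np.nan)
    for _, w in words_part.iterrows():
        (v0, v1) = w["voiced_intervals"][0]
        i0, i1 = int(round(v0 * fs)), min(int(round(v1 * fs)), n)
        if i1 <= i0:
            continue
        tt = (np.arange(i0, i1) - (i0 + i1) / 2) / fs
        slope = float(w["f0_rate"]) * (1 if rng.random() < 0.5 else -1)
        f0[i0:i1] = np.clip(w["mean_f0"] + slope * tt, 60.0, 180.0)
    return f0


def _render_features(
    words_part: pd.DataFrame, duration: float, spec: SyntheticSpec, rng
) -> tuple[StimulusFeatures, PitchTrack]:
    """Directly synthesize (f1, f2) at the EEG rate for one part.

    Voiced spans carry the pitch oscillation with 10 ms onset/offset
    ramps; unvoiced stretches carry low-level band-limited background
    (``spec.background_level`` relative RMS), as band-pass filtering
    real recordings leaves — exact digital silence would make the
    time-reversed null scoring degenerate over mirrored gaps.
    """
    fs = spec.fs
    n = int(round(duration * fs))
    f0 = _f0_course(words_part, n, fs, rng)
    voiced = np.isfinite(f0)
    inst = np.where(voiced, f0, 0.0)
    phase = 2 * np.pi * np.cumsum(inst) / fs
    ramp_len = int(round(0.010 * fs))
    taper = np.ones(n)
    edges = np.flatnonzero(np.diff(voiced.astype(int)))
    for e in edges:
        lo, hi = max(e - ramp_len, 0), min(e + ramp_len, n)
        ramp = 0.5 - 0.5 * np.cos(np.linspace(0, np.pi, hi - lo))
        taper[lo:hi] = ramp if voiced[min(e + 1, n - 1)] else ramp[::-1]
    f1 = np.where(voiced, np.sin(phase), 0.0) * taper
    f2 = np.zeros(n)
    for _, w in words_part.iterrows():
        (v0, v1) = w["voiced_intervals"][0]
        i0, i1 = int(round(v0 * fs)), min(int(round(v1 * fs)), n)
        if i1 <= i0:
            continue
        phi = rng.uniform(0, 2 * np.pi)
        f2[i0:i1] = np.sin(phase[i0:i1] + phi) * taper[i0:i1]
    if spec.background_level > 0:
        taps = design_bandpass_fir(BandSpec(60.0, 180.0, 18.7, 38.12), fs)
        for arr in (f1, f2):
            bg = apply_zero_phase(rng.standard_normal(n), taps)
            bg *= spec.background_level / max(bg.std(), 1e-12)
            arr += bg
    # exact pitch track at 10 ms frames
    step = 0.010
    frames = np.arange(step / 2, duration, step)
    fi = np.minimum((frames * fs).astype(int), n - 1)
    track_f0 = np.where(voiced[fi], f0[fi], np.nan)
    pitch = PitchTrack(frames, track_f0, step)
    return StimulusFeatures(f1, f2, fs), pitch


def synthesize_features(
    words: pd.DataFrame, spec: SyntheticSpec, seed: int
) -> tuple[list[StimulusFeatures], list[PitchTrack], list[pd.DataFrame]]:
    """Per-part stimulus features, pitch tracks and alignments."""
    rng = np.random.default_rng(seed)
    feats, pitches, aligns = [], [], []
    for part in range(spec.n_parts):
        wp = words[words["part"] == part]
        duration = float(wp["offset"].max()) + spec.lead_in
        f, p = _render_features(wp, duration, spec, rng)
        feats.append(f)
        pitches.append(p)
        aligns.append(wp.reset_index(drop=True))
    return feats, pitches, aligns


def synthesize_stimulus(
    words: pd.DataFrame, spec: SyntheticSpec, seed: int, fs_audio: float = 8000.0
) -> tuple[np.ndarray, PitchTrack, pd.DataFrame]:
    """Audio-rate harmonic-complex rendering of one part's words.

    Voiced spans carry a harmonic complex (orders ``spec.harmonics``,
    amplitude 1/h) at the word's f0 trajectory; gaps are silent.  Used
    to exercise the audio front end; returns the exact pitch track and
    alignment alongside.
    """
    rng = np.random.default_rng(seed)
    wp = words[words["part"] == words["part"].min()]
    duration = float(wp["offset"].max()) + spec.lead_in
    n = int(round(duration * fs_audio))
    f0 = _f0_course(wp, n, fs_audio, rng)
    voiced = np.isfinite(f0)
    inst = np.where(voiced, f0, 0.0)
    phase = 2 * np.pi * np.cumsum(inst) / fs_audio
    audio = np.zeros(n)
    nyq = fs_audio / 2
    for h in spec.harmonics:
        ok = voiced & (inst * h < 0.95 * nyq)
        audio[ok] += np.sin(h * phase[ok]) / h
    step = 0.010
    frames = np.arange(step / 2, duration, step)
    fi = np.minimum((frames * fs_audio).astype(int), n - 1)
    pitch = PitchTrack(frames, np.where(voiced[fi], f0[fi], np.nan), step)
    return audio, pitch, wp.reset_index(drop=True)


def _response_kernel(k: KernelSpec, fs: float) -> np.ndarray:
    sigma = k.width_ms / 1000.0
    peak = k.peak_ms / 1000.0
    t = np.arange(0.0, peak + 5 * sigma, 1.0 / fs) - peak
    f_lo, f_hi = k.band
    pulse = (f_hi * np.sinc(2 * f_hi * t) - f_lo * np.sinc(2 * f_lo * t)) / (f_hi - f_lo)
    return k.amplitude * np.exp(-(t**2) / (2 * sigma**2)) * pulse


def word_gains(features: pd.DataFrame, betas: np.ndarray) -> np.ndarray:
    """Planted per-word response gain: 1 + standardized features @ betas."""
    from .lagged import standardize

    X = standardize(features[list(FEATURE_ORDER)].to_numpy(dtype=float))
    g = 1.0 + X @ np.asarray(betas, dtype=float)
    if np.any(g <= 0):
        warnings.warn(f"{int((g <= 0).sum())} word gains <= 0 clipped at 0.1")
        g = np.maximum(g, 0.1)
    return g


def simulate_eeg(
    features: StimulusFeatures,
    words_part: pd.DataFrame,
    spec: SyntheticSpec,
    subject_seed: int,
    gains: np.ndarray | None = None,
) -> np.ndarray:
    """One part's multichannel EEG with a planted lagged response.

    Each channel is the sum over stimulus features of the convolution of
    the gain-modulated feature with that feature's kernel, scaled by the
    channel's topography weight, plus band-limited Gaussian noise at
    ``spec.snr_db``.  ``gains`` holds one gain per word (indexed by
    ``word_index``); omitted gains default to 1.
    """
    rng = np.random.default_rng(subject_seed)
    fs = spec.fs
    n = features.n_samples
    gain_signal = np.ones(n)
    if gains is not None:
        for _, w in words_part.iterrows():
            g = gains[int(w["word_index"])]
            i0 = int(round(w["onset"] * fs))
            i1 = min(int(round(w["offset"] * fs)), n)
            gain_signal[i0:i1] = g
    C = spec.n_channels
    base = np.array([1.0, -1.0, 0.8, -0.8, 0.6, -0.6, 0.4, -0.4])
    weights = np.resize(base, C)
    sig = np.zeros((n, C))
    F = features.as_array()
    for j, kspec in enumerate(spec.kernels):
        kern = _response_kernel(kspec, fs)
        drive = gain_signal * F[:, j]
        conv = signal.fftconvolve(drive, kern)[:n]
        sig += conv[:, None] * weights[None, :]
    sig_sd = sig.std(axis=0)
    noise = rng.standard_normal((n, C))
    taps = design_bandpass_fir(EEG_BAND, fs)
    noise = np.column_stack([apply_zero_phase(noise[:, c], taps) for c in range(C)])
    noise /= noise.std(axis=0)
    if np.all(sig_sd == 0):
        return noise
    target_noise_sd = sig_sd / (10 ** (spec.snr_db / 20.0))
    return sig + noise * target_noise_sd[None, :]


# ------------------------------------------------------------------ bundles

@dataclass
class SyntheticDataset:
    """Everything one simulated experiment produces, plus ground truth."""

    spec: SyntheticSpec
    words: pd.DataFrame                      # global table with features & layout
    feature_parts: list[StimulusFeatures]
    pitch_parts: list[PitchTrack]
    words_per_part: list[pd.DataFrame]
    eeg_parts_per_subject: list[list[np.ndarray]]
    gains: np.ndarray
    ground_truth: dict


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full simulated experiment at the spec's study conditions."""
    rng = np.random.default_rng(spec.seed)
    feats = correlated_word_features(
        spec.n_words, spec.feature_correlation, seed=int(rng.integers(2**31))
    )
    words = _layout_words(feats, spec, rng)
    feature_parts, pitch_parts, words_per_part = synthesize_features(
        words, spec, seed=int(rng.integers(2**31))
    )
    gains = word_gains(words, spec.modulation_betas)
    eegs = []
    for s in range(spec.n_subjects):
        subject_parts = [
            simulate_eeg(
                feature_parts[p],
                words_per_part[p],
                spec,
                subject_seed=int(rng.integers(2**31)),
                gains=gains,
            )
            for p in range(spec.n_parts)
        ]
        eegs.append(subject_parts)
    truth = {
        "modulation_betas": spec.modulation_betas.tolist(),
        "kernel_peaks_ms": [k.peak_ms for k in spec.kernels],
        "kernel_amplitudes": [k.amplitude for k in spec.kernels],
        "snr_db": spec.snr_db,
        "seed": spec.seed,
    }
    return SyntheticDataset(
        spec, words, feature_parts, pitch_parts, words_per_part, eegs, gains, truth
    )
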