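"""Word-level acoustic and linguistic predictors.

Each word is described by seven features.  Three are acoustic, computed
from the pitch track over the word's voiced part: mean fundamental
frequency, rate of f0 change (mean absolute first derivative of the f0
course) and voiced duration.  Four are information-theoretic, computed
in nats from a language-model probability source: inverted word
frequency -ln P(w), surprisal -ln P(w_n | context), precision
1 / E(w_n) with E the conditional next-word entropy, and the
precision x surprisal interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import PitchTrack
from .trf import by_correct

FEATURE_ORDER = (
    "mean_f0",
    "f0_rate",
    "voiced_duration",
    "inv_freq",
    "precision",
    "surprisal",
    "interaction",
)

ENTROPY_CLAMP = 1e-6  # nats; lower bound on E before inverting


class VoicelessWordError(ValueError):
    """Raised for words whose span contains no voiced pitch frames."""


@dataclass
class WordRecord:
    """One word's boundaries, voicing and features.

    Intervals are half-open ``[onset, offset)`` seconds; voiced intervals
    must lie within the word and not overlap.
    """

    word: str
    onset: float
    offset: float
    voiced_intervals: list[tuple[float, float]] = field(default_factory=list)
    mean_f0: float | None = None
    f0_rate: float | None = None
    voiced_duration: float | None = None
    inv_freq: float | None = None
    surprisal: float | None = None
    precision: float | None = None
    interaction: float | None = None

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("onset must precede offset")
        prev_end = self.onset
        for s, e in sorted(self.voiced_intervals):
            if s < prev_end - 1e-9 or e > self.offset + 1e-9 or e <= s:
                raise ValueError("voiced intervals must be disjoint and inside the word")
            prev_end = e


class LanguageProbabilitySource:
    """Per-position word probabilities from any language model.

    Concrete sources must provide, for each word position, the realized
    word's unconditional probability, its conditional probability given
    the preceding context, and the entropy of the conditional next-word
    distribution.  The model that produces them (n-gram counts, an RNN,
    a Markov chain...) is outside this interface.
    """

    def unigram_prob(self, position: int) -> float:
        raise NotImplementedError

    def conditional_prob(self, position: int) -> float:
        raise NotImplementedError

    def entropy(self, position: int) -> float:
        raise NotImplementedError

    def __len__(self) -> int:
        raise NotImplementedError


class TabularProbabilitySource(LanguageProbabilitySource):
    """Probabilities precomputed per position (CSV-friendly)."""

    def __init__(self, p_unigram: np.ndarray, p_conditional: np.ndarray, entropies: np.ndarray):
        self.p_uni = np.asarray(p_unigram, dtype=float)
        self.p_cond = np.asarray(p_conditional, dtype=float)
        self.ent = np.asarray(entropies, dtype=float)
        if not (self.p_uni.shape == self.p_cond.shape == self.ent.shape):
            raise ValueError("per-position arrays must align")

    def unigram_prob(self, position: int) -> float:
        return float(self.p_uni[position])

    def conditional_prob(self, position: int) -> float:
        return float(self.p_cond[position])

    def entropy(self, position: int) -> float:
        return float(self.ent[position])

    def __len__(self) -> int:
        return self.p_uni.size


def distribution_entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats; 0 * ln 0 = 0; distribution must sum to 1."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("not a probability distribution")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def information_features(
    source: LanguageProbabilitySource, position: int, clamp: float = ENTROPY_CLAMP
) -> tuple[float, float, float, float, bool]:
    """(inv_freq, surprisal, precision, interaction, entropy_clamped).

    All in nats.  A zero realized-word probability is an error (the
    source's smoothing contract should prevent it); entropy below the
    clamp is clamped before inversion and flagged.
    """
    p_uni = source.unigram_prob(position)
    p_cond = source.conditional_prob(position)
    if p_uni <= 0 or p_cond <= 0:
        raise ValueError(f"zero probability for realized word at position {position}")
    ent = source.entropy(position)
    if ent < 0:
        raise ValueError("negative entropy")
    clamped = ent < clamp
    precision = 1.0 / max(ent, clamp)
    inv_freq = -np.log(p_uni)
    surprisal = -np.log(p_cond)
    return float(inv_freq), float(surprisal), float(precision), float(precision * surprisal), clamped


def acoustic_features(pitch: PitchTrack, word: WordRecord) -> tuple[float, float, float]:
    """(mean_f0 Hz, f0_rate Hz/s, voiced_duration s) for one word.

    Pitch frames are assigned by frame-center time to the half-open word
    interval; only voiced frames count.  The f0 derivative is averaged
    over consecutive voiced frame pairs within the same voiced interval
    (no difference is taken across unvoiced gaps).
    """
    t = pitch.times
    in_word = (t >= word.onset) & (t < word.offset)
    voiced = in_word & pitch.voiced
    if word.voiced_intervals:
        interval_id = np.full(t.size, -1)
        for k, (s, e) in enumerate(word.voiced_intervals):
            interval_id[(t >= s) & (t < e)] = k
        voiced = voiced & (interval_id >= 0)
        duration = float(sum(e - s for s, e in word.voiced_intervals))
    else:
        # derive contiguity from the frame grid itself
        interval_id = np.cumsum(np.concatenate([[0], (np.diff(voiced.astype(int)) == 1)]))
        duration = float(voiced.sum() * pitch.frame_step)
    if not np.any(voiced):
        raise VoicelessWordError(f"word {word.word!r} has no voiced frames")
    f0 = pitch.f0[voiced]
    mean_f0 = float(f0.mean())
    tv = t[voiced]
    iv = interval_id[voiced]
    same = iv[1:] == iv[:-1]
    if np.any(same):
        rates = np.abs(np.diff(f0) / np.diff(tv))[same]
        f0_rate = float(rates.mean())
    else:
        f0_rate = 0.0
    return mean_f0, f0_rate, duration


def compute_word_features(
    words: list[WordRecord],
    pitch: PitchTrack,
    source: LanguageProbabilitySource | None = None,
) -> pd.DataFrame:
    """Fill all seven features; voiceless words are flagged, not dropped.

    Returns a frame with one row per word, the seven ``FEATURE_ORDER``
    columns, and a boolean ``voiceless`` column for downstream exclusion.
    """
    rows = []
    for i, w in enumerate(words):
        row: dict = {"word_index": i, "word": w.word, "onset": w.onset, "offset": w.offset}
        try:
            m, r, d = acoustic_features(pitch, w)
            row.update(mean_f0=m, f0_rate=r, voiced_duration=d, voiceless=False)
        except VoicelessWordError:
            row.update(mean_f0=np.nan, f0_rate=np.nan, voiced_duration=0.0, voiceless=True)
        if source is not None:
            inv_f, s, p, inter, clamped = information_features(source, i)
            row.update(
                inv_freq=inv_f, surprisal=s, precision=p, interaction=inter,
                entropy_clamped=clamped,
            )
        elif w.inv_freq is not None:
            row.update(
                inv_freq=w.inv_freq, surprisal=w.surprisal,
                precision=w.precision, interaction=w.interaction,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def feature_correlation_matrix(features: pd.DataFrame) -> dict:
    """Pairwise Pearson correlations of the seven word features.

    Returns the 7x7 matrix, raw and Benjamini-Yekutieli corrected
    p-values for the 21 off-diagonal pairs, and a significance mask
    (p_fdr < 0.05).  Constant features yield undefined correlations,
    reported as NaN and masked.
    """
    cols = [c for c in FEATURE_ORDER if c in features.columns]
    if len(cols) < 2:
        raise ValueError("need at least two feature columns")
    X = features[cols].to_numpy(dtype=float)
    X = X[np.all(np.isfinite(X), axis=1)]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 complete records")
    k = len(cols)
    r = np.eye(k)
    p_raw = np.full((k, k), np.nan)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            if X[:, i].std() == 0 or X[:, j].std() == 0:
                r[i, j] = r[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = rr
            p_raw[i, j] = p_raw[j, i] = pp
            pairs.append((i, j, pp))
    p_fdr = np.full((k, k), np.nan)
    if pairs:
        adj = by_correct(np.array([p for _, _, p in pairs]))
        for (i, j, _), a in zip(pairs, adj):
            p_fdr[i, j] = p_fdr[j, i] = a
    mask = np.zeros((k, k), dtype=bool)
    with np.errstate(invalid="ignore"):
        mask[np.isfinite(p_fdr)] = p_fdr[np.isfinite(p_fdr)] < 0.05
    return {"features": cols, "r": r, "p_raw": p_raw, "p_fdr": p_fdr, "significant": mask}
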