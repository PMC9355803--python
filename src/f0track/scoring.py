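"""Per-word neural-response strength from cross-validated decoders.

For every retained (voiced) word, each per-lambda decoder held out from
the word's fold reconstructs the stimulus features; Pearson's r over the
word's voiced samples is the raw score.  The null-corrected word score
is the difference of the per-word maxima over the regularization grid,

    r(i) = max_lambda r_model(i) - max_lambda r_null(i),

where the null decoders were trained on time-reversed features.  A
word's null score is the score the time-reversed pipeline assigns to it
(its mirrored window carries the word's own reversed features), which
keeps the voicing composition and length of the scored segment matched
between model and null.  The corrected scores are averaged across
subjects per word and standardized over words to form the population
response used as the regression target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import DecoderCV
from .lagged import standardize

MIN_WORD_SAMPLES = 20


@dataclass
class WordScoreTable:
    """Raw per-(word, subject, lambda) scores and derived summaries."""

    raw: pd.DataFrame        # word_index, subject, feature, lambda_n, kind, r
    corrected: pd.DataFrame  # word_index, subject, feature, r
    population: pd.DataFrame  # word_index, feature, score (standardized)


def _word_sample_indices(word_row: pd.Series, fs: float, voiced_only: bool = True):
    """Sample indices of one word within its recording part."""
    if voiced_only and word_row.get("voiced_intervals"):
        idx = []
        for s, e in word_row["voiced_intervals"]:
            idx.append(np.arange(int(round(s * fs)), int(round(e * fs))))
        return np.concatenate(idx) if idx else np.array([], dtype=int)
    return np.arange(int(round(word_row["onset"] * fs)), int(round(word_row["offset"] * fs)))


def score_words(
    cv: DecoderCV,
    words_per_part: list[pd.DataFrame],
    subject: int = 0,
    voiced_only: bool = True,
    min_samples: int = MIN_WORD_SAMPLES,
) -> pd.DataFrame:
    """Raw per-word reconstruction scores for one subject.

    ``cv`` must be a fitted :class:`DecoderCV`; words are scored with the
    decoders of the fold that held their part out, so no word is scored
    by a decoder trained on it.  Words without voiced samples, or
    shorter than ``min_samples``, are excluded/flagged.

    Returns a tidy frame: word_index, subject, feature, lambda_n, kind
    ('model'/'null'), r, n_samples, flagged_short.
    """
    fs = cv.fs
    n_lam = cv.lambda_grid.size
    frames = []
    for part, words in enumerate(words_per_part):
        if words.empty:
            continue
        word_idx_list, sample_idx, bounds = [], [], [0]
        for _, w in words.iterrows():
            if w.get("voiceless", False):
                continue
            idx = _word_sample_indices(w, fs, voiced_only)
            word_idx_list.append(int(w["word_index"]))
            sample_idx.append(idx)
            bounds.append(bounds[-1] + idx.size)
        if not word_idx_list:
            continue
        word_ids = np.asarray(word_idx_list)
        part_len = cv.part_lengths[part]
        truth_model = cv.truth(part, "model")
        for kind in ("model", "null"):
            recon, t_start = cv.reconstruct_part(part, kind)
            nv = recon.shape[1]
            if kind == "null":
                # the time-reversed pipeline places word i at its mirrored
                # window; flipping the null reconstruction back lets every
                # word be scored on its own samples against the actual
                # features, with matched voicing composition and length
                recon = recon[:, ::-1, :]
                t_start = part_len - t_start - nv
            truth_full = truth_model
            # clip each word's samples to the reconstructable range
            sel_parts, counts = [], np.empty(word_ids.size, dtype=int)
            for i, idx in enumerate(sample_idx):
                sel = idx[(idx >= t_start) & (idx < t_start + nv)]
                sel_parts.append(sel)
                counts[i] = sel.size
            keep = counts >= 3
            if not np.any(keep):
                continue
            starts = np.concatenate([[0], np.cumsum(counts[keep])[:-1]])
            flat = np.concatenate([s for s, k in zip(sel_parts, keep) if k])
            truth = truth_full[flat]                           # (L, 2)
            R = recon[:, flat - t_start, :]                    # (n_lam, L, 2)
            Rf = R.transpose(1, 0, 2).reshape(flat.size, -1)   # (L, n_lam*2)
            n = counts[keep].astype(float)[:, None]
            s_x = np.add.reduceat(Rf, starts, axis=0)
            s_xx = np.add.reduceat(Rf * Rf, starts, axis=0)
            s_y = np.add.reduceat(truth, starts, axis=0)
            s_yy = np.add.reduceat(truth * truth, starts, axis=0)
            prod = Rf * np.tile(truth, (1, n_lam))
            s_xy = np.add.reduceat(prod, starts, axis=0)
            var_x = s_xx - s_x**2 / n
            var_y = (s_yy - s_y**2 / n)                        # (W, 2)
            var_y_full = np.tile(var_y, (1, n_lam))
            s_y_full = np.tile(s_y, (1, n_lam))
            cov = s_xy - s_x * s_y_full / n
            with np.errstate(invalid="ignore", divide="ignore"):
                den = np.sqrt(var_x * var_y_full)
                r = np.where(den > 0, cov / np.where(den > 0, den, 1.0), np.nan)
            W = int(keep.sum())
            r3 = r.reshape(W, n_lam, 2)
            frames.append(
                pd.DataFrame(
                    {
                        "word_index": np.repeat(word_ids[keep], n_lam * 2),
                        "subject": subject,
                        "feature": np.tile(np.tile([0, 1], n_lam), W),
                        "lambda_n": np.tile(np.repeat(cv.lambda_grid, 2), W),
                        "kind": kind,
                        "r": r3.ravel(),
                        "n_samples": np.repeat(counts[keep], n_lam * 2),
                        "flagged_short": np.repeat(counts[keep] < min_samples, n_lam * 2),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["word_index", "subject", "feature", "lambda_n", "kind", "r",
                     "n_samples", "flagged_short"]
        )
    return pd.concat(frames, ignore_index=True)


def corrected_word_score(model_scores: np.ndarray, null_scores: np.ndarray) -> float:
    """max over lambda of model minus max over lambda of null.

    The two maxima may occur at different lambda; non-finite entries are
    excluded; the result may be negative.  All-non-finite input raises.
    """
    m = np.asarray(model_scores, dtype=float)
    n = np.asarray(null_scores, dtype=float)
    if m.size == 0 or n.size == 0:
        raise ValueError("need nonempty score lists")
    m = m[np.isfinite(m)]
    n = n[np.isfinite(n)]
    if m.size == 0 or n.size == 0:
        raise ValueError("all scores non-finite; word must be dropped")
    return float(m.max() - n.max())


def correct_scores(raw: pd.DataFrame, fixed_lambda: float | None = None) -> pd.DataFrame:
    """Per-(word, subject, feature) null-corrected scores.

    With ``fixed_lambda`` the maxima are replaced by the score at that
    lambda_n for both model and null (the fixed-regularization control).
    """
    df = raw
    if fixed_lambda is not None:
        lam = df["lambda_n"].unique()
        nearest = lam[np.argmin(np.abs(np.log10(lam) - np.log10(fixed_lambda)))]
        df = df[df["lambda_n"] == nearest]
    grouped = (
        df.groupby(["word_index", "subject", "feature", "kind"])["r"].max().unstack("kind")
    )
    grouped = grouped.dropna(subset=["model", "null"])
    out = (grouped["model"] - grouped["null"]).rename("r").reset_index()
    return out


def population_scores(corrected: pd.DataFrame) -> pd.DataFrame:
    """Subject-averaged, standardized per-word scores, per feature.

    Words missing in some subjects are averaged over the subjects that
    have them (the count is kept).  Standardization (zero mean, unit sd)
    is over the retained words, separately per feature.
    """
    agg = (
        corrected.groupby(["word_index", "feature"])["r"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "raw_score", "count": "n_subjects"})
    )
    out = []
    for j, sub in agg.groupby("feature"):
        sub = sub.copy()
        sub["score"] = standardize(sub["raw_score"].to_numpy())
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def word_score_table(
    raw: pd.DataFrame, fixed_lambda: float | None = None
) -> WordScoreTable:
    corrected = correct_scores(raw, fixed_lambda)
    return WordScoreTable(raw, corrected, population_scores(corrected))
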