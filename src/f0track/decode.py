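"""Backward (decoding) models: stimulus reconstruction from lagged EEG.

Each stimulus feature is reconstructed as

    f_j(t) = sum_tau sum_c beta(tau, c, j) * r(t - tau, c)

with real-valued coefficients, lags -5..49 ms by default and ridge
regularization on a 51-value logarithmic grid of normalized parameters
(lambda_n from 1e-10 to 1e10, effective penalty lambda_n * e_m).

Decoders are trained and evaluated by contiguous five-fold
cross-validation over the recording parts; reconstruction quality is
Pearson's r between reconstructed and actual features, computed over
test segments that are either fixed-duration windows or word spans.
Null decoders trained on time-reversed features estimate chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .lagged import (
    BACKWARD_LAGS,
    LagGrid,
    lagged_cross,
    lagged_gram,
    standardize,
    _valid_bounds,
)
from .stimulus import StimulusFeatures
from .trf import by_correct

DEFAULT_LAMBDA_GRID = np.logspace(-10, 10, 51)
MIN_SEGMENT_SAMPLES = 20  # Pearson r is unstable below this


@dataclass
class BackwardDecoder:
    """Real-valued decoder coefficients over (lag, channel, feature)."""

    beta: np.ndarray  # (n_lags, n_channels, 2)
    lag_grid: LagGrid
    lambda_n: float
    e_m: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape[0] != self.lag_grid.n_lags:
            raise ValueError("beta shape inconsistent with lag grid")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class SegmentationScheme:
    """How test data is split before per-segment scoring."""

    mode: str  # "fixed_duration" | "word_boundaries"
    duration: float | None = None  # seconds, fixed mode only

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_duration", "word_boundaries"):
            raise ValueError(f"unknown segmentation mode {self.mode!r}")
        if self.mode == "fixed_duration" and (self.duration is None or self.duration <= 0):
            raise ValueError("fixed_duration mode needs a positive duration")

    @property
    def label(self) -> str:
        return "words" if self.mode == "word_boundaries" else f"{self.duration:g}s"


def _design_lags(lag_grid: LagGrid) -> np.ndarray:
    """Design-matrix sample lags implementing the decoder convention.

    A decoder lag tau means the EEG sample at ``t + tau`` contributes to
    the feature estimate at ``t`` (tau = -5 ms: EEG precedes the
    stimulus; tau = 49 ms: EEG follows it, where the neural response
    lives).  The lagged-design machinery shifts by ``t - lag``, so the
    design lags are the negated, re-sorted decoder lags.
    """
    return (-lag_grid.lags_samples)[::-1].copy()


def _reshape_beta(B: np.ndarray, n_lags: int, n_channels: int) -> np.ndarray:
    """(C*T, 2) solver output (design order) -> (T, C, 2) in decoder-lag order."""
    return B.reshape(n_channels, n_lags, 2).transpose(1, 0, 2)[::-1]


def fit_backward_decoders(
    eeg: np.ndarray,
    features: StimulusFeatures,
    lag_grid: LagGrid | None = None,
    lambda_grid: np.ndarray | list[float] | None = None,
    standardize_inputs: bool = True,
) -> list[BackwardDecoder]:
    """One ridge decoder per lambda_n, both features fitted simultaneously.

    The lag convention mirrors the forward model: the EEG sample at
    ``t + tau`` contributes to the feature estimate at ``t``, tau in
    -5..49 ms, so the decoder reads the EEG window *following* each
    stimulus sample — where the (causal, 11-18 ms) response lives.
    """
    lag_grid = lag_grid or BACKWARD_LAGS
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    F = features.as_array()
    if standardize_inputs:
        eeg = standardize(eeg)
        F = standardize(F)
    lags = _design_lags(lag_grid)
    G, n_valid = lagged_gram(eeg, lags)
    C = lagged_cross(eeg, lags, F)
    from .lagged import solve_ridge

    B_all, em = solve_ridge(G, C, n_valid, lambda_grid)
    n_ch = eeg.shape[1]
    return [
        BackwardDecoder(_reshape_beta(B_all[k], lag_grid.n_lags, n_ch), lag_grid, float(ln), em)
        for k, ln in enumerate(lambda_grid)
    ]


def reconstruct(decoder: BackwardDecoder, eeg: np.ndarray, standardize_inputs: bool = True):
    """Reconstruct both features over the valid samples of ``eeg``.

    Returns ``(recon, t_start)`` where ``recon`` is (n_valid, 2) and
    ``t_start`` the index of its first sample in the input.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    if standardize_inputs:
        eeg = standardize(eeg)
    recon, t_start = _reconstruct_multi(decoder.beta[None], decoder.lag_grid, eeg)
    return recon[0], t_start


def _reconstruct_multi(betas: np.ndarray, lag_grid: LagGrid, eeg_std: np.ndarray):
    """Reconstruction for a stack of decoders sharing one lag grid.

    betas: (n_dec, T, C, 2) in decoder-lag order.  Returns
    (recon (n_dec, n_valid, 2), t_start).  Uses FFT convolution per
    channel, summing channel contributions.
    """
    lags = _design_lags(lag_grid)
    n = eeg_std.shape[0]
    T = lags.size
    t_start, t_end = _valid_bounds(n, lags)
    n_valid = t_end - t_start + 1
    n_dec = betas.shape[0]
    d0 = int(lags[0])
    out = np.zeros((n_dec, n_valid, 2))
    # one short-kernel overlap-add convolution per (channel, decoder, feature)
    for c in range(eeg_std.shape[1]):
        z = np.ascontiguousarray(eeg_std[:, c])
        # design-order kernel: entry j multiplies eeg at t - (d0 + j)
        B_c = betas[:, ::-1, c, :]  # (n_dec, T, 2) flipped to design order
        for dct in range(n_dec):
            for f in range(2):
                y = signal.oaconvolve(z, B_c[dct, :, f])
                out[dct, :, f] += y[t_start - d0 : t_start - d0 + n_valid]
    return out, t_start


def segment_pearson(
    x: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    min_len: int = MIN_SEGMENT_SAMPLES,
):
    """Pearson r of (x, y) within each [start, end) segment.

    Segments shorter than ``min_len`` or with zero variance get NaN; the
    counts of both are returned alongside the scores.
    """
    rs = np.full(len(starts), np.nan)
    n_short = n_degenerate = 0
    for i, (s, e) in enumerate(zip(starts, ends)):
        if e - s < min_len:
            n_short += 1
            continue
        xs, ys = x[s:e], y[s:e]
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        den = np.sqrt((xs @ xs) * (ys @ ys))
        if den == 0:
            n_degenerate += 1
            continue
        rs[i] = float(xs @ ys / den)
    return rs, n_short, n_degenerate


def _fixed_segments(n_valid: int, duration: float, fs: float):
    step = int(round(duration * fs))
    starts = np.arange(0, n_valid - step + 1, step)
    return starts, starts + step


def evaluate_segments(
    decoder: BackwardDecoder,
    eeg: np.ndarray,
    features: StimulusFeatures,
    scheme: SegmentationScheme,
    words: pd.DataFrame | None = None,
    min_len: int = MIN_SEGMENT_SAMPLES,
) -> pd.DataFrame:
    """Reconstruct once over the test data, then score per segment.

    ``words`` (columns onset, offset in seconds) is required for
    word-boundary segmentation.  Returns a tidy frame with one row per
    (segment, feature).
    """
    F = standardize(features.as_array())
    recon, t_start = reconstruct(decoder, eeg)
    fs = features.fs
    n_valid = recon.shape[0]
    if scheme.mode == "fixed_duration":
        starts, ends = _fixed_segments(n_valid, scheme.duration, fs)
    else:
        if words is None:
            raise ValueError("word-boundary segmentation needs a word table")
        starts = np.maximum(np.round(words["onset"].to_numpy() * fs).astype(int) - t_start, 0)
        ends = np.minimum(
            np.round(words["offset"].to_numpy() * fs).astype(int) - t_start, n_valid
        )
        ok = ends > starts
        starts, ends = starts[ok], ends[ok]
    rows = []
    for j in range(2):
        truth = F[t_start : t_start + n_valid, j]
        rs, n_short, n_deg = segment_pearson(recon[:, j], truth, starts, ends, min_len)
        for seg_i, r in enumerate(rs):
            rows.append(
                {
                    "feature": j,
                    "segment": seg_i,
                    "r": r,
                    "n_samples": int(ends[seg_i] - starts[seg_i]),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["n_short"] = n_short
    df.attrs["n_degenerate"] = n_deg
    df.attrs["scheme"] = scheme.label
    return df


def assign_folds(part_lengths: list[int], k: int) -> list[int]:
    """Contiguous, near-equal-duration assignment of parts to k folds."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > len(part_lengths):
        raise ValueError("k exceeds the number of recording parts")
    total = sum(part_lengths)
    target = total / k
    folds, acc, fold = [], 0.0, 0
    remaining = len(part_lengths)
    for i, ln in enumerate(part_lengths):
        folds.append(fold)
        acc += ln
        remaining -= 1
        # advance when the fold has reached its share, keeping enough
        # parts for the folds still to fill
        if fold < k - 1 and (acc >= target * (fold + 1) or remaining <= k - fold - 1):
            fold += 1
    return folds


class DecoderCV:
    """Cross-validated backward decoders (model and time-reversed null).

    Fits, for every fold, one decoder per lambda_n on the training
    parts, for the actual features and for per-part time-reversed
    features.  Reconstructions of held-out parts are exposed for
    segment- and word-level scoring.
    """

    def __init__(
        self,
        eeg_parts: list[np.ndarray],
        feature_parts: list[StimulusFeatures],
        lag_grid: LagGrid | None = None,
        lambda_grid: np.ndarray | None = None,
        k: int = 5,
    ):
        if len(eeg_parts) != len(feature_parts) or not eeg_parts:
            raise ValueError("need matching, nonempty part lists")
        self.lag_grid = lag_grid or BACKWARD_LAGS
        self.lambda_grid = (
            DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
        )
        if self.lambda_grid.size == 0:
            raise ValueError("empty lambda grid")
        self.k = k
        # standardization statistics per recording part
        self.eeg_parts = [standardize(np.atleast_2d(np.asarray(e, float))) for e in eeg_parts]
        self.feat_parts = [standardize(f.as_array()) for f in feature_parts]
        self.fs = feature_parts[0].fs
        self.part_lengths = [e.shape[0] for e in self.eeg_parts]
        self.folds = assign_folds(self.part_lengths, k)
        self._fitted = False

    def fit(self) -> "DecoderCV":
        lags = _design_lags(self.lag_grid)
        grams, crosses, crosses_null = [], [], []
        for e, f in zip(self.eeg_parts, self.feat_parts):
            G, nv = lagged_gram(e, lags)
            grams.append((G, nv))
            crosses.append(lagged_cross(e, lags, f))
            crosses_null.append(lagged_cross(e, lags, f[::-1]))
        n_ch = self.eeg_parts[0].shape[1]
        T = self.lag_grid.n_lags
        self.decoders_: dict[int, dict[str, np.ndarray]] = {}
        self.e_m_: dict[int, float] = {}
        from .lagged import solve_ridge

        for fold in range(self.k):
            train = [i for i, f in enumerate(self.folds) if f != fold]
            G = sum(grams[i][0] for i in train)
            nv = sum(grams[i][1] for i in train)
            C = sum(crosses[i] for i in train)
            Cn = sum(crosses_null[i] for i in train)
            B, em = solve_ridge(G, C, nv, self.lambda_grid)
            Bn, _ = solve_ridge(G, Cn, nv, self.lambda_grid)
            self.decoders_[fold] = {
                "model": np.stack([_reshape_beta(b, T, n_ch) for b in B]),
                "null": np.stack([_reshape_beta(b, T, n_ch) for b in Bn]),
            }
            self.e_m_[fold] = em
        self._fitted = True
        return self

    def decoders(self, fold: int, kind: str = "model") -> list[BackwardDecoder]:
        betas = self.decoders_[fold][kind]
        return [
            BackwardDecoder(betas[i], self.lag_grid, float(ln), self.e_m_[fold])
            for i, ln in enumerate(self.lambda_grid)
        ]

    def reconstruct_part(self, part: int, kind: str = "model"):
        """Held-out reconstruction of one part by its fold's decoders.

        Returns (recon (n_lambda, n_valid, 2), t_start).  The truth to
        score against is the (per-part standardized) feature array, time
        reversed for the null pipeline.
        """
        if not self._fitted:
            raise RuntimeError("call fit() first")
        fold = self.folds[part]
        betas = self.decoders_[fold][kind]
        return _reconstruct_multi(betas, self.lag_grid, self.eeg_parts[part])

    def truth(self, part: int, kind: str = "model") -> np.ndarray:
        f = self.feat_parts[part]
        return f if kind == "model" else f[::-1]


def crossvalidate(
    eeg_parts: list[np.ndarray],
    feature_parts: list[StimulusFeatures],
    k: int = 5,
    lambda_grid: np.ndarray | None = None,
    schemes: list[SegmentationScheme] | None = None,
    lag_grid: LagGrid | None = None,
    words_per_part: list[pd.DataFrame] | None = None,
    kind: str = "model",
    min_len: int = MIN_SEGMENT_SAMPLES,
) -> pd.DataFrame:
    """Five-fold CV scores for every (lambda, scheme), one subject.

    Folds are contiguous groups of recording parts with near-equal
    duration.  Scores are the arithmetic mean of per-segment Pearson r
    within each held-out part, averaged over parts/folds.
    Returns a tidy frame (feature, scheme, lambda_n, r, n_segments).
    """
    if schemes is None:
        schemes = [SegmentationScheme("fixed_duration", 1.0)]
    cv = DecoderCV(eeg_parts, feature_parts, lag_grid, lambda_grid, k).fit()
    acc: dict[tuple, list] = {}
    for part in range(len(eeg_parts)):
        recon, t_start = cv.reconstruct_part(part, kind)
        truth = cv.truth(part, kind)
        n_valid = recon.shape[1]
        for scheme in schemes:
            if scheme.mode == "fixed_duration":
                starts, ends = _fixed_segments(n_valid, scheme.duration, cv.fs)
            else:
                if words_per_part is None:
                    raise ValueError("word segmentation needs words_per_part")
                w = words_per_part[part]
                starts = np.maximum(
                    np.round(w["onset"].to_numpy() * cv.fs).astype(int) - t_start, 0
                )
                ends = np.minimum(
                    np.round(w["offset"].to_numpy() * cv.fs).astype(int) - t_start, n_valid
                )
                sel = ends > starts
                starts, ends = starts[sel], ends[sel]
            for li in range(cv.lambda_grid.size):
                for j in range(2):
                    rs, _, _ = segment_pearson(
                        recon[li, :, j],
                        truth[t_start : t_start + n_valid, j],
                        starts,
                        ends,
                        min_len,
                    )
                    acc.setdefault((j, scheme.label, li), []).extend(
                        rs[np.isfinite(rs)].tolist()
                    )
    rows = [
        {
            "feature": j,
            "scheme": label,
            "lambda_n": float(cv.lambda_grid[li]),
            "r": float(np.mean(v)) if v else np.nan,
            "n_segments": len(v),
        }
        for (j, label, li), v in acc.items()
    ]
    return pd.DataFrame(rows)


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Exact signed-rank p for n <= 25; zero differences dropped; p=1 if all zero."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 and np.unique(np.abs(d)).size == d.size else "auto"
    return float(stats.wilcoxon(d, zero_method="wilcox", method=method).pvalue)


def segment_duration_comparison(
    subject_scores: pd.DataFrame, durations: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Friedman + pairwise Wilcoxon tests over segment durations.

    ``subject_scores``: tidy frame (subject, feature, scheme, r) with one
    averaged score per subject per scheme per feature.  Families of
    p-values (pairwise-within-feature; feature-vs-feature per duration)
    are Benjamini-Yekutieli corrected.  Friedman with identical columns
    is reported as statistic 0, p = 1 (average-rank tie convention).
    """
    if durations is None:
        durations = sorted(subject_scores["scheme"].unique())
    pivot = {
        j: subject_scores[subject_scores["feature"] == j]
        .pivot(index="subject", columns="scheme", values="r")[durations]
        for j in (0, 1)
    }
    for j in (0, 1):
        if pivot[j].shape[0] < 3:
            raise ValueError("Friedman test needs at least 3 subjects")

    fried_rows = []
    for j in (0, 1):
        cols = [pivot[j][d].to_numpy() for d in durations]
        if all(np.allclose(c, cols[0]) for c in cols[1:]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.friedmanchisquare(*cols)
        fried_rows.append({"feature": j, "statistic": float(stat), "p": float(p)})
    friedman = pd.DataFrame(fried_rows)

    pair_rows = []
    for j in (0, 1):
        for i1 in range(len(durations)):
            for i2 in range(i1 + 1, len(durations)):
                p = _paired_wilcoxon(
                    pivot[j][durations[i1]].to_numpy(), pivot[j][durations[i2]].to_numpy()
                )
                pair_rows.append(
                    {"feature": j, "a": durations[i1], "b": durations[i2], "p_raw": p}
                )
    pairwise = pd.DataFrame(pair_rows)
    if not pairwise.empty:
        for j in (0, 1):
            m = pairwise["feature"] == j
            pairwise.loc[m, "p_fdr"] = by_correct(pairwise.loc[m, "p_raw"].to_numpy())

    feat_rows = []
    for d in durations:
        p = _paired_wilcoxon(pivot[0][d].to_numpy(), pivot[1][d].to_numpy())
        feat_rows.append({"scheme": d, "p_raw": p})
    feature_cmp = pd.DataFrame(feat_rows)
    feature_cmp["p_fdr"] = by_correct(feature_cmp["p_raw"].to_numpy())
    return {"friedman": friedman, "pairwise": pairwise, "feature_comparison": feature_cmp}
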