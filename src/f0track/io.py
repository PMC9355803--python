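"""Readers and writers for every format the pipeline touches.

EEG lives either in BrainVision files (read through MNE) or in the
package's flat binary-with-JSON-sidecar container (lossless float64
round trip).  Audio is WAV (PCM or float).  Pitch tracks, word
alignments, word features and score tables are CSV; ground truth and
provenance are JSON; pipeline configuration is TOML.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import PitchTrack, StimulusFeatures

PACKAGE_VERSION = "0.1.0"


@dataclass
class EEGRecording:
    """Multichannel EEG samples with rate, labels and reference state."""

    data: np.ndarray  # (n_samples, n_channels)
    fs: float
    channel_names: list[str]
    reference: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} labels for {self.data.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def write_eeg(rec: EEGRecording, path: str | Path) -> None:
    """Flat float64 binary plus JSON sidecar; lossless."""
    path = Path(path)
    if path.suffix != ".dat":
        path = path.with_suffix(".dat")
    rec.data.astype("<f8").tofile(path)
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "reference": rec.reference,
        "shape": list(rec.data.shape),
        "dtype": "<f8",
        "meta": rec.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg(path: str | Path, expected_fs: float | None = None) -> EEGRecording:
    """Read BrainVision (.vhdr) or the flat .dat/.json container."""
    path = Path(path)
    if path.suffix == ".vhdr":
        rec = _read_brainvision(path)
    elif path.suffix in (".dat", ".json"):
        sidecar = json.loads(path.with_suffix(".json").read_text())
        data = np.fromfile(path.with_suffix(".dat"), dtype=sidecar["dtype"]).reshape(
            sidecar["shape"]
        )
        if len(sidecar["channel_names"]) != data.shape[1]:
            raise ValueError("channel label count does not match data")
        rec = EEGRecording(
            data,
            float(sidecar["fs"]),
            sidecar["channel_names"],
            sidecar.get("reference", "unknown"),
            sidecar.get("meta", {}),
        )
    else:
        raise ValueError(
            f"unknown EEG format {path.suffix!r}; supported: .vhdr (BrainVision), .dat/.json (flat)"
        )
    if expected_fs is not None and rec.fs != expected_fs:
        raise ValueError(f"sampling rate {rec.fs} does not match configured {expected_fs}")
    return rec


def _read_brainvision(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    return EEGRecording(
        raw.get_data().T,
        float(raw.info["sfreq"]),
        list(raw.ch_names),
        reference="as-recorded",
        meta={"source": str(path)},
    )


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        data = (data.astype(float) - np.iinfo(data.dtype).max / 2) / (
            np.iinfo(data.dtype).max / 2
        )
    if data.ndim > 1:
        data = data.mean(axis=1)
    return data.astype(float), float(fs)


def write_wav(path: str | Path, audio: np.ndarray, fs: float) -> None:
    from scipy.io import wavfile

    wavfile.write(path, int(fs), np.asarray(audio, dtype=np.float32))


def _header_comment(config_hash: str | None) -> str:
    h = config_hash or "unconfigured"
    return f"# f0track {PACKAGE_VERSION} config={h}\n"


def write_csv(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """CSV with a provenance header comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_pitch_csv(pitch: PitchTrack, path: str | Path, config_hash: str | None = None) -> None:
    f0 = ["" if not np.isfinite(v) else f"{v:.6g}" for v in pitch.f0]
    df = pd.DataFrame({"time_s": pitch.times, "f0_hz": f0})
    write_csv(df, path, config_hash)


def read_pitch_csv(path: str | Path, frame_step: float | None = None) -> PitchTrack:
    df = read_csv(path)
    times = df["time_s"].to_numpy(dtype=float)
    f0 = pd.to_numeric(df["f0_hz"], errors="coerce").to_numpy(dtype=float)
    if frame_step is None:
        frame_step = float(np.median(np.diff(times))) if times.size > 1 else 0.01
    return PitchTrack(times, f0, frame_step)


def write_alignment_csv(words: pd.DataFrame, path: str | Path, config_hash=None) -> None:
    df = words.copy()
    if "voiced_intervals" in df.columns:
        df["voiced_intervals"] = df["voiced_intervals"].apply(
            lambda iv: ";".join(f"{s:.6f}:{e:.6f}" for s, e in iv) if isinstance(iv, list) else ""
        )
    write_csv(df, path, config_hash)


def read_alignment_csv(path: str | Path) -> pd.DataFrame:
    df = read_csv(path)
    if "voiced_intervals" in df.columns:
        def parse(s):
            if not isinstance(s, str) or not s:
                return []
            return [tuple(map(float, pair.split(":"))) for pair in s.split(";")]

        df["voiced_intervals"] = df["voiced_intervals"].apply(parse)
    return df


def read_textgrid_words(path: str | Path, tier: str = "words") -> pd.DataFrame:
    """Minimal Praat TextGrid interval-tier reader (long text format)."""
    text = Path(path).read_text()
    rows = []
    in_tier = False
    cur: dict = {}
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("name ="):
            in_tier = line.split("=", 1)[1].strip().strip('"') == tier
            continue
        if not in_tier:
            continue
        if line.startswith("xmin ="):
            cur["onset"] = float(line.split("=")[1])
        elif line.startswith("xmax ="):
            cur["offset"] = float(line.split("=")[1])
        elif line.startswith("text ="):
            token = line.split("=", 1)[1].strip().strip('"')
            if token:
                rows.append({"word": token, **cur})
            cur = {}
    if not rows:
        raise ValueError(f"no intervals found in tier {tier!r} of {path}")
    return pd.DataFrame(rows)


def write_features(features: StimulusFeatures, path: str | Path, config_hash=None) -> None:
    df = pd.DataFrame({"f1": features.f1, "f2": features.f2})
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        fh.write(f"# fs={features.fs}\n")
        df.to_csv(fh, index=False)


def read_features(path: str | Path) -> StimulusFeatures:
    fs = 1000.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# fs="):
                fs = float(line.strip().split("=")[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    return StimulusFeatures(df["f1"].to_numpy(), df["f2"].to_numpy(), fs)


# ------------------------------------------------------------------ config

@dataclass
class PipelineConfig:
    """Validated pipeline configuration (TOML on disk).

    Times are seconds, sample indices 0-based, intervals half-open.
    """

    mode: str = "synthetic"  # "synthetic" | "real"
    output_dir: str = "f0track_out"
    # real-data paths
    audio_path: str | None = None
    eeg_paths: list[str] = field(default_factory=list)
    alignment_path: str | None = None
    pitch_path: str | None = None
    probabilities_path: str | None = None
    # analysis parameters
    band_percentiles: tuple[float, float] = (5.0, 95.0)
    forward_lags_ms: tuple[float, float] = (-250.0, 499.0)
    backward_lags_ms: tuple[float, float] = (-5.0, 49.0)
    lambda_grid: dict = field(
        default_factory=lambda: {"lo": -10.0, "hi": 10.0, "num": 51}
    )
    n_folds: int = 5
    segment_durations: list[float] = field(
        default_factory=lambda: [0.1, 0.26, 0.31, 1.0, 10.0, 30.0]
    )
    n_bootstrap: int = 10000
    seed: int = 0
    outlier_n_trees: int = 1000
    fixed_forward_lambda: float = 1.0
    # synthetic spec overrides
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            for name in ("audio_path", "alignment_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"real-data mode requires existing {name}")
            if not self.eeg_paths or not all(Path(p).exists() for p in self.eeg_paths):
                raise ValueError("real-data mode requires existing eeg_paths")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def lambda_values(self) -> np.ndarray:
        g = self.lambda_grid
        return np.logspace(g["lo"], g["hi"], int(g["num"]))

    def hash(self) -> str:
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("band_percentiles", "forward_lags_ms", "backward_lags_ms"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    if cfg.synthetic:
        from .synthetic import SyntheticSpec

        spec_fields = set(SyntheticSpec.__dataclass_fields__) - {"seed"}
        bad = set(cfg.synthetic) - spec_fields
        if bad:
            raise ValueError(f"unknown synthetic keys: {sorted(bad)}")
    cfg.validate()
    return cfg
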