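"""EEG preprocessing for f0-band analysis: band-pass and average reference.

The analysis band (50-280 Hz) brackets the speaker's pitch range with
margin; the FIR is a one-pass zero-phase Hamming design (transition
bandwidths 12.5 / 70 Hz, 265 taps at 1 kHz).
"""

from __future__ import annotations

import numpy as np

from .io import EEGRecording
from .stimulus import BandSpec, apply_zero_phase, design_bandpass_fir

ANALYSIS_BAND = BandSpec(50.0, 280.0, lower_transition=12.5, upper_transition=70.0)


def bandpass_array(data: np.ndarray, fs: float, band: BandSpec = ANALYSIS_BAND) -> np.ndarray:
    taps = design_bandpass_fir(band, fs)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return np.column_stack(
        [apply_zero_phase(data[:, c], taps) for c in range(data.shape[1])]
    )


def average_reference(data: np.ndarray) -> np.ndarray:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return data - data.mean(axis=1, keepdims=True)


def preprocess_eeg(rec: EEGRecording, band: BandSpec = ANALYSIS_BAND) -> EEGRecording:
    """Band-pass to the analysis band, then re-reference to the average."""
    out = average_reference(bandpass_array(rec.data, rec.fs, band))
    meta = dict(rec.meta)
    meta["preprocessing"] = {
        "bandpass_hz": (band.f_lo, band.f_hi),
        "fir": "hamming zero-phase",
        "reference": "average",
    }
    return EEGRecording(out, rec.fs, rec.channel_names, reference="average", meta=meta)
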