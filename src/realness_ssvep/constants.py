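"""Study-design constants: stimulation timing, montage, stimulus coding.

The paradigm presents a face image every 200 ms (5 Hz) for 100 ms,
alternating with a phase-scrambled background for the remaining 100 ms,
so the face/background reversal rate is 10 Hz.  Trials last 10 s; the
36 stimulus images form a complete 6 (realness) x 2 (gender) x
3 (emotion) factorial.
"""

from __future__ import annotations

import functools

import numpy as np

#: Face presentation frequency in Hz (one face onset every 200 ms).
STIM_FREQ = 5.0
#: Face/background reversal frequency in Hz (100 ms face + 100 ms background).
REVERSAL_FREQ = 10.0
#: Face-on duration within each 200 ms cycle, seconds.
FACE_DURATION_S = 0.100
#: Trial duration in seconds.
TRIAL_S = 10.0
#: Leading gray-screen gap at trial start, seconds (signal-free time).
GRAY_LEAD_S = 0.200
#: Number of trials (= stimulus images) per session.
N_TRIALS_PER_SESSION = 36
#: Realness levels, coded 1 (R0, most cartoon-like) .. 6 (R5, photograph).
REALNESS_LEVELS = (1, 2, 3, 4, 5, 6)

GENDERS = ("female", "male")
EMOTIONS = ("angry", "happy", "neutral")

#: Acquisition sampling rate in Hz.
RAW_SRATE = 1000.0
#: Analysis sampling rate after decimation, Hz.
ANALYSIS_SRATE = 250.0

#: Parieto-occipital electrode cluster used for SSVEP and classification.
CLUSTER9 = ("Pz", "PO3", "PO7", "PO4", "PO8", "POz", "O1", "Oz", "O2")

#: 64-channel actiCAP layout (10-10 system); FCz is the recording reference
#: and AFz the ground, neither carried as a data channel.
MONTAGE64 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)


def face_onsets(trial_s: float = TRIAL_S, stim_freq: float = STIM_FREQ) -> np.ndarray:
    """Face onset times (s) within one trial, spaced exactly 1/stim_freq."""
    period = 1.0 / stim_freq
    n = int(round(trial_s * stim_freq))
    return np.arange(n) * period


def image_id(realness: int, gender: str, emotion: str) -> int:
    """Map a factorial cell to its stimulus image id (1..36)."""
    if realness not in REALNESS_LEVELS:
        raise ValueError(f"realness must be in {REALNESS_LEVELS}, got {realness}")
    g = GENDERS.index(gender)
    e = EMOTIONS.index(emotion)
    return (realness - 1) * 6 + g * 3 + e + 1


def decode_image_id(code: int) -> tuple[int, str, str]:
    """Inverse of :func:`image_id`: (realness, gender, emotion) for an id."""
    if not 1 <= code <= 36:
        raise ValueError(f"image id must be in 1..36, got {code}")
    c = code - 1
    realness = c // 6 + 1
    g, e = divmod(c % 6, 3)
    return realness, GENDERS[g], EMOTIONS[e]


@functools.lru_cache(maxsize=1)
def _standard_positions() -> dict:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    return montage.get_positions()["ch_pos"]


def montage_positions(ch_names=MONTAGE64) -> np.ndarray:
    """3-D electrode positions (meters) for the given 10-10 labels.

    Uses the standard-1005 idealized head montage shipped with MNE.
    """
    pos = _standard_positions()
    return np.array([pos[name] for name in ch_names])
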