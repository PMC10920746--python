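"""Power spectra and single-trial FFT amplitudes at the tagging frequencies.

Amplitudes are computed per trial with a Hamming window and normalized by
the window's coherent gain (sum of window / N), so a unit-amplitude on-bin
sinusoid reads 1.0 uV regardless of trial length.  The stimulation
frequency and its harmonics (5, 10, 15 Hz) are the default query set; an
electrode-cluster amplitude is the unweighted mean over member channels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .constants import CLUSTER9
from .io_preproc import Epochs

__all__ = ["welch_psd", "fft_amplitudes", "cluster_amplitudes"]

LABEL_COLS = ("subject", "session", "trial", "image_id", "realness", "gender",
              "emotion")


def welch_psd(ep: Epochs, window_s: float = 2.0, overlap: float = 0.5
              ) -> pd.DataFrame:
    """Welch power spectral density averaged over trials.

    Returns a tidy frame with columns ``channel``, ``freq`` (Hz) and
    ``power`` (uV^2/Hz).  Uses Hamming-windowed modified periodograms of
    ``window_s``-second segments with fractional ``overlap``.
    """
    nperseg = int(round(window_s * ep.srate))
    if nperseg > ep.n_samples:
        raise ValueError(
            f"window of {window_s} s ({nperseg} samples) exceeds trial length "
            f"({ep.n_samples} samples)"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    freqs, pxx = signal.welch(ep.data, fs=ep.srate, window="hamming",
                              nperseg=nperseg,
                              noverlap=int(round(overlap * nperseg)), axis=2)
    mean_pxx = pxx.mean(axis=0)  # average periodograms across trials
    rows = []
    for ci, ch in enumerate(ep.ch_names):
        rows.append(pd.DataFrame({"channel": ch, "freq": freqs,
                                  "power": mean_pxx[ci]}))
    return pd.concat(rows, ignore_index=True)


def _bin_indices(freqs, n_samples: int, srate: float) -> list[int]:
    resolution = srate / n_samples
    idx = []
    for f in freqs:
        k = f / resolution
        if abs(k - round(k)) > 1e-6:
            raise ValueError(
                f"{f} Hz is not an exact FFT bin at {n_samples} samples / "
                f"{srate} Hz (resolution {resolution:g} Hz); use a trial "
                f"length that is a multiple of {1.0 / f:g} s"
            )
        idx.append(int(round(k)))
    return idx


def fft_amplitudes(ep: Epochs, freqs=(5.0, 10.0, 15.0), channels=None
                   ) -> pd.DataFrame:
    """Single-trial Hamming-windowed FFT amplitudes at exact bins.

    Returns a long-format table with one row per trial x channel x
    frequency; ``amplitude`` is in uV (single-sided, coherent-gain
    normalized).  ``channels`` restricts/orders the channels (default all).
    """
    if channels is not None:
        ep = ep.pick_channels(list(channels))
    idx = _bin_indices(freqs, ep.n_samples, ep.srate)
    win = np.hamming(ep.n_samples)
    spec = np.fft.rfft(ep.data * win, axis=2)
    amps = 2.0 * np.abs(spec[:, :, idx]) / win.sum()  # trials x channels x freqs

    label_cols = [c for c in LABEL_COLS if c in ep.labels.columns]
    rows = []
    for ci, ch in enumerate(ep.ch_names):
        for fi, f in enumerate(freqs):
            block = ep.labels[label_cols].copy()
            block["channel"] = ch
            block["freq"] = float(f)
            block["amplitude"] = amps[:, ci, fi]
            rows.append(block)
    return pd.concat(rows, ignore_index=True)


def cluster_amplitudes(amps: pd.DataFrame, members=CLUSTER9,
                       name: str = "cluster9") -> pd.DataFrame:
    """Collapse per-channel amplitudes to an electrode-cluster mean.

    ``amps`` is the output of :func:`fft_amplitudes`; the cluster value for
    each trial x frequency is the unweighted mean over member channels.
    """
    members = list(members)
    sub = amps[amps["channel"].isin(members)]
    missing = set(members) - set(sub["channel"].unique())
    if missing:
        raise KeyError(f"cluster members absent from amplitude table: {sorted(missing)}")
    keys = [c for c in amps.columns if c not in ("channel", "amplitude")]
    out = sub.groupby(keys, as_index=False, observed=True)["amplitude"].mean()
    out["channel"] = name
    return out[amps.columns.tolist()]
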