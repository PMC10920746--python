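"""Spatio-spectral decomposition (SSD) for narrowband SSVEP extraction.

SSD finds spatial filters w maximizing the generalized Rayleigh quotient

    w' C_s w / w' C_n w,

where C_s is the covariance of the data band-passed in the signal band
(default [4, 6] Hz around the 5 Hz tagging frequency) and C_n the summed
covariance of the data band-passed in the two flanking noise bands
([2, 3] and [7, 8] Hz).  Activation patterns are reconstructed from the
filters via the forward-model identity ``A = C_s W (W' C_s W)^{-1}``
(Haufe-style reconstruction), and each (filter, pattern) pair is sign-
standardized so the pattern is non-negative at a reference channel
(default Oz).  Components are kept while their eigenvalue exceeds a
threshold (default 0.7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg, signal

from .io_preproc import Epochs, Recording

__all__ = ["SSDModel", "fit_ssd", "apply_ssd", "match_components"]


@dataclass
class SSDModel:
    """Fitted SSD: ``filters`` (components x channels), ``patterns``
    (channels x components), eigenvalues sorted descending."""

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    ch_names: list[str]
    signal_band: tuple
    noise_bands: tuple
    reference: str
    status: str = "ok"

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]

    def save(self, basepath) -> Path:
        """Serialize to JSON metadata + .npz weights; returns JSON path."""
        base = Path(basepath)
        np.savez(base.with_suffix(".npz"), filters=self.filters,
                 patterns=self.patterns, eigenvalues=self.eigenvalues)
        meta = dict(ch_names=self.ch_names, signal_band=list(self.signal_band),
                    noise_bands=[list(b) for b in self.noise_bands],
                    reference=self.reference, status=self.status,
                    weights=base.with_suffix(".npz").name)
        path = base.with_suffix(".json")
        path.write_text(json.dumps(meta, indent=2))
        return path


def _band_cov(data: np.ndarray, band, srate: float, order: int = 2) -> np.ndarray:
    sos = signal.butter(order, list(band), btype="bandpass", fs=srate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, data, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return filtered @ filtered.T / filtered.shape[1]


def fit_ssd(rec: Recording, signal_band=(4.0, 6.0),
            noise_bands=((2.0, 3.0), (7.0, 8.0)), n_components: int = 3,
            eig_threshold: float = 0.7, reference: str = "Oz",
            shrinkage: float = 1e-6) -> SSDModel:
    """Fit SSD on continuous (concatenated) data of one participant.

    ``shrinkage`` adds ``lambda * trace(C_n)/n_ch * I`` to the noise
    covariance to guard against rank deficiency introduced by narrowband
    filtering.  Raises if the regularized noise covariance is still
    numerically singular; returns an empty model with ``status='warning'``
    when no eigenvalue passes the threshold.
    """
    nyq = rec.srate / 2
    for band in (signal_band, *noise_bands):
        if not 0 < band[0] < band[1] < nyq:
            raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    if rec.n_samples < 10 * rec.srate:
        raise ValueError("need at least 10 s of data for stable covariances")

    c_s = _band_cov(rec.data, signal_band, rec.srate)
    c_n = sum(_band_cov(rec.data, band, rec.srate) for band in noise_bands)
    n_ch = rec.n_channels
    c_n = c_n + shrinkage * np.trace(c_n) / n_ch * np.eye(n_ch)
    cond = np.linalg.cond(c_n)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "noise covariance is rank deficient; increase the shrinkage "
            "regularization"
        )

    eigvals, eigvecs = linalg.eigh(c_s, c_n)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    keep = min(n_components, n_ch)
    mask = eigvals[:keep] > eig_threshold
    n_keep = int(mask.sum())
    if n_keep == 0:
        return SSDModel(np.empty((0, n_ch)), np.empty((n_ch, 0)),
                        eigvals, list(rec.ch_names), tuple(signal_band),
                        tuple(tuple(b) for b in noise_bands), reference,
                        status="warning: no eigenvalue above threshold")

    w = eigvecs[:, :n_keep]                      # channels x components
    patterns = c_s @ w @ np.linalg.inv(w.T @ c_s @ w)
    if reference not in rec.ch_names:
        raise KeyError(f"reference channel {reference!r} not in recording")
    ref_idx = rec.ch_names.index(reference)
    flip = np.where(patterns[ref_idx] < 0, -1.0, 1.0)
    w = w * flip
    patterns = patterns * flip
    return SSDModel(w.T, patterns, eigvals, list(rec.ch_names),
                    tuple(signal_band), tuple(tuple(b) for b in noise_bands),
                    reference)


def apply_ssd(model: SSDModel, ep: Epochs) -> Epochs:
    """Project epochs into SSD component space (arbitrary units)."""
    if list(ep.ch_names) != list(model.ch_names):
        missing = set(model.ch_names) - set(ep.ch_names)
        if missing:
            raise KeyError(f"epochs lack SSD model channels: {sorted(missing)}")
        ep = ep.pick_channels(model.ch_names)
    comp = np.einsum("kc,tcs->tks", model.filters, ep.data)
    names = [f"SSD{i + 1}" for i in range(model.n_components)]
    return Epochs(comp, ep.srate, names, ep.labels.copy(), ep.tmin)


def match_components(models: list[SSDModel]) -> tuple[list[int], np.ndarray]:
    """Select, per subject, the component most similar across subjects.

    Similarity between two patterns is the absolute dot product of the
    unit-normalized patterns (in [0, 1]).  For each subject the component
    maximizing the mean similarity to all other subjects' candidate
    patterns is chosen.  Returns (selected component index per subject,
    subjects x subjects similarity matrix of the selected patterns).
    """
    if len(models) < 2:
        raise ValueError("need at least two subjects to match components")
    if any(m.n_components == 0 for m in models):
        raise ValueError("every subject needs at least one SSD component")
    normed = []
    for m in models:
        p = m.patterns / np.linalg.norm(m.patterns, axis=0, keepdims=True)
        normed.append(p)

    selected = []
    for i, p_i in enumerate(normed):
        scores = np.zeros(p_i.shape[1])
        for k in range(p_i.shape[1]):
            sims = []
            for j, p_j in enumerate(normed):
                if j == i:
                    continue
                sims.append(np.max(np.abs(p_j.T @ p_i[:, k])))
            scores[k] = np.mean(sims)
        selected.append(int(np.argmax(scores)))

    n = len(models)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = abs(float(normed[i][:, selected[i]] @ normed[j][:, selected[j]]))
            sim[i, j] = sim[j, i] = s
    return selected, sim
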