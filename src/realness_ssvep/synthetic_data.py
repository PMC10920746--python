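"""Synthetic EEG generator emulating the face-realness SSVEP study design.

The generator reproduces the statistical structure the downstream analysis
assumes, so that every stage can be exercised without access to recordings:

* 6 realness levels x 2 genders x 3 emotions = 36 images, one trial per
  image per session; trials are 10 s with a 5 Hz face presentation rate
  (100 ms face / 100 ms scrambled background, a 10 Hz reversal rate).
* Each face onset evokes a biphasic transient (positive peak near 100 ms,
  negative N170-like trough near 170 ms), modeled as a sum of Gaussian
  bumps; the steady-state response is the 5 Hz superposition of these
  transients.
* The evoked amplitude follows a quadratic (U-shaped) function of realness
  ``a(r) = b0 + b1*r + b2*r**2`` plus a Gaussian subject random intercept;
  the N170 latency is realness-dependent.
* The evoked source projects to the scalp through a fixed occipito-parietal
  topography with right lateralization (Gaussian spatial profile centered
  between PO8 and O2); background activity is 1/f (pink) noise plus an
  optional 10 Hz alpha rhythm with a posterior profile and random phase.
* Stimulus attributes carry an eye-size confound that decreases with
  realness, except that the two most realistic levels (R4, R5) share the
  same eye-size distribution.

Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from .io_preproc import Epochs, Recording, write_brainvision

__all__ = [
    "EvokedKernel",
    "GenerativeParams",
    "make_design",
    "make_kernel",
    "class_kernel",
    "kernel_train",
    "face_visibility_train",
    "amplitude_profile",
    "simulate_epochs",
    "simulate_dataset",
    "simulate_amplitudes",
    "make_stimulus_table",
    "evoked_topography",
]


# ---------------------------------------------------------------------------
# Evoked kernel
# ---------------------------------------------------------------------------

@dataclass
class EvokedKernel:
    """Transient response to one face onset, sampled over [0, 200) ms."""

    waveform: np.ndarray
    srate: float
    components: tuple  # (latency_ms, amplitude_uv, width_ms) per bump

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.waveform.size) / self.srate * 1000.0

    def window_mean(self, lo_ms: float, hi_ms: float) -> float:
        """Mean waveform value over samples with lo_ms <= t < hi_ms."""
        t = self.times_ms
        mask = (t >= lo_ms) & (t < hi_ms)
        return float(self.waveform[mask].mean())


def make_kernel(peak_latencies_ms=(100.0, 170.0), peak_amplitudes_uv=(2.0, -5.0),
                widths_ms=(15.0, 15.0), srate: float = C.RAW_SRATE,
                duration_ms: float = 200.0) -> EvokedKernel:
    """Sum-of-Gaussians evoked kernel.

    Each component is ``amp * exp(-(t - latency)^2 / (2 width^2))``.  With
    the default latencies and widths the kernel decays to ~0 at the window
    edges, so consecutive 5 Hz responses do not overlap.
    """
    lat = np.atleast_1d(np.asarray(peak_latencies_ms, dtype=float))
    amp = np.atleast_1d(np.asarray(peak_amplitudes_uv, dtype=float))
    wid = np.atleast_1d(np.asarray(widths_ms, dtype=float))
    if not (lat.size == amp.size == wid.size):
        raise ValueError("latencies, amplitudes and widths must have equal length")
    if np.any((lat < 0) | (lat >= duration_ms)):
        raise ValueError(
            f"peak latencies must lie within [0, {duration_ms}) ms, got {lat}"
        )
    t = np.arange(int(round(duration_ms / 1000.0 * srate))) / srate * 1000.0
    wave = np.zeros_like(t)
    for mu, a, w in zip(lat, amp, wid):
        wave += a * np.exp(-0.5 * ((t - mu) / w) ** 2)
    peak = np.max(np.abs(wave))
    if peak > 0 and abs(wave[0]) > 0.01 * peak:
        raise ValueError(
            "kernel does not vanish at t=0; move peaks away from the window edge"
        )
    return EvokedKernel(wave, srate, tuple(zip(lat, amp, wid)))


# ---------------------------------------------------------------------------
# Generative parameters
# ---------------------------------------------------------------------------

#: N170-like trough latency (ms) for realness levels 1..6.  Realness-dependent
#: latencies give each class a distinct response shape, which is what the
#: template-correlation classifier can exploit; the spread (a few ms, smallest
#: gap between levels 5 and 6) mirrors the reported small latency differences.
DEFAULT_N170_LATENCIES_MS = (173.1, 176.9, 175.5, 178.9, 177.51, 177.38)


@dataclass
class GenerativeParams:
    """Parameters of the synthetic EEG generator.

    ``beta`` defines the quadratic amplitude profile
    ``a(r) = beta[0] + beta[1]*r + beta[2]*r**2`` (microvolt scale factors
    applied to the evoked kernel, realness r in 1..6).  The default is
    U-shaped with its vertex at r = 3.5; its magnitude is an arbitrary
    choice sized so a ten-subject experiment detects the quadratic term
    with high (but not saturated) likelihood-ratio power.
    """

    beta: tuple = (1.2, -0.175, 0.025)
    subject_sd: float = 0.3          # SD of subject random intercepts (scale units)
    amplitude_noise_sd: float = 1.0  # trial-level amplitude noise (simulate_amplitudes)
    noise_sd: float = 1.0            # broadband pink-noise SD per channel, uV
    pink_exponent: float = 1.0       # 1/f^exponent spectral shape
    alpha_sd: float = 0.5            # 10 Hz alpha SD at its topographic peak, uV
    alpha_freq: float = 10.0
    p100_latency_ms: float = 100.0
    p100_amplitude_uv: float = 2.0
    n170_amplitude_uv: float = -5.0
    n170_latencies_ms: tuple = DEFAULT_N170_LATENCIES_MS
    peak_width_ms: float = 15.0
    topo_center: tuple = ("PO8", "O2")  # evoked source peaks between these
    topo_width_m: float = 0.05          # spatial Gaussian width, meters
    confound_slope: float = -30.0       # eye-size pixels per realness level
    confound_drives_eeg: bool = False
    confound_eeg_gain: float = 0.0      # amplitude shift per SD of eye size
    seed: int = 0


def amplitude_profile(params: GenerativeParams) -> np.ndarray:
    """True condition-mean amplitude scale a(r) for r = 1..6."""
    r = np.arange(1, 7, dtype=float)
    b0, b1, b2 = params.beta
    a = b0 + b1 * r + b2 * r ** 2
    if params.confound_drives_eeg and params.confound_eeg_gain != 0.0:
        eye = _eye_size_mean(r, params.confound_slope)
        a = a + params.confound_eeg_gain * (eye - eye.mean()) / eye.std()
    return a


def class_kernel(params: GenerativeParams, realness: int,
                 srate: float = C.RAW_SRATE,
                 amplitude_scale: float = 1.0) -> EvokedKernel:
    """Evoked kernel for one realness level.

    ``amplitude_scale`` multiplies only the N170-like trough: realness
    modulates the face-specific component, while the earlier positive
    deflection is a realness-independent visual onset response.  Besides
    the realness-specific trough latency, this gives each class a distinct
    waveform shape (P100:N170 ratio), which is what a template-correlation
    classifier can exploit.
    """
    return make_kernel(
        (params.p100_latency_ms, params.n170_latencies_ms[realness - 1]),
        (params.p100_amplitude_uv,
         amplitude_scale * params.n170_amplitude_uv),
        (params.peak_width_ms, params.peak_width_ms),
        srate=srate,
    )


def kernel_train(kernel: EvokedKernel, duration_s: float,
                 stim_freq: float = C.STIM_FREQ, skip_before_s: float = 0.0) -> np.ndarray:
    """Tile the kernel at the stimulation rate over ``duration_s`` seconds.

    Onsets earlier than ``skip_before_s`` are suppressed (gray-screen lead).
    """
    n = int(round(duration_s * kernel.srate))
    out = np.zeros(n)
    period = int(round(kernel.srate / stim_freq))
    if period != kernel.waveform.size:
        raise ValueError("kernel duration must equal one stimulation period")
    for start in range(0, n, period):
        if start / kernel.srate < skip_before_s - 1e-9:
            continue
        stop = min(start + period, n)
        out[start:stop] = kernel.waveform[: stop - start]
    return out


def face_visibility_train(duration_s: float = C.TRIAL_S,
                          srate: float = C.RAW_SRATE) -> np.ndarray:
    """Binary face-on/background indicator: 1 while a face is displayed.

    Faces are shown for 100 ms at each 200 ms onset, so the indicator
    reverses at 10 Hz.
    """
    t = np.arange(int(round(duration_s * srate))) / srate
    phase = np.mod(t, 1.0 / C.STIM_FREQ)
    return (phase < C.FACE_DURATION_S - 1e-12).astype(float)


# ---------------------------------------------------------------------------
# Design and stimulus tables
# ---------------------------------------------------------------------------

def make_design(n_subjects: int, n_sessions: int, seed: int = 0) -> pd.DataFrame:
    """Factorial trial design: one row per subject x session x trial.

    Each session presents all 36 images (6 realness x 2 gender x 3 emotion)
    exactly once, in an order randomized per session.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if n_sessions < 2:
        raise ValueError(
            "need at least two sessions: TRCA training maximizes covariance "
            "across session pairs and is undefined for a single session"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for subject in range(1, n_subjects + 1):
        for session in range(1, n_sessions + 1):
            order = rng.permutation(C.N_TRIALS_PER_SESSION) + 1
            for trial, img in enumerate(order, start=1):
                realness, gender, emotion = C.decode_image_id(int(img))
                rows.append(dict(subject=subject, session=session, trial=trial,
                                 image_id=int(img), realness=realness,
                                 gender=gender, emotion=emotion))
    design = pd.DataFrame(rows)
    design.attrs["onset_times"] = C.face_onsets().tolist()
    return design


def _eye_size_mean(realness, slope: float, intercept: float = 300.0) -> np.ndarray:
    """Deterministic eye-size trend; levels 5 and 6 share one mean."""
    r = np.minimum(np.asarray(realness, dtype=float), 5.0)
    return intercept + slope * r


def make_stimulus_table(confound_slope: float = -30.0, seed: int = 0,
                        jitter_sd: float = 8.0) -> pd.DataFrame:
    """Stimulus attributes and behavioral ratings for the 36 images.

    Eye size decreases with realness at ``confound_slope`` pixels/level but
    is drawn from the same distribution for the two most realistic levels,
    so an R4-vs-R5 comparison is confound-free.  The realism rating
    increases with realness; luminosity has no systematic trend.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for img in range(1, C.N_TRIALS_PER_SESSION + 1):
        realness, gender, emotion = C.decode_image_id(img)
        rows.append(dict(image_id=img, realness=realness, gender=gender,
                         emotion=emotion))
    stim = pd.DataFrame(rows)
    r = stim["realness"].to_numpy(dtype=float)
    n = len(stim)
    stim["eye_size"] = _eye_size_mean(r, confound_slope) + rng.normal(0, jitter_sd, n)
    stim["sclera_size"] = 0.35 * stim["eye_size"] + rng.normal(0, 0.35 * jitter_sd, n)
    stim["luminosity"] = 128.0 + rng.normal(0, 5.0, n)

    def scale(x):
        return np.clip(x, 1.0, 7.0)

    stim["realism"] = scale(1.0 + 1.05 * (r - 1) + rng.normal(0, 0.5, n))
    # mild affinity dip for the near-real level (r=5), echoing uncanny-valley
    # shaped behavioral profiles
    dip = 1.0 * np.exp(-0.5 * (r - 5.0) ** 2)
    stim["appeal"] = scale(4.5 - dip + rng.normal(0, 0.5, n))
    stim["reassurance"] = scale(4.5 - dip + rng.normal(0, 0.5, n))
    stim["attractiveness"] = scale(4.2 - 0.8 * dip + rng.normal(0, 0.5, n))
    stim["familiarity"] = scale(2.0 + 0.7 * r + rng.normal(0, 0.5, n))
    return stim


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------

def evoked_topography(channels, params: GenerativeParams) -> np.ndarray:
    """Spatial mixing weights for the evoked source (peak weight 1).

    A Gaussian profile in sensor space centered midway between the
    ``topo_center`` electrodes, which places the peak over right
    parieto-occipital cortex.
    """
    pos = C.montage_positions(tuple(channels))
    all_pos = C.montage_positions(C.MONTAGE64)
    name_to_pos = dict(zip(C.MONTAGE64, all_pos))
    c1, c2 = params.topo_center
    center = 0.5 * (name_to_pos[c1] + name_to_pos[c2])
    d2 = np.sum((pos - center) ** 2, axis=1)
    return np.exp(-0.5 * d2 / params.topo_width_m ** 2)


def _alpha_topography(channels) -> np.ndarray:
    pos = C.montage_positions(tuple(channels))
    all_pos = dict(zip(C.MONTAGE64, C.montage_positions(C.MONTAGE64)))
    center = 0.5 * (all_pos["POz"] + all_pos["Oz"])
    d2 = np.sum((pos - center) ** 2, axis=1)
    return np.exp(-0.5 * d2 / 0.06 ** 2)


def _pink_noise(rng: np.random.Generator, shape, n_samples: int, srate: float,
                exponent: float) -> np.ndarray:
    """1/f^exponent noise with unit variance along the last axis."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((*shape, freqs.size))
            + 1j * rng.standard_normal((*shape, freqs.size))) * gain
    noise = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = noise.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd


def _subject_intercepts(params: GenerativeParams, subjects) -> dict:
    rng = np.random.default_rng(params.seed + 7919)
    return {s: float(rng.normal(0.0, params.subject_sd))
            for s in sorted(set(subjects))}


def _component_trains(params: GenerativeParams, srate: float,
                      duration_s: float, skip_before_s: float = 0.0):
    """5 Hz trains of the P100-like (shared) and N170-like (per-class)
    kernel components; the realness amplitude scale multiplies only the
    latter."""
    p100 = make_kernel((params.p100_latency_ms,),
                       (params.p100_amplitude_uv,),
                       (params.peak_width_ms,), srate=srate)
    p100_train = kernel_train(p100, duration_s, skip_before_s=skip_before_s)
    n170_trains = {}
    for r in C.REALNESS_LEVELS:
        n170 = make_kernel((params.n170_latencies_ms[r - 1],),
                           (params.n170_amplitude_uv,),
                           (params.peak_width_ms,), srate=srate)
        n170_trains[r] = kernel_train(n170, duration_s,
                                      skip_before_s=skip_before_s)
    return p100_train, n170_trains


def simulate_epochs(design: pd.DataFrame, params: GenerativeParams,
                    channels=C.CLUSTER9, srate: float = C.ANALYSIS_SRATE,
                    duration_s: float = 8.0,
                    tmin: float = 1.0) -> tuple[Epochs, pd.DataFrame]:
    """Generate steady-state epochs directly (post-trim view of the data).

    Fast path for simulation studies: returns trials x channels x samples
    epochs of ``duration_s`` seconds in which every 200 ms window carries
    the realness-specific evoked kernel scaled by ``a(realness) + subject
    intercept``, mixed through the evoked topography, plus pink noise and
    alpha.  Also returns the per-trial ground-truth amplitude table.
    """
    channels = list(channels)
    rng = np.random.default_rng(params.seed)
    n_samp = int(round(duration_s * srate))
    mix = evoked_topography(channels, params)
    alpha_mix = _alpha_topography(channels)
    p100_train, n170_trains = _component_trains(params, srate, duration_s)
    a_r = amplitude_profile(params)
    intercepts = _subject_intercepts(params, design["subject"])

    n_trials = len(design)
    data = np.empty((n_trials, len(channels), n_samp))
    truth_amp = np.empty(n_trials)
    t = np.arange(n_samp) / srate
    for i, row in enumerate(design.itertuples(index=False)):
        amp = a_r[row.realness - 1] + intercepts[row.subject]
        truth_amp[i] = amp
        sig = np.outer(mix, p100_train + amp * n170_trains[row.realness])
        if params.noise_sd > 0:
            sig = sig + params.noise_sd * _pink_noise(
                rng, (len(channels),), n_samp, srate, params.pink_exponent)
        if params.alpha_sd > 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig = sig + params.alpha_sd * np.outer(
                alpha_mix, np.sin(2 * np.pi * params.alpha_freq * t + phase))
        data[i] = sig
    truth = design.copy()
    truth["true_amplitude"] = truth_amp
    labels = design.reset_index(drop=True).copy()
    ep = Epochs(data, srate, channels, labels, tmin=tmin)
    return ep, truth


def simulate_dataset(design: pd.DataFrame, params: GenerativeParams,
                     channels=C.MONTAGE64, srate: float = C.RAW_SRATE,
                     out_dir=None) -> tuple[list[Recording], pd.DataFrame, np.ndarray]:
    """Generate continuous 10 s/trial recordings, one per subject x session.

    Each trial starts with a 200 ms signal-free gray-screen gap, then the
    5 Hz kernel train; a stimulus marker (image id) is placed at every
    trial start.  Returns (recordings, ground-truth table, mixing weights);
    if ``out_dir`` is given, each recording is also written as a
    BrainVision triplet ``sub-XX_ses-YY.vhdr``.
    """
    channels = list(channels)
    required = set(C.CLUSTER9)
    if not required.issubset(channels):
        raise ValueError(
            f"channel set must include the parieto-occipital cluster "
            f"{sorted(required - set(channels))} are missing"
        )
    rng = np.random.default_rng(params.seed)
    mix = evoked_topography(channels, params)
    alpha_mix = _alpha_topography(channels)
    a_r = amplitude_profile(params)
    intercepts = _subject_intercepts(params, design["subject"])
    trial_samp = int(round(C.TRIAL_S * srate))
    p100_train, n170_trains = _component_trains(params, srate, C.TRIAL_S,
                                                skip_before_s=C.GRAY_LEAD_S)

    recordings, truth_rows = [], []
    for (subject, session), grp in design.groupby(["subject", "session"], sort=True):
        grp = grp.sort_values("trial")
        n_samples = trial_samp * len(grp)
        data = np.zeros((len(channels), n_samples))
        events = []
        t_trial = np.arange(trial_samp) / srate
        for k, row in enumerate(grp.itertuples(index=False)):
            start = k * trial_samp
            amp = a_r[row.realness - 1] + intercepts[row.subject]
            seg = np.outer(mix, p100_train + amp * n170_trains[row.realness])
            if params.alpha_sd > 0:
                phase = rng.uniform(0, 2 * np.pi)
                seg = seg + params.alpha_sd * np.outer(
                    alpha_mix,
                    np.sin(2 * np.pi * params.alpha_freq * t_trial + phase))
            data[:, start:start + trial_samp] = seg
            events.append((start, row.image_id))
            truth_rows.append(dict(subject=subject, session=session,
                                   trial=row.trial, image_id=row.image_id,
                                   realness=row.realness,
                                   true_amplitude=amp))
        if params.noise_sd > 0:
            data += params.noise_sd * _pink_noise(
                rng, (len(channels),), n_samples, srate, params.pink_exponent)
        rec = Recording(data, srate, channels, events,
                        meta=dict(subject=int(subject), session=int(session)))
        recordings.append(rec)
        if out_dir is not None:
            base = Path(out_dir) / f"sub-{subject:02d}_ses-{session:02d}"
            write_brainvision(rec, base)
    return recordings, pd.DataFrame(truth_rows), mix


def simulate_amplitudes(design: pd.DataFrame, params: GenerativeParams,
                        seed: int | None = None) -> pd.DataFrame:
    """Per-trial response amplitudes without waveform simulation.

    Amplitude = a(realness) + subject intercept + trial noise.  This is the
    generative model the mixed-model comparison assumes, used for
    statistical calibration studies where full EEG synthesis is
    unnecessary.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    a_r = amplitude_profile(params)
    subjects = sorted(design["subject"].unique())
    intercepts = {s: float(rng.normal(0.0, params.subject_sd)) for s in subjects}
    out = design.copy()
    out["amplitude"] = (
        a_r[out["realness"].to_numpy() - 1]
        + out["subject"].map(intercepts).to_numpy()
        + rng.normal(0.0, params.amplitude_noise_sd, len(out))
    )
    return out


def write_tables(out_dir, design: pd.DataFrame | None = None,
                 stimulus: pd.DataFrame | None = None,
                 truth: pd.DataFrame | None = None) -> list[Path]:
    """Write design/stimulus/ground-truth tables as TSV; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (("design", design), ("stimuli", stimulus),
                     ("ground_truth", truth)):
        if df is not None:
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
    return written
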