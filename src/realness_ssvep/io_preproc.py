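"""Reading, filtering, epoching and downsampling of multi-channel EEG.

Containers
----------
:class:`Recording`
    Continuous channels x samples data in microvolts with event markers.
:class:`Epochs`
    Trials x channels x samples with one label row per trial.
:class:`SegmentedEpochs`
    Trials x segments x channels x samples, where segments are
    consecutive non-overlapping 200 ms windows aligned to face onsets.

The preprocessing chain mirrors a frequency-tagging pipeline: zero-phase
band-pass (3-40 Hz Butterworth, order 3 per pass of the forward-backward
filter), trimming of each 10 s trial to [1 s, 9 s] to drop SSVEP ramp-up
and ramp-down, decimation to 250 Hz with an anti-alias low-pass, and
segmentation into 200 ms stimulus-locked windows (40 per 8 s trial).

File I/O: BrainVision triplets (.vhdr/.vmrk/.eeg) are written natively
(multiplexed IEEE float 32, microvolts) and read back through MNE, which
also provides EDF reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .constants import decode_image_id

__all__ = [
    "Recording",
    "Epochs",
    "SegmentedEpochs",
    "FormatError",
    "read_raw",
    "write_brainvision",
    "write_edf",
    "save_epochs",
    "load_epochs",
    "bandpass_filter",
    "trim_and_epoch",
    "downsample",
    "segment_200ms",
]


class FormatError(RuntimeError):
    """Raised when an EEG file set is missing parts or internally inconsistent."""


@dataclass
class Recording:
    """Continuous EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    srate: float
    ch_names: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.ch_names)} channel names"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        self.events = sorted(self.events)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), events=list(self.events),
                       meta=dict(self.meta))


@dataclass
class Epochs:
    """Epoched EEG: ``data`` is trials x channels x samples.

    ``tmin`` is the time of the first sample relative to the trial-start
    marker.  ``labels`` holds one row per trial (subject, session, trial,
    image_id, realness, gender, emotion).
    """

    data: np.ndarray
    srate: float
    ch_names: list[str]
    labels: pd.DataFrame
    tmin: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Epochs.data must be 3-D (trials x channels x samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} trials but {len(self.labels)} label rows"
            )
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the trial-start marker."""
        return self.tmin + np.arange(self.n_samples) / self.srate

    def pick_channels(self, names) -> "Epochs":
        """Return a copy restricted to ``names`` (order preserved as given)."""
        missing = [n for n in names if n not in self.ch_names]
        if missing:
            raise KeyError(f"channels not in epochs: {missing}")
        idx = [self.ch_names.index(n) for n in names]
        return Epochs(self.data[:, idx, :].copy(), self.srate, list(names),
                      self.labels.copy(), self.tmin)

    def crop(self, tmin: float, tmax: float) -> "Epochs":
        """Restrict to samples with time in [tmin, tmax) (trial-relative)."""
        t = self.times
        mask = (t >= tmin - 1e-9) & (t < tmax - 1e-9)
        if not mask.any():
            raise ValueError(f"empty crop window [{tmin}, {tmax})")
        return Epochs(self.data[:, :, mask].copy(), self.srate,
                      list(self.ch_names), self.labels.copy(), tmin=float(t[mask][0]))


@dataclass
class SegmentedEpochs:
    """Stimulus-locked segments: trials x segments x channels x samples."""

    data: np.ndarray
    srate: float
    ch_names: list[str]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("SegmentedEpochs.data must be 4-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label row count must equal trial count")

    @property
    def n_segments(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to each segment's face onset."""
        return np.arange(self.data.shape[3]) / self.srate


# ---------------------------------------------------------------------------
# BrainVision writing / reading
# ---------------------------------------------------------------------------

def write_brainvision(rec: Recording, basepath) -> Path:
    """Write ``rec`` as a BrainVision triplet; returns the .vhdr path.

    Data are stored multiplexed as IEEE float 32 in microvolts; markers are
    written as ``Stimulus,S<nnn>`` at their sample positions (1-based).
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    interval_us = 1e6 / rec.srate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.ch_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20200101120000000000",
    ]
    for k, (sample, code) in enumerate(rec.events, start=2):
        mlines.append(f"Mk{k}=Stimulus,S{code:>3d},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr


def write_edf(rec: Recording, path) -> Path:
    """Write a minimal EDF file (16-bit, 1 s data records, microvolts).

    Plain EDF carries no event markers; only the continuous signals are
    stored.  The recording is zero-padded to a whole number of 1 s
    records.  Amplitudes are quantized to the 16-bit digital range, so a
    read-back matches to ~(peak-to-peak range)/65535.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    srate = rec.srate
    if abs(srate - round(srate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(srate))
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((rec.n_channels, n_rec * spr))
    data[:, :rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767

    def pad(value, width):
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    ns = rec.n_channels
    header = b"".join([
        pad("0", 8), pad("X", 80), pad("synthetic EEG", 80),
        pad("01.01.20", 8), pad("12.00.00", 8),
        pad(256 * (1 + ns), 8), pad("", 44), pad(n_rec, 8), pad(1, 8),
        pad(ns, 4),
    ])
    fields = [
        [pad(name, 16) for name in rec.ch_names],
        [pad("AgAgCl electrode", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{v:.6g}"[:8], 8) for v in pmin],
        [pad(f"{v:.6g}"[:8], 8) for v in pmax],
        [pad(dmin, 8)] * ns,
        [pad(dmax, 8)] * ns,
        [pad("", 80)] * ns,
        [pad(spr, 8)] * ns,
        [pad("", 32)] * ns,
    ]
    header += b"".join(b"".join(f) for f in fields)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    with path.open("wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def save_epochs(ep: Epochs, basepath) -> Path:
    """Cache epochs as .npz (data) + .json sidecar (labels, metadata)."""
    import json

    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.savez(base.with_suffix(".npz"), data=ep.data)
    meta = dict(srate=ep.srate, tmin=ep.tmin, ch_names=list(ep.ch_names),
                labels={k: list(v) for k, v in
                        ep.labels.to_dict(orient="list").items()},
                data_file=base.with_suffix(".npz").name)
    side = base.with_suffix(".json")
    side.write_text(json.dumps(
        meta, default=lambda o: o.item() if hasattr(o, "item") else str(o)))
    return side


def load_epochs(sidecar_path) -> Epochs:
    """Load epochs written by :func:`save_epochs`."""
    import json

    side = Path(sidecar_path)
    meta = json.loads(side.read_text())
    data = np.load(side.parent / meta["data_file"])["data"]
    return Epochs(data, meta["srate"], meta["ch_names"],
                  pd.DataFrame(meta["labels"]), meta["tmin"])


def _check_brainvision(vhdr: Path) -> None:
    """Light consistency checks before handing the triplet to the reader."""
    if not vhdr.exists():
        raise FormatError(f"header file not found: {vhdr}")
    text = vhdr.read_text(encoding="utf-8", errors="replace")
    fields = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    for key in ("DataFile", "MarkerFile", "NumberOfChannels"):
        if key not in fields:
            raise FormatError(f"{vhdr.name}: missing {key} entry")
    data_file = vhdr.parent / fields["DataFile"]
    marker_file = vhdr.parent / fields["MarkerFile"]
    if not data_file.exists():
        raise FormatError(f"data file not found: {data_file}")
    if not marker_file.exists():
        raise FormatError(f"marker file not found: {marker_file}")
    n_ch = int(fields["NumberOfChannels"])
    fmt = fields.get("BinaryFormat", "IEEE_FLOAT_32")
    itemsize = {"IEEE_FLOAT_32": 4, "INT_16": 2}.get(fmt)
    if itemsize is None:
        raise FormatError(f"{vhdr.name}: unsupported BinaryFormat {fmt}")
    size = data_file.stat().st_size
    if size == 0 or size % (n_ch * itemsize) != 0:
        raise FormatError(
            f"{data_file.name}: size {size} bytes is not a whole number of "
            f"{n_ch}-channel frames ({fmt}); file truncated or corrupt"
        )


def read_raw(path, fmt: str | None = None) -> Recording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording into microvolts.

    ``fmt`` may be ``"brainvision"`` or ``"edf"``; by default it is inferred
    from the file extension.  Stimulus markers ``S<n>`` become events
    ``(sample_index, n)``.
    """
    import mne

    path = Path(path)
    if fmt is None:
        fmt = {".vhdr": "brainvision", ".edf": "edf"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from extension: {path.name}")
    if fmt == "brainvision":
        _check_brainvision(path)
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif fmt == "edf":
        if not path.exists():
            raise FormatError(f"EDF file not found: {path}")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format: {fmt!r}")

    data_uv = raw.get_data() * 1e6
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        token = desc.split("/")[-1].strip()
        if token.startswith("S"):
            try:
                code = int(token[1:].strip())
            except ValueError:
                continue
            events.append((int(round(onset * raw.info["sfreq"])), code))
    return Recording(data_uv, float(raw.info["sfreq"]), list(raw.ch_names), events)


# ---------------------------------------------------------------------------
# Filtering / epoching / resampling
# ---------------------------------------------------------------------------

def bandpass_filter(rec: Recording, low: float = 3.0, high: float = 40.0,
                    order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass, order ``order`` per pass.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    net magnitude response is the squared Butterworth response and the
    group delay is zero.
    """
    nyq = rec.srate / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high={high} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.srate,
                        output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def bandpass_sos(low: float, high: float, srate: float, order: int = 3):
    """SOS coefficients of the band-pass used by :func:`bandpass_filter`."""
    return signal.butter(order, [low, high], btype="bandpass", fs=srate,
                         output="sos")


def trim_and_epoch(rec: Recording, tmin: float = 1.0, tmax: float = 9.0,
                   subject=None, session=None) -> Epochs:
    """Cut trials into [tmin, tmax) windows relative to each trial marker.

    Defaults drop the first and last second of each 10 s trial, keeping
    8 s of steady-state response.  Trial labels are decoded from the
    stimulus image id carried by each marker; subject/session fall back to
    ``rec.meta`` when not given.
    """
    if tmax <= tmin:
        raise ValueError("tmax must exceed tmin")
    if not rec.events:
        raise ValueError("recording has no trial markers")
    start_off = int(round(tmin * rec.srate))
    stop_off = int(round(tmax * rec.srate))
    segments, rows = [], []
    subject = subject if subject is not None else rec.meta.get("subject", 0)
    session = session if session is not None else rec.meta.get("session", 0)
    for k, (sample, code) in enumerate(rec.events, start=1):
        stop = sample + stop_off
        if stop > rec.n_samples:
            raise ValueError(
                f"trial {k} (marker S{code} at sample {sample}) runs past the "
                f"end of the recording ({rec.n_samples} samples)"
            )
        segments.append(rec.data[:, sample + start_off:stop])
        realness, gender, emotion = decode_image_id(code)
        rows.append(dict(subject=subject, session=session, trial=k,
                         image_id=code, realness=realness, gender=gender,
                         emotion=emotion))
    return Epochs(np.stack(segments), rec.srate, list(rec.ch_names),
                  pd.DataFrame(rows), tmin=tmin)


def downsample(ep: Epochs, target: float = 250.0) -> Epochs:
    """Anti-alias low-pass (0.4 x target, zero-phase) then integer decimation."""
    factor = ep.srate / target
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"sampling rate {ep.srate} Hz is not an integer multiple of "
            f"target {target} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return Epochs(ep.data.copy(), ep.srate, list(ep.ch_names),
                      ep.labels.copy(), ep.tmin)
    sos = signal.butter(8, 0.4 * target, btype="low", fs=ep.srate, output="sos")
    smoothed = signal.sosfiltfilt(sos, ep.data, axis=2)
    return Epochs(smoothed[:, :, ::factor].copy(), target, list(ep.ch_names),
                  ep.labels.copy(), ep.tmin)


def segment_200ms(ep: Epochs, segment_ms: float = 200.0) -> SegmentedEpochs:
    """Reshape each trial into consecutive non-overlapping 200 ms segments.

    Segment boundaries coincide with face onsets provided the epoch start
    (``tmin``) is a multiple of the 200 ms stimulation period, which holds
    for the default [1 s, 9 s] trim.
    """
    seg_len = segment_ms / 1000.0 * ep.srate
    if abs(seg_len - round(seg_len)) > 1e-9:
        raise ValueError(
            f"segment of {segment_ms} ms is not a whole number of samples at "
            f"{ep.srate} Hz"
        )
    seg_len = int(round(seg_len))
    if ep.n_samples % seg_len != 0:
        raise ValueError(
            f"trial length {ep.n_samples} samples is not divisible by the "
            f"{seg_len}-sample segment; trim the epochs first"
        )
    n_seg = ep.n_samples // seg_len
    data = ep.data.reshape(ep.n_trials, len(ep.ch_names), n_seg, seg_len)
    data = np.ascontiguousarray(data.transpose(0, 2, 1, 3))
    return SegmentedEpochs(data, ep.srate, list(ep.ch_names), ep.labels.copy())
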