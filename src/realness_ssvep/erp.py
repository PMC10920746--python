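"""Time-domain (ERP-like) analysis of the 200 ms stimulus-locked segments.

With a 5 Hz presentation rate, each 8 s trial contributes forty 200 ms
segments; averaging them yields an ERP-like waveform in which an N170-like
negative deflection is measurable.  The N170 amplitude convention follows
the frequency-tagging literature: the *signed* amplitude is the mean value
in the 150-190 ms window (negative for a canonical N170); the magnitude is
its inverse, so larger magnitudes mean stronger responses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_preproc import SegmentedEpochs

__all__ = ["ERPWaveform", "N170Metrics", "compute_erp", "n170_metrics",
           "latency_anova", "erp_table"]


@dataclass
class ERPWaveform:
    """Averaged 200 ms response for one condition group and channel set."""

    condition: dict
    channel: str
    times_ms: np.ndarray
    waveform: np.ndarray
    n_segments: int


@dataclass
class N170Metrics:
    """N170 summary: signed window-mean amplitude and trough latency."""

    amplitude: float      # mean uV in [150, 190) ms, signed
    latency_ms: float     # time of the minimum within the search window
    channel: str
    window: tuple
    search: tuple

    @property
    def magnitude(self) -> float:
        """Inverted amplitude (larger = stronger N170)."""
        return -self.amplitude


def compute_erp(seg: SegmentedEpochs, group_by=("realness",),
                channels="PO8") -> list[ERPWaveform]:
    """Average segments within each label group at a channel or cluster.

    ``channels`` may be one channel name or a list (cluster: waveforms are
    averaged across member channels).  Returns one waveform per group, in
    sorted group order.
    """
    if isinstance(channels, str):
        members, chan_label = [channels], channels
    else:
        members = list(channels)
        chan_label = "+".join(members)
    missing = [c for c in members if c not in seg.ch_names]
    if missing:
        raise KeyError(f"channels not present: {missing}")
    idx = [seg.ch_names.index(c) for c in members]
    group_by = list(group_by)

    out = []
    for key, grp in seg.labels.groupby(group_by, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        rows = grp.index.to_numpy()
        if rows.size == 0:
            raise ValueError(f"empty group {dict(zip(group_by, key))}")
        # trials x segments x members x samples -> mean over all but samples
        block = seg.data[rows][:, :, idx, :]
        wave = block.mean(axis=(0, 1, 2))
        out.append(ERPWaveform(dict(zip(group_by, key)), chan_label,
                               seg.times * 1000.0, wave,
                               n_segments=rows.size * seg.n_segments))
    return out


def erp_table(waveforms: list[ERPWaveform]) -> pd.DataFrame:
    """Tidy long-format table of ERP waveforms."""
    frames = []
    for w in waveforms:
        df = pd.DataFrame({"time_ms": w.times_ms, "amplitude": w.waveform})
        for k, v in w.condition.items():
            df[k] = v
        df["channel"] = w.channel
        df["n_segments"] = w.n_segments
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def n170_metrics(erp: ERPWaveform, window=(150.0, 190.0),
                 search=(130.0, 200.0)) -> N170Metrics:
    """Signed window-mean amplitude and trough latency of the N170.

    Amplitude averages samples with ``window[0] <= t < window[1]`` ms;
    latency is the time of the waveform minimum within ``search``.
    """
    t = erp.times_ms
    if window[0] < t[0] or window[1] > t[-1] + (t[1] - t[0]):
        raise ValueError(f"window {window} outside ERP time axis "
                         f"[{t[0]}, {t[-1]}] ms")
    wmask = (t >= window[0]) & (t < window[1])
    smask = (t >= search[0]) & (t <= search[1])
    if not wmask.any() or not smask.any():
        raise ValueError("empty measurement window")
    amplitude = float(erp.waveform[wmask].mean())
    s_times, s_wave = t[smask], erp.waveform[smask]
    latency = float(s_times[np.argmin(s_wave)])
    return N170Metrics(amplitude, latency, erp.channel, tuple(window),
                       tuple(search))


def latency_anova(latencies: pd.DataFrame, dv: str = "latency_ms",
                  subject: str = "subject", factors=("realness", "emotion")
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way repeated-measures ANOVA on latencies + pairwise realness tests.

    ``latencies`` must contain one value per subject x factor cell.  The
    omnibus test is a two-factor repeated-measures ANOVA; post hoc, all 15
    pairs of realness levels are compared with paired t-tests on subject
    means and Bonferroni correction (p x 15, capped at 1).
    """
    import pingouin as pg

    f1, f2 = factors
    counts = latencies.groupby([subject, f1, f2], observed=True)[dv].count()
    n_subj = latencies[subject].nunique()
    expected = n_subj * latencies[f1].nunique() * latencies[f2].nunique()
    if len(counts) != expected or (counts != 1).any():
        raise ValueError(
            "latency table must contain exactly one value per "
            f"subject x {f1} x {f2} cell"
        )
    if n_subj < 2 or latencies[f1].nunique() < 2:
        raise ValueError("need at least 2 subjects and 2 factor levels")

    anova = pg.rm_anova(data=latencies, dv=dv, within=[f1, f2],
                        subject=subject, detailed=True)

    levels = sorted(latencies[f1].unique())
    subj_means = (latencies.groupby([subject, f1], observed=True)[dv]
                  .mean().unstack(f1))
    n_pairs = len(levels) * (len(levels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = subj_means[a] - subj_means[b]
        if np.allclose(diff.std(ddof=1), 0.0):
            tstat, p = 0.0, 1.0
        else:
            tstat, p = sps.ttest_rel(subj_means[a], subj_means[b])
        rows.append(dict(level_a=a, level_b=b, t=float(tstat),
                         p_uncorrected=float(p),
                         p_bonferroni=min(1.0, float(p) * n_pairs)))
    return anova, pd.DataFrame(rows)
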