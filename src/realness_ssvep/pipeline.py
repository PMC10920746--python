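"""End-to-end pipeline: simulate -> preprocess -> spectral/ERP/SSD -> TRCA -> stats.

A single config dict (YAML/JSON-serializable) drives every stage; outputs
are tidy TSV tables plus a JSON manifest recording the config hash and
per-stage status, so a saved config reruns to identical outputs.

Seeding: the global ``seed`` expands to per-stage seeds by a fixed counter
scheme (``stage_seed = seed * 100 + stage_index``), so stages are
individually reproducible when rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp, spectral, ssd, stats, synthetic_data, trca
from .constants import CLUSTER9, MONTAGE64
from .io_preproc import bandpass_filter, downsample, segment_200ms, trim_and_epoch
from .synthetic_data import GenerativeParams

__all__ = ["default_config", "validate_config", "run_pipeline"]

_STAGE_SEEDS = {"simulate": 0, "stimuli": 1, "permutation": 2}


def default_config() -> dict:
    """Scaled-down default configuration (simulate mode)."""
    return {
        "seed": 1,
        "out_dir": "results",
        "simulate": {
            "n_subjects": 4,
            "n_sessions": 4,
            "channels": "cluster9",
        },
        "filter": {"low": 3.0, "high": 40.0, "order": 3},
        "trim": {"tmin": 1.0, "tmax": 9.0},
        "downsample": {"target": 250.0},
        "spectral": {"freqs": [5.0, 10.0, 15.0], "channel": "Oz"},
        "ssd": {"signal_band": [4.0, 6.0],
                "noise_bands": [[2.0, 3.0], [7.0, 8.0]],
                "n_components": 3, "eig_threshold": 0.7},
        "erp": {"channel": "PO8", "window": [150.0, 190.0],
                "search": [130.0, 200.0]},
        "trca": {"tasks": ["six", "pair:1,6", "pair:5,6"],
                 "windows": [2.0, 8.0], "n_perm": 0},
    }


_CHANNEL_SETS = {"cluster9": CLUSTER9, "montage64": MONTAGE64}


def validate_config(config: dict) -> dict:
    """Merge with defaults and reject unknown fields or channel names."""
    defaults = default_config()
    merged = {}
    unknown = set(config) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for section, dvals in defaults.items():
        cval = config.get(section, dvals)
        if isinstance(dvals, dict):
            extra = set(cval) - set(dvals)
            if extra:
                raise ValueError(
                    f"unknown field(s) in config section {section!r}: "
                    f"{sorted(extra)}")
            merged[section] = {**dvals, **cval}
        else:
            merged[section] = cval
    chans = merged["simulate"]["channels"]
    if isinstance(chans, str):
        if chans not in _CHANNEL_SETS:
            raise ValueError(
                f"simulate.channels: unknown channel set {chans!r} "
                f"(choose from {sorted(_CHANNEL_SETS)})")
    else:
        bad = [c for c in chans if c not in MONTAGE64]
        if bad:
            raise ValueError(f"simulate.channels: unknown channel name(s) {bad}")
    for name in (merged["spectral"]["channel"], merged["erp"]["channel"]):
        if name not in MONTAGE64:
            raise ValueError(f"unknown channel name in config: {name!r}")
    return merged


def _task_classes(task: str) -> list[int]:
    if task == "six":
        return [1, 2, 3, 4, 5, 6]
    if task.startswith("pair:"):
        a, b = task.split(":", 1)[1].split(",")
        return [int(a), int(b)]
    raise ValueError(f"unknown task spec: {task!r}")


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path.name


def run_pipeline(config: dict) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {"config_hash": cfg_hash, "config": cfg, "stages": {},
                "outputs": []}

    def done(stage, *files):
        manifest["stages"][stage] = "ok"
        manifest["outputs"].extend(files)

    # --- simulate -----------------------------------------------------------
    sim = cfg["simulate"]
    channels = sim["channels"]
    if isinstance(channels, str):
        channels = list(_CHANNEL_SETS[channels])
    design = synthetic_data.make_design(sim["n_subjects"], sim["n_sessions"],
                                        seed=seed * 100 + _STAGE_SEEDS["simulate"])
    params = GenerativeParams(seed=seed * 100 + _STAGE_SEEDS["simulate"])
    stim = synthetic_data.make_stimulus_table(
        confound_slope=params.confound_slope,
        seed=seed * 100 + _STAGE_SEEDS["stimuli"])
    recordings, truth, mixing = synthetic_data.simulate_dataset(
        design, params, channels=channels)
    topo = pd.DataFrame({"channel": channels, "weight": mixing})
    done("simulate",
         _write(design, out_dir / "design.tsv"),
         _write(stim, out_dir / "stimuli.tsv"),
         _write(truth, out_dir / "ground_truth.tsv"),
         _write(topo, out_dir / "true_topography.tsv"))

    # --- preprocess ---------------------------------------------------------
    fl, tr = cfg["filter"], cfg["trim"]
    epochs_list = []
    for rec in recordings:
        filtered = bandpass_filter(rec, fl["low"], fl["high"], fl["order"])
        ep = trim_and_epoch(filtered, tr["tmin"], tr["tmax"])
        epochs_list.append(downsample(ep, cfg["downsample"]["target"]))
    ep_all = epochs_list[0]
    if len(epochs_list) > 1:
        data = np.concatenate([e.data for e in epochs_list])
        labels = pd.concat([e.labels for e in epochs_list], ignore_index=True)
        from .io_preproc import Epochs
        ep_all = Epochs(data, ep_all.srate, list(ep_all.ch_names), labels,
                        ep_all.tmin)
    manifest["stages"]["preprocess"] = "ok"

    # --- spectral -----------------------------------------------------------
    spec_cfg = cfg["spectral"]
    psd = spectral.welch_psd(ep_all.pick_channels([spec_cfg["channel"]]))
    amps = spectral.fft_amplitudes(ep_all, freqs=spec_cfg["freqs"])
    cluster = spectral.cluster_amplitudes(amps)
    amps_all = pd.concat([amps, cluster], ignore_index=True)
    done("spectral",
         _write(psd, out_dir / "psd.tsv"),
         _write(amps_all, out_dir / "fft_amplitudes.tsv"))

    # --- ssd ----------------------------------------------------------------
    ssd_cfg = cfg["ssd"]
    models, comp_amp_frames = [], []
    for subject, grp in design.groupby("subject", sort=True):
        recs = [r for r in recordings if r.meta["subject"] == subject]
        concat = recs[0].copy()
        concat.data = np.concatenate([r.data for r in recs], axis=1)
        concat.events = []
        model = ssd.fit_ssd(concat, tuple(ssd_cfg["signal_band"]),
                            tuple(tuple(b) for b in ssd_cfg["noise_bands"]),
                            ssd_cfg["n_components"], ssd_cfg["eig_threshold"])
        models.append(model)
    if all(m.n_components > 0 for m in models) and len(models) >= 2:
        selected, sim_matrix = ssd.match_components(models)
    else:
        selected = [0] * len(models)
        sim_matrix = np.eye(len(models))
    subjects = sorted(design["subject"].unique())
    for subj, model, comp in zip(subjects, models, selected):
        if model.n_components == 0:
            continue
        sub_ep = ep_all  # select this subject's trials
        rows = sub_ep.labels.index[sub_ep.labels["subject"] == subj].to_numpy()
        from .io_preproc import Epochs
        sub = Epochs(sub_ep.data[rows], sub_ep.srate, list(sub_ep.ch_names),
                     sub_ep.labels.iloc[rows], sub_ep.tmin)
        comp_ep = ssd.apply_ssd(model, sub)
        comp_amps = spectral.fft_amplitudes(comp_ep, freqs=[5.0],
                                            channels=[f"SSD{comp + 1}"])
        comp_amps["channel"] = "SSD"
        comp_amp_frames.append(comp_amps)
    ssd_amps = (pd.concat(comp_amp_frames, ignore_index=True)
                if comp_amp_frames else pd.DataFrame())
    pattern_rows = []
    for subj, model in zip(subjects, models):
        for k in range(model.n_components):
            for ch, val in zip(model.ch_names, model.patterns[:, k]):
                pattern_rows.append(dict(subject=subj, component=k + 1,
                                         channel=ch, pattern=val,
                                         eigenvalue=model.eigenvalues[k]))
    files = [_write(pd.DataFrame(pattern_rows), out_dir / "ssd_patterns.tsv")]
    if len(ssd_amps):
        files.append(_write(ssd_amps, out_dir / "ssd_amplitudes.tsv"))
    sim_df = pd.DataFrame(sim_matrix, columns=[f"s{s}" for s in subjects])
    files.append(_write(sim_df, out_dir / "ssd_pattern_similarity.tsv"))
    done("ssd", *files)

    # --- erp ----------------------------------------------------------------
    erp_cfg = cfg["erp"]
    seg = segment_200ms(ep_all)
    metric_rows = []
    waves = erp.compute_erp(seg, group_by=("subject", "realness"),
                            channels=erp_cfg["channel"])
    for w in waves + erp.compute_erp(seg, group_by=("subject", "realness"),
                                     channels=list(CLUSTER9)):
        m = erp.n170_metrics(w, tuple(erp_cfg["window"]),
                             tuple(erp_cfg["search"]))
        metric_rows.append(dict(**w.condition, channel=w.channel,
                                amplitude=m.amplitude, magnitude=m.magnitude,
                                latency_ms=m.latency_ms))
    n170 = pd.DataFrame(metric_rows)
    n170_single = n170[n170["channel"] == erp_cfg["channel"]]
    n170_cluster = n170[n170["channel"] != erp_cfg["channel"]]
    done("erp",
         _write(erp.erp_table(waves), out_dir / "erp_waveforms.tsv"),
         _write(n170, out_dir / "n170_metrics.tsv"))

    # --- trca ---------------------------------------------------------------
    trca_cfg = cfg["trca"]
    trca_rows, conf_files = [], []
    for task in trca_cfg["tasks"]:
        classes = _task_classes(task)
        for window in trca_cfg["windows"]:
            result = trca.cross_validate(ep_all, classes=classes,
                                         window_s=window)
            p_value = None
            if trca_cfg["n_perm"] > 0:
                perm = trca.permutation_test(
                    ep_all, classes=classes, n_perm=trca_cfg["n_perm"],
                    seed=seed * 100 + _STAGE_SEEDS["permutation"],
                    window_s=window)
                p_value = perm.p_value
            trca_rows.append(dict(task=task, window_s=window,
                                  accuracy=result.accuracy,
                                  accuracy_sd=result.accuracy_sd,
                                  n_trials=result.n_trials, p_value=p_value))
            conf = pd.DataFrame(result.confusion,
                                index=classes, columns=classes)
            name = f"confusion_{task.replace(':', '_').replace(',', '-')}_{window:g}s.tsv"
            conf.to_csv(out_dir / name, sep="\t")
            conf_files.append(name)
    done("trca", _write(pd.DataFrame(trca_rows), out_dir / "trca_results.tsv"),
         *conf_files)

    # --- stats --------------------------------------------------------------
    comparisons = []
    oz = amps_all[(amps_all["channel"] == spec_cfg["channel"])
                  & (amps_all["freq"] == 5.0)]
    comparisons.append(stats.compare_models(oz, unit=spec_cfg["channel"]))
    clus = amps_all[(amps_all["channel"] == "cluster9")
                    & (amps_all["freq"] == 5.0)]
    comparisons.append(stats.compare_models(clus, unit="cluster9"))
    if len(ssd_amps):
        comparisons.append(stats.compare_models(ssd_amps, unit="SSD"))
    for block, unit in ((n170_single, erp_cfg["channel"]),
                        (n170_cluster, "cluster9")):
        n170_amp = block.rename(columns={"magnitude": "n170_magnitude"})
        comparisons.append(stats.compare_models(
            n170_amp, response="n170_magnitude", unit=unit))
    # confound-adjusted variants (eye size merged by realness-level mean)
    eye = stim.groupby("realness", observed=True)["eye_size"].mean()
    oz_eye = oz.copy()
    oz_eye["eye_size"] = oz_eye["realness"].map(eye)
    comparisons.append(stats.compare_models(oz_eye, unit=spec_cfg["channel"],
                                            confound="eye_size"))
    table = pd.concat([c.to_rows() for c in comparisons], ignore_index=True)
    ci = stats.within_subject_ci(oz)
    corr = stats.stimulus_correlations(stim, amps=oz)
    balance = stats.confound_balance_tests(stim)
    done("stats",
         _write(table, out_dir / "model_comparison.tsv"),
         _write(ci, out_dir / "within_subject_ci.tsv"),
         _write(corr, out_dir / "correlations.tsv"),
         _write(balance, out_dir / "confound_balance.tsv"))

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    return manifest
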