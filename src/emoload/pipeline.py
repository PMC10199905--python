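"""End-to-end orchestration: synth -> preprocess -> ERSP -> cluster ->
behavior -> regression, under one config with per-stage derived seeds."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import cluster_stats as cs
from . import ersp as ersp_mod
from . import preprocess as pre
from . import synth
from . import traits_regression as tr
from .io import read_brainvision, read_events_tsv
from .montage import generate_montage

logger = logging.getLogger(__name__)

STAGES = ("synth", "preprocess", "ersp", "cluster", "behavior", "regress")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[stage:{stage}] {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every knob of the demo pipeline; round-trips through YAML."""

    out_dir: str = "emoload_out"
    master_seed: int = 7
    montage_preset: str = "low32"
    n_subjects_per_group: int = 6
    n_epochs_per_cell: int = 4
    loads: tuple = ("IAPS", "MOT4")
    effect_band: tuple = (4.0, 8.0)
    effect_window: tuple = (0.0, 0.5)
    effect_channels: tuple = ("F3", "Fz", "F4", "C3", "Cz")
    effect_db: float = 8.0
    effect_load: str = "MOT4"
    noise_rms_uv: float = 10.0
    bandpass_lo: float = 0.1
    bandpass_hi: float = 100.0
    line_freq: float = 60.0
    epoch_tmin: float = -1.11
    epoch_tmax: float = 2.0
    reject_uv: float = 150.0
    n_freqs: int = 16
    f_max: float = 40.0
    tfr_decim: int = 13
    n_surrogates: int = 200
    surrogate_alpha: float = 0.05
    n_perm: int = 200
    cluster_alpha: float = 0.05
    posthoc_alpha: float = 0.025
    min_sensors: int = 2
    regress_scales: tuple = ("UB", "TOT", "DSM-5", "AL", "SER")

    def stage_seed(self, stage: str) -> int:
        """Derived stream per stage: master * 100 + stage index (mod 2^31)."""
        return (self.master_seed * 100 + STAGES.index(stage)) % (2 ** 31)

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        fields = cls.__dataclass_fields__
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key: {k}")
            default = fields[k].default
            kwargs[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v) \
                if isinstance(v, list) else v
        return cls(**kwargs)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return every violated invariant (empty list = valid)."""
    errors = []
    for name in ("surrogate_alpha", "cluster_alpha", "posthoc_alpha"):
        a = getattr(config, name)
        if not (0.0 < a < 1.0):
            errors.append(f"{name} must lie in (0, 1), got {a}")
    if not isinstance(config.master_seed, (int, np.integer)):
        errors.append("master_seed must be an integer")
    if config.n_perm <= 0:
        errors.append("n_perm must be positive")
    if config.montage_preset not in ("low32", "high24", "shared"):
        errors.append(f"unknown montage preset {config.montage_preset!r}")
    if config.bandpass_lo >= config.bandpass_hi:
        errors.append("bandpass_lo must be below bandpass_hi")
    if config.epoch_tmin >= 0 or config.epoch_tmax <= 0:
        errors.append("epoch window must straddle the stimulus onset")
    if not (4.0 <= config.effect_band[0] < config.effect_band[1] <= 90.0):
        errors.append("effect band must lie within [4, 90] Hz")
    if config.effect_load not in config.loads:
        errors.append("effect_load must be one of the simulated loads")
    if config.n_subjects_per_group < 2:
        errors.append("need at least 2 subjects per group")
    return errors


def _study_config(config: PipelineConfig) -> synth.StudyConfig:
    effect = synth.EffectSpec(
        band=tuple(config.effect_band), window=tuple(config.effect_window),
        channels=tuple(config.effect_channels), delta_db=config.effect_db,
        conditions=tuple((e, config.effect_load) for e in synth.EMOTIONS))
    return synth.StudyConfig(
        n_subjects_per_group=config.n_subjects_per_group,
        n_epochs_per_cell=config.n_epochs_per_cell,
        loads=tuple(config.loads), effects=(effect,),
        noise={"exponent": 1.0, "rms_uv": config.noise_rms_uv},
        seed=config.stage_seed("synth"))


def _preprocess_one(config, vhdr, events_tsv, montage, sid, group):
    data, srate, labels, _ = read_brainvision(vhdr)
    order = [labels.index(l) for l in montage.labels]
    data = data[order]
    data = pre.average_rereference(data)
    data = pre.remove_channel_mean(data)
    data = pre.bandpass(data, srate, config.bandpass_lo, config.bandpass_hi)
    data = pre.remove_line_noise(data, srate, config.line_freq)
    bad = pre.detect_bad_channels(data, srate, config.line_freq)
    if bad:
        data = pre.spherical_spline_interpolate(
            data, montage, [montage.labels[i] for i in bad])
    events = read_events_tsv(events_tsv)
    epochs = pre.epoch(data, events, srate, config.epoch_tmin,
                       config.epoch_tmax, labels=montage.labels,
                       subject_id=sid, group=group)
    epochs, report = pre.reject_epochs_amplitude(epochs, config.reject_uv)
    epochs = pre.resample(epochs, 256.0)
    report.bad_channels = {montage.labels[i]: rules for i, rules in bad.items()}
    report.n_interpolated = len(bad)
    return epochs, report


def run_all(config: PipelineConfig) -> dict:
    """Run the whole demo study; returns the result bundle.

    Writes cluster tables, behavioral statistics, regression reports and a
    recovery report (detected vs planted effect) under ``config.out_dir``.
    Any stage failure raises ``StageError`` tagged with the stage name.
    """
    errors = validate_config(config)
    if errors:
        raise StageError("config", ValueError("; ".join(errors)))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    try:
        study = _study_config(config)
        manifest = synth.write_synthetic_study(study, out / "synth")
        bundle["manifest"] = manifest
    except StageError:
        raise
    except Exception as err:
        raise StageError("synth", err) from err

    try:
        montage = generate_montage(config.montage_preset)
        epochsets: dict = {}
        reports = {}
        for key, vhdr in manifest["eeg"].items():
            sid, load = key.split("/")
            if not sid.startswith("L"):
                continue  # demo analyses run within the low-traits group
            ep, rep = _preprocess_one(config, vhdr, manifest["events"][key],
                                      montage, sid, "low-ASRS")
            epochsets[(sid, load)] = ep
            reports[key] = rep
        bundle["preprocess_reports"] = reports
    except Exception as err:
        raise StageError("preprocess", err) from err

    try:
        freqs = np.linspace(4.0, config.f_max, config.n_freqs)
        stacks = {}
        for (sid, load), ep in epochsets.items():
            stacks[(sid, load)] = ersp_mod.compute_ersp(
                ep, freqs, decim=config.tfr_decim,
                n_surrogates=config.n_surrogates,
                alpha=config.surrogate_alpha,
                seed=config.stage_seed("ersp"))
        bundle["ersp"] = stacks
    except Exception as err:
        raise StageError("ersp", err) from err

    try:
        subjects = sorted({sid for sid, _ in stacks})
        ref_load = next(l for l in config.loads if l != config.effect_load)
        data = np.stack([
            np.stack([stacks[(sid, config.effect_load)].values,
                      stacks[(sid, ref_load)].values])
            for sid in subjects])  # subjects x 2 x ch x f x t
        adjacency = cs.build_adjacency(montage)
        clusters = cs.permutation_test(
            data, "paired", adjacency, n_perm=config.n_perm,
            seed=config.stage_seed("cluster"),
            min_sensors=config.min_sensors)
        stack0 = stacks[(subjects[0], config.effect_load)]
        for c in clusters:
            c.summarize(montage.labels, stack0.freqs, stack0.times)
        bundle["clusters"] = clusters
        table = pd.DataFrame([
            {"mass": c.mass, "p": c.monte_carlo_p,
             "time_lo": c.time_window[0], "time_hi": c.time_window[1],
             "freq_lo": c.freq_window[0], "freq_hi": c.freq_window[1],
             "channels": ",".join(c.channels)} for c in clusters])
        table.to_csv(out / "clusters.tsv", sep="\t", index=False)
        bundle["recovery"] = _recovery_report(config, clusters, stack0)
        (out / "recovery.json").write_text(json.dumps(bundle["recovery"], indent=2))
    except Exception as err:
        raise StageError("cluster", err) from err

    try:
        trials = pd.read_csv(Path(manifest["behavior"]), sep="\t")
        records = beh.tracking_records(trials)
        records.to_csv(out / "tracking.tsv", sep="\t", index=False)
        bundle["tracking"] = records
        if records["condition"].nunique() >= 2:
            anova = beh.rm_two_way_anova(records, "m_prime", "subject_id",
                                         "condition", between="group")
            bundle["tc_anova"] = anova
            (out / "tc_anova.json").write_text(json.dumps(
                {k: {kk: (list(vv) if isinstance(vv, tuple) else vv)
                     for kk, vv in v.items()}
                 for k, v in anova.effects.items()}, indent=2))
    except Exception as err:
        raise StageError("behavior", err) from err

    try:
        traits = pd.read_csv(Path(manifest["traits"]), sep="\t")
        cond = config.loads[-1] if "MOT4" not in records["condition"].values \
            else "MOT4"
        tc = records[records["condition"] == cond].set_index("subject_id")["m_prime"]
        x = traits.set_index("subject_id").loc[tc.index, list(config.regress_scales)]
        model = tr.ridge_gcv(x, tc.to_numpy())
        coef_table = pd.DataFrame({
            "predictor": model.predictors, "estimate": model.coef,
            "se": model.se, "t": model.t, "p": model.p})
        coef_table.to_csv(out / "ridge.tsv", sep="\t", index=False)
        bundle["ridge"] = model
    except Exception as err:
        raise StageError("regress", err) from err

    return bundle


def _recovery_report(config, clusters, stack) -> dict:
    """Did the best cluster hit the planted effect?"""
    planted = np.zeros(stack.values.shape, dtype=bool)
    ch_idx = [stack.labels.index(c) for c in config.effect_channels]
    f_sel = ((stack.freqs >= config.effect_band[0])
             & (stack.freqs <= config.effect_band[1]))
    t_sel = ((stack.times >= config.effect_window[0])
             & (stack.times <= config.effect_window[1]))
    planted[np.ix_(ch_idx, np.flatnonzero(f_sel), np.flatnonzero(t_sel))] = True
    report = {"planted_samples": int(planted.sum()), "detected": False,
              "best_p": None, "overlap": 0.0}
    if clusters:
        best = clusters[0]
        overlap = float((best.member_mask() & planted).sum() / planted.sum())
        report.update(detected=bool(best.monte_carlo_p <= config.cluster_alpha
                                    and overlap > 0),
                      best_p=best.monte_carlo_p, overlap=overlap)
    return report
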