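"""Synthetic study generator: EEG epochs, MOT behavior, trait scores.

The generator emulates the structure the downstream analysis assumes: 256 Hz
epochs spanning [-1.11, 2] s around auditory onsets presented at a 3.11 s
stimulus-onset asynchrony, six emotional-prosody categories x up to 24 trials
x three visual-load conditions (neutral-image viewing, 4-disc MOT, 8-disc
MOT), a 1/f^alpha background, and band/time/channel-localized event-related
synchronization or desynchronization planted in dB against the realized
pre-stimulus baseline.

Planted effects are implemented multiplicatively: the band-limited component
of the background is rescaled by 10^(dB/20) inside the effect window (with a
tapered edge), so the window band power changes by exactly the requested dB
relative to the untouched baseline -- the contract the ERSP stage recovers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .montage import Montage, generate_montage

SRATE = 256.0
N_SAMPLES = 797            # floor(3.11 s * 256 Hz) + 1
ONSET_IDX = 285            # t = 0 lands on this sample
SOA = 3.11                 # stimulus-onset asynchrony, s
EMOTIONS = ("anger", "disgust", "fear", "happiness", "neutral", "sadness")
LOADS = ("IAPS", "MOT4", "MOT8")
GROUPS = ("low-ASRS", "high-ASRS")

#: the 13 trait scales (T-scores, mean 50 / SD 10 in the normative sample)
TRAIT_SCALES = (
    "SC", "UB", "SR", "TOT", "DSM-5", "PS", "AS",
    "SER", "AL", "ST", "BR", "SS", "AT",
)


def epoch_times(n_samples: int = N_SAMPLES, onset_idx: int = ONSET_IDX,
                srate: float = SRATE) -> np.ndarray:
    """Time axis in seconds relative to stimulus onset."""
    return (np.arange(n_samples) - onset_idx) / srate


@dataclass(frozen=True)
class EffectSpec:
    """A planted band/time/channel-localized power change.

    Parameters
    ----------
    band : (float, float)
        Frequency band [f_lo, f_hi] in Hz, inside [4, 90].
    window : (float, float)
        Post-stimulus time window [t_start, t_end] in s, inside [0, 2].
    channels : tuple of str
        Channel labels the effect is planted on.
    delta_db : float
        Signed power change in dB; positive = synchronization (ERS),
        negative = desynchronization (ERD).
    conditions : tuple of (emotion, load) pairs
        Cells the effect applies to; empty tuple means every cell.
    """

    band: tuple[float, float]
    window: tuple[float, float]
    channels: tuple[str, ...]
    delta_db: float
    conditions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        f_lo, f_hi = self.band
        if not (4.0 <= f_lo < f_hi <= 90.0):
            raise ValueError(f"band must satisfy 4 <= lo < hi <= 90, got {self.band}")
        t0, t1 = self.window
        if not (0.0 <= t0 < t1 <= 2.0):
            raise ValueError(f"window must satisfy 0 <= start < end <= 2, got {self.window}")
        if len(self.channels) == 0:
            raise ValueError("effect needs at least one channel")

    def applies_to(self, emotion: str, load: str) -> bool:
        if not self.conditions:
            return True
        return (emotion, load) in self.conditions


@dataclass
class EpochSet:
    """Subject-level epoched EEG tensor with condition labels.

    ``data`` is (n_epochs, n_channels, n_samples) in microvolts; ``times`` is
    seconds relative to stimulus onset; ``emotions`` labels each epoch.
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    labels: tuple[str, ...]
    emotions: np.ndarray
    load: str
    subject_id: str = "S00"
    group: str = "low-ASRS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("channel count does not match labels")
        if self.data.shape[2] != len(self.times):
            raise ValueError("sample count does not match time axis")
        if len(self.emotions) != self.data.shape[0]:
            raise ValueError("one emotion label per epoch required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be all-finite")
        self.emotions = np.asarray(self.emotions, dtype=object)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select_emotion(self, emotion: str) -> "EpochSet":
        keep = self.emotions == emotion
        return EpochSet(self.data[keep], self.times, self.srate, self.labels,
                        self.emotions[keep], self.load, self.subject_id, self.group)


def pink_noise(shape, srate: float, rng: np.random.Generator,
               exponent: float = 1.0, rms_uv: float = 10.0) -> np.ndarray:
    """1/f^exponent Gaussian noise along the last axis, scaled to a target RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    cur = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x * (rms_uv / cur)


def _band_sos(band, srate):
    lo, hi = band
    return signal.butter(4, [lo, hi], btype="bandpass", fs=srate, output="sos")


def _window_taper(n_win: int) -> np.ndarray:
    # flat over ~80% of the window, cosine ramps at the edges
    return signal.windows.tukey(n_win, alpha=0.2)


def _apply_effect_windows(data: np.ndarray, srate: float, effect: EffectSpec,
                          ch_idx: np.ndarray, onsets_smp: np.ndarray) -> None:
    """Rescale the band component of ``data`` (channels x samples, in place)
    by 10^(dB/20) inside the effect window after each onset."""
    if len(ch_idx) == 0 or len(onsets_smp) == 0:
        return
    gain = 10.0 ** (effect.delta_db / 20.0)
    sos = _band_sos(effect.band, srate)
    band = signal.sosfiltfilt(sos, data[ch_idx], axis=-1)
    weight = np.zeros(data.shape[-1])
    i0 = int(round(effect.window[0] * srate))
    i1 = int(round(effect.window[1] * srate))
    taper = _window_taper(i1 - i0)
    for onset in onsets_smp:
        a, b = onset + i0, onset + i1
        if a < 0 or b > data.shape[-1]:
            raise ValueError("effect window falls outside the recording")
        weight[a:b] = np.maximum(weight[a:b], taper)
    data[ch_idx] += (gain - 1.0) * weight * band


def generate_epochs(montage: Montage, effects=(), n_epochs_per_cell: int = 24,
                    noise: dict | None = None, seed: int = 0,
                    load: str = "MOT4", subject_id: str = "S00",
                    group: str = "low-ASRS") -> EpochSet:
    """Generate one subject x load EpochSet with planted ERS/ERD effects.

    ``noise`` takes keys ``exponent`` (1/f slope, default 1.0) and ``rms_uv``
    (default 10). Epochs cycle over the six emotions, ``n_epochs_per_cell``
    each (capped at 24, the per-cell trial count of the study design).
    Identical seeds give bit-identical output.
    """
    if not (1 <= n_epochs_per_cell <= 24):
        raise ValueError("n_epochs_per_cell must be in 1..24")
    noise = {"exponent": 1.0, "rms_uv": 10.0, **(noise or {})}
    for eff in effects:
        missing = [c for c in eff.channels if c not in montage.labels]
        if missing:
            raise ValueError(f"effect channels not in montage: {missing}")
    rng = np.random.default_rng(seed)
    emotions = np.array(
        [e for e in EMOTIONS for _ in range(n_epochs_per_cell)], dtype=object)
    n_epochs = len(emotions)
    data = pink_noise((n_epochs, len(montage), N_SAMPLES), SRATE, rng,
                      noise["exponent"], noise["rms_uv"])
    for eff in effects:
        ch_idx = np.array([montage.index(c) for c in eff.channels])
        for ep in range(n_epochs):
            if eff.applies_to(emotions[ep], load):
                _apply_effect_windows(data[ep], SRATE, eff, ch_idx,
                                      np.array([ONSET_IDX]))
    return EpochSet(data, epoch_times(), SRATE, montage.labels, emotions,
                    load, subject_id, group)


def generate_continuous(montage: Montage, effects=(), n_epochs_per_cell: int = 24,
                        noise: dict | None = None, seed: int = 0,
                        load: str = "MOT4", pad_s: float = 2.0):
    """Continuous recording with events at the study SOA.

    Returns ``(data channels x samples, events DataFrame)`` where events has
    columns onset_s / emotion / load. Emotion order is a seeded shuffle, as in
    the randomized stimulus sequences of the task.
    """
    noise = {"exponent": 1.0, "rms_uv": 10.0, **(noise or {})}
    rng = np.random.default_rng(seed)
    emotions = np.array(
        [e for e in EMOTIONS for _ in range(n_epochs_per_cell)], dtype=object)
    rng.shuffle(emotions)
    n_events = len(emotions)
    n_samples = int(round((2 * pad_s + n_events * SOA) * SRATE))
    data = pink_noise((len(montage), n_samples), SRATE, rng,
                      noise["exponent"], noise["rms_uv"])
    onsets_s = pad_s + np.arange(n_events) * SOA
    onsets_smp = np.round(onsets_s * SRATE).astype(int)
    for eff in effects:
        ch_idx = np.array([montage.index(c) for c in eff.channels])
        hits = onsets_smp[[eff.applies_to(e, load) for e in emotions]]
        _apply_effect_windows(data, SRATE, eff, ch_idx, hits)
    events = pd.DataFrame(
        {"onset_s": onsets_s, "emotion": emotions, "load": load})
    return data, events


def generate_mot_behavior(m_true: float, d: int, n_trials: int = 40,
                          seed: int = 0, subject_id: str = "S00",
                          group: str = "low-ASRS") -> pd.DataFrame:
    """Bernoulli MOT trial table for one subject x condition.

    The per-trial success probability follows the study's guessing model with
    a single target: p_true = (m_true + d/2) / d, so m_true = d/2 gives
    certain success and m_true = -d/2 certain failure. (As printed, this model
    puts chance at 1/2 for d = 4 rather than the stated 1/d guess rate; the
    generator follows the printed form.)
    """
    if not (-d / 2 <= m_true <= d / 2):
        raise ValueError(f"m_true must be within [-d/2, d/2] = [{-d/2}, {d/2}]")
    p_true = float(np.clip((m_true + d / 2) / d, 0.0, 1.0))
    rng = np.random.default_rng(seed)
    correct = (rng.random(n_trials) < p_true).astype(int)
    return pd.DataFrame({
        "subject_id": subject_id,
        "group": group,
        "condition": f"MOT{d}",
        "trial": np.arange(1, n_trials + 1),
        "n": 1,
        "d": d,
        "correct": correct,
    })


def default_trait_correlation(rho: float = 0.95) -> np.ndarray:
    """Compound-symmetric inter-scale correlation.

    The default rho = 0.95 reproduces the severe multicollinearity that the
    trait-regression stage is built around (most scales with VIF >= 10 at
    n = 31).
    """
    k = len(TRAIT_SCALES)
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


def generate_trait_scores(n_subjects: int, group_means=None, correlation=None,
                          sd: float = 10.0, seed: int = 0,
                          group: str = "low-ASRS",
                          subject_ids=None) -> pd.DataFrame:
    """Multivariate-normal T-score table, rounded to integers in [20, 120]."""
    k = len(TRAIT_SCALES)
    if group_means is None:
        group_means = np.full(k, 65.0 if group == "high-ASRS" else 45.0)
    group_means = np.asarray(group_means, dtype=float)
    if correlation is None:
        correlation = default_trait_correlation()
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (k, k) or not np.allclose(correlation, correlation.T):
        raise ValueError("correlation must be a symmetric 13 x 13 matrix")
    try:
        chol = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as err:
        raise ValueError("correlation matrix must be positive-definite") from err
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_subjects, k)) @ (sd * chol.T)
    scores = np.clip(np.round(group_means + z), 20, 120).astype(int)
    if subject_ids is None:
        subject_ids = [f"S{i:02d}" for i in range(n_subjects)]
    out = pd.DataFrame(scores, columns=list(TRAIT_SCALES))
    out.insert(0, "subject_id", list(subject_ids))
    out.insert(1, "group", group)
    return out


@dataclass
class StudyConfig:
    """Parameters of a written synthetic study."""

    n_subjects_per_group: int = 2
    n_epochs_per_cell: int = 4
    loads: tuple[str, ...] = ("IAPS", "MOT4", "MOT8")
    effects: tuple[EffectSpec, ...] = (
        EffectSpec(band=(4.0, 11.0), window=(0.0, 0.5),
                   channels=("F3", "Fz", "F4", "C3", "Cz"), delta_db=6.0),
    )
    noise: dict = field(default_factory=lambda: {"exponent": 1.0, "rms_uv": 10.0})
    #: effective targets tracked per (group, condition); the MOT4/MOT8 values
    #: mirror the two groups' observed capacity gap
    m_true: dict = field(default_factory=lambda: {
        ("low-ASRS", "MOT4"): 1.58, ("low-ASRS", "MOT8"): 2.6,
        ("high-ASRS", "MOT4"): 0.78, ("high-ASRS", "MOT8"): 1.32,
    })
    seed: int = 0


def write_synthetic_study(config: StudyConfig, out_dir) -> dict:
    """Emit a full synthetic study to ``out_dir``; return the file manifest.

    Per subject x load: a BrainVision recording plus an events TSV. Study
    level: behavior TSV, traits TSV, and a ground-truth JSON (planted effects,
    per-subject m_true, seeds) enabling recovery tests.
    """
    from .io import write_brainvision

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"eeg": {}, "events": {}, "ground_truth": None}
    behavior_rows, trait_tables = [], []
    gt = {"effects": [asdict(e) for e in config.effects],
          "m_true": {}, "seed": config.seed,
          "noise": config.noise,
          "n_epochs_per_cell": config.n_epochs_per_cell}
    for gi, grp in enumerate(GROUPS):
        montage = generate_montage("low32" if grp == "low-ASRS" else "high24")
        for si in range(config.n_subjects_per_group):
            sid = f"{'L' if grp == 'low-ASRS' else 'H'}{si:02d}"
            for load in config.loads:
                # stable per-(group, subject, load) stream
                seed = (config.seed * 1000003 + gi * 10007 + si * 101
                        + LOADS.index(load) * 13 + 1) % (2**31)
                data, events = generate_continuous(
                    montage, config.effects, config.n_epochs_per_cell,
                    config.noise, seed=seed, load=load)
                base = out / f"sub-{sid}_task-{load}"
                write_brainvision(
                    data, SRATE, montage.labels, base,
                    events=[(float(r.onset_s), f"{r.emotion}/{r.load}")
                            for r in events.itertuples()])
                events.to_csv(f"{base}_events.tsv", sep="\t", index=False)
                manifest["eeg"][f"{sid}/{load}"] = f"{base}.vhdr"
                manifest["events"][f"{sid}/{load}"] = f"{base}_events.tsv"
            # both MOT tasks are always performed, EEG loads aside
            for cond in ("MOT4", "MOT8"):
                bseed = (config.seed * 1000003 + gi * 10007 + si * 101
                         + LOADS.index(cond) * 13 + 7) % (2**31)
                m = config.m_true[(grp, cond)]
                behavior_rows.append(generate_mot_behavior(
                    m, int(cond[3:]), seed=bseed, subject_id=sid, group=grp))
                gt["m_true"][f"{sid}/{cond}"] = m
        trait_tables.append(generate_trait_scores(
            config.n_subjects_per_group, seed=config.seed + gi, group=grp,
            subject_ids=[f"{'L' if grp == 'low-ASRS' else 'H'}{i:02d}"
                         for i in range(config.n_subjects_per_group)]))
    behavior = pd.concat(behavior_rows, ignore_index=True)
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    manifest["behavior"] = str(out / "behavior.tsv")
    traits = pd.concat(trait_tables, ignore_index=True)
    traits.to_csv(out / "traits.tsv", sep="\t", index=False)
    manifest["traits"] = str(out / "traits.tsv")
    gt_path = out / "ground_truth.json"
    gt_path.write_text(json.dumps(gt, indent=2))
    manifest["ground_truth"] = str(gt_path)
    return manifest
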