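"""Continuous-EEG cleaning and epoching.

The chain mirrors a conventional scalp-EEG pipeline: average re-reference,
channel mean removal, 0.1-100 Hz zero-phase Butterworth bandpass, 60 Hz line
removal by sliding-window sinusoid regression, three-rule bad-channel
detection, spherical-spline interpolation (Perrin-style, order m = 4 with a
7-term Legendre expansion), epoching around auditory onsets, amplitude-based
epoch rejection, and polyphase resampling to 256 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal, special, stats

from .montage import Montage
from .synth import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """What the cleaning chain did: bad channels per rule, epoch counts."""

    bad_channels: dict = field(default_factory=dict)  # label -> [rule names]
    n_interpolated: int = 0
    n_epochs_in: int = 0
    n_epochs_kept: int = 0
    filter_settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_epochs_kept > self.n_epochs_in:
            raise ValueError("cannot keep more epochs than supplied")


def average_rereference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous channel mean (channels on axis -2)."""
    data = np.asarray(data, dtype=float)
    if data.shape[-2] < 2:
        raise ValueError("average reference needs at least two channels")
    return data - data.mean(axis=-2, keepdims=True)


def remove_channel_mean(data: np.ndarray) -> np.ndarray:
    """Subtract each channel's temporal mean (time on the last axis)."""
    data = np.asarray(data, dtype=float)
    return data - data.mean(axis=-1, keepdims=True)


def bandpass(data: np.ndarray, srate: float, lo: float = 0.1,
             hi: float = 100.0, order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth bandpass of the given total order.

    ``hi`` is clipped to 0.95 x Nyquist (with a logged warning) when it
    exceeds it, so a 200 Hz recording passes through a 0.1-95 Hz band.
    """
    if lo >= hi:
        raise ValueError("low cutoff must be below high cutoff")
    nyq = srate / 2.0
    if hi >= nyq:
        hi_clipped = 0.95 * nyq
        logger.warning("bandpass high cutoff %.3g Hz >= Nyquist %.3g Hz; "
                       "clipping to %.3g Hz", hi, nyq, hi_clipped)
        hi = hi_clipped
    # scipy doubles the order for bandpass designs
    sos = signal.butter(order // 2, [lo, hi], btype="bandpass",
                        fs=srate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def remove_line_noise(data: np.ndarray, srate: float, line: float = 60.0,
                      window_s: float = 4.0) -> np.ndarray:
    """Remove mains interference by windowed least-squares sinusoid fits.

    A sine/cosine pair at the line frequency and its harmonics (below
    Nyquist) is fitted in 4 s windows with 50 % overlap; the Hann-weighted
    fits are overlap-added and subtracted, so slow drifts of the line
    amplitude are tracked while broadband content is untouched.
    """
    data = np.asarray(data, dtype=float)
    if line >= srate / 2:
        raise ValueError("line frequency must be below Nyquist")
    orig_shape = data.shape
    flat = data.reshape(-1, orig_shape[-1])
    n = flat.shape[-1]
    win_len = min(int(round(window_s * srate)), n)
    hop = max(win_len // 2, 1)
    freqs = [f for f in np.arange(line, srate / 2, line) if f < 0.95 * srate / 2]
    t = np.arange(n) / srate
    fitted_num = np.zeros_like(flat)
    weight = np.zeros(n)
    hann = signal.windows.hann(win_len, sym=False)
    starts = list(range(0, max(n - win_len, 0) + 1, hop))
    if starts[-1] + win_len < n:
        starts.append(n - win_len)
    for s in starts:
        sl = slice(s, s + win_len)
        design = np.column_stack(
            [fn(2 * np.pi * f * t[sl]) for f in freqs for fn in (np.sin, np.cos)])
        coef, *_ = np.linalg.lstsq(design, flat[:, sl].T, rcond=None)
        fit = (design @ coef).T
        fitted_num[:, sl] += hann * fit
        weight[sl] += hann
    good = weight > 1e-6
    fitted = np.zeros_like(flat)
    fitted[:, good] = fitted_num[:, good] / weight[good]
    return (flat - fitted).reshape(orig_shape)


def _flatline_run(x: np.ndarray, srate: float, max_s: float = 5.0,
                  tol: float = 1e-8) -> bool:
    flat = np.abs(np.diff(x)) < tol
    if not flat.any():
        return False
    # longest run of consecutive True
    edges = np.diff(np.concatenate(([0], flat.view(np.int8), [0])))
    runs = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
    return runs.max() / srate > max_s


def detect_bad_channels(data: np.ndarray, srate: float, line: float = 60.0,
                        flat_s: float = 5.0, line_z: float = 4.0,
                        logprob_z: float = 5.0) -> dict:
    """Flag channels by three population rules.

    (1) a flatline longer than ``flat_s`` seconds; (2) line-band to broadband
    power ratio more than ``line_z`` SD above the channel population; (3) mean
    log-likelihood under a pooled Gaussian kernel density of amplitudes more
    than ``logprob_z`` SD below the population mean. Returns
    ``{label_index: [rules]}``; raises if every channel is flagged.
    """
    data = np.asarray(data, dtype=float)
    n_ch = data.shape[0]
    if n_ch < 8:
        raise ValueError("population rules need at least 8 channels")
    flagged: dict[int, list[str]] = {}

    for c in range(n_ch):
        if _flatline_run(data[c], srate, flat_s):
            flagged.setdefault(c, []).append("flatline")
    if len(flagged) == n_ch:
        raise ValueError("all channels flagged bad; data unusable")

    f, pxx = signal.welch(data, fs=srate, nperseg=min(int(srate * 2), data.shape[-1]))
    band = (f >= line - 1) & (f <= line + 1)
    total = pxx.sum(axis=1)
    ratio = np.where(total > 0, pxx[:, band].sum(axis=1) / np.where(total > 0, total, 1.0), 0.0)
    z = (ratio - ratio.mean()) / (ratio.std() + 1e-30)
    for c in np.flatnonzero(z > line_z):
        flagged.setdefault(int(c), []).append("line_noise")

    # deterministic subsampling keeps the KDE O(hundreds x thousands)
    eval_step = max(data.shape[-1] // 400, 1)
    samp = data[:, ::eval_step]
    pooled = samp.ravel()
    pool_step = max(pooled.size // 4000, 1)
    if pooled.std() > 0:
        kde = stats.gaussian_kde(pooled[::pool_step])  # Silverman bandwidth
        loglik = np.array([np.log(kde(samp[c]) + 1e-300).mean()
                           for c in range(n_ch)])
        zl = (loglik - loglik.mean()) / (loglik.std() + 1e-30)
        for c in np.flatnonzero(zl < -logprob_z):
            flagged.setdefault(int(c), []).append("log_probability")

    if len(flagged) == n_ch:
        raise ValueError("all channels flagged bad; data unusable")
    return flagged


def _spline_g(cosang: np.ndarray, m: int, terms: int) -> np.ndarray:
    """Spherical-spline kernel g(cos angle), Legendre series truncated."""
    g = np.zeros_like(cosang, dtype=float)
    for l in range(1, terms + 1):
        g += (2 * l + 1) / (l * (l + 1)) ** m * special.eval_legendre(l, cosang)
    return g / (4 * np.pi)


def spherical_spline_interpolate(data: np.ndarray, montage: Montage, bad,
                                 m: int = 4, terms: int = 7) -> np.ndarray:
    """Replace bad channels with the spherical-spline field estimate.

    ``bad`` is a set of labels; good channels are untouched. The spline is
    order ``m`` with the Legendre expansion truncated at ``terms`` terms, and
    reproduces spatially constant fields exactly (via its constant term).
    """
    bad = list(bad)
    if not bad:
        return np.array(data, dtype=float, copy=True)
    unknown = [b for b in bad if b not in montage.labels]
    if unknown:
        raise ValueError(f"bad channels not in montage: {unknown}")
    good_idx = np.array([i for i, l in enumerate(montage.labels) if l not in bad])
    bad_idx = np.array([montage.index(b) for b in bad])
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    pos = montage.positions
    g_gg = _spline_g(pos[good_idx] @ pos[good_idx].T, m, terms)
    g_bg = _spline_g(pos[bad_idx] @ pos[good_idx].T, m, terms)
    n_good = len(good_idx)
    a = np.zeros((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    # mapping matrix: bad = M @ good, from solving [G 1; 1' 0][c;c0]=[v;0]
    a_inv = np.linalg.pinv(a)
    mapping = np.hstack([g_bg, np.ones((len(bad_idx), 1))]) @ a_inv[:, :n_good]
    out = np.array(data, dtype=float, copy=True)
    out[..., bad_idx, :] = mapping @ out[..., good_idx, :]
    return out


def epoch(data: np.ndarray, events: pd.DataFrame, srate: float,
          tmin: float = -1.11, tmax: float = 2.0, labels=None,
          load: str | None = None, subject_id: str = "S00",
          group: str = "low-ASRS") -> EpochSet:
    """Cut epochs around event onsets.

    ``events`` needs columns onset_s and emotion (and optionally load).
    Events whose window exceeds the recording are dropped with a log entry.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    pre = int(np.ceil(-tmin * srate))
    n_samples = int(np.floor((tmax - tmin) * srate)) + 1
    times = (np.arange(n_samples) - pre) / srate
    eps, emos = [], []
    for row in events.itertuples():
        onset = int(round(row.onset_s * srate))
        start = onset - pre
        if start < 0 or start + n_samples > data.shape[-1]:
            logger.info("dropping event at %.3f s: epoch window outside "
                        "recording", row.onset_s)
            continue
        eps.append(data[:, start:start + n_samples])
        emos.append(row.emotion)
    if not eps:
        raise ValueError("no event fits inside the recording")
    if load is None:
        load = str(events["load"].iloc[0]) if "load" in events else "IAPS"
    return EpochSet(np.stack(eps), times, srate, tuple(labels),
                    np.array(emos, dtype=object), load, subject_id, group)


def reject_epochs_amplitude(epochs: EpochSet, threshold_uv: float = 150.0):
    """Drop epochs containing any |sample| above threshold.

    Returns ``(EpochSet, PreprocessReport)``; raises if nothing survives.
    This amplitude gate is the pipeline's stand-in for transient-artifact
    removal, sized for synthetic data that carries no physiological artifacts.
    """
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    if not keep.any():
        raise ValueError("all epochs exceed the amplitude threshold")
    report = PreprocessReport(
        n_epochs_in=epochs.n_epochs, n_epochs_kept=int(keep.sum()),
        filter_settings={"reject_threshold_uv": threshold_uv})
    kept = EpochSet(epochs.data[keep], epochs.times, epochs.srate,
                    epochs.labels, epochs.emotions[keep], epochs.load,
                    epochs.subject_id, epochs.group)
    return kept, report


def resample(epochs: EpochSet, target: float = 256.0) -> EpochSet:
    """Polyphase anti-aliased resampling to ``target`` Hz (downsampling only)."""
    if target > epochs.srate:
        raise ValueError("upsampling not supported")
    if target == epochs.srate:
        return epochs
    frac = Fraction(target / epochs.srate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=-1)
    times = epochs.times[0] + np.arange(data.shape[-1]) / target
    return EpochSet(data, times, target, epochs.labels, epochs.emotions,
                    epochs.load, epochs.subject_id, epochs.group)
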