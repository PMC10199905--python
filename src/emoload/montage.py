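"""Sensor montages on an idealized spherical head.

Two acquisition set-ups are supported: a 32-channel cap used for the
low-autistic-traits group and a 24-channel mobile set-up used for the
high-traits group, both placed by the modified expanded 10-20 system.
Group comparisons are restricted to the label intersection of the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: 32-channel cap (low-ASRS group).
LOW32_LABELS = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8", "Oz",
)

#: 24-channel mobile set-up (high-ASRS group).
HIGH24_LABELS = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz",
    "A1", "A2", "AFz", "CPz", "POz",
)


@dataclass(frozen=True)
class Montage:
    """Named scalp sensors with positions on the unit sphere.

    Parameters
    ----------
    labels : tuple of str
        Unique channel names (10-20 nomenclature).
    positions : ndarray, shape (n_channels, 3)
        Cartesian coordinates, each of unit norm (dimensionless).
    reference : str
        Reference label, or ``"average"``.
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    reference: str = "average"

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("montage needs at least one channel")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("every position must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels) -> "Montage":
        """Return the montage restricted to ``labels`` (order preserved)."""
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx], self.reference)

    def intersect(self, other: "Montage") -> "Montage":
        """Label intersection with another montage (this montage's order)."""
        keep = [l for l in self.labels if l in other.labels]
        return self.subset(keep)


def _ideal_positions(labels) -> np.ndarray:
    """Unit-sphere positions for 10-20 labels from the standard 10-05 layout.

    The template head-frame coordinates are least-squares sphere-fitted and
    projected radially, which idealizes the (slightly ellipsoidal) template
    onto a spherical head.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos_map = std.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos_map]
    if missing:
        raise ValueError(f"labels not in the 10-05 template: {missing}")
    xyz = np.array([pos_map[l] for l in labels], dtype=float)
    # least-squares sphere fit: minimize ||x - c||^2 - r^2 over (c, r)
    a = np.c_[2 * xyz, np.ones(len(xyz))]
    b = (xyz**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    centered = xyz - center
    return centered / np.linalg.norm(centered, axis=1, keepdims=True)


def generate_montage(preset: str) -> Montage:
    """Build one of the study montage presets.

    Parameters
    ----------
    preset : {"low32", "high24", "shared"}
        ``low32`` -- 32-channel cap; ``high24`` -- 24-channel mobile set-up;
        ``shared`` -- label intersection of the two (used for between-group
        statistics).
    """
    if preset == "low32":
        labels = LOW32_LABELS
    elif preset == "high24":
        labels = HIGH24_LABELS
    elif preset == "shared":
        labels = tuple(l for l in LOW32_LABELS if l in HIGH24_LABELS)
    else:
        raise ValueError(
            f"unknown montage preset {preset!r}; expected low32, high24 or shared"
        )
    return Montage(labels, _ideal_positions(labels))
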