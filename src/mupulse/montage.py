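"""32-channel extended 10-20 montage with a flat 2-D scalp projection.

The head is a unit circle in an (x, y) plane: +x is the subject's right,
+y anterior.  Positions are the standard schematic projection used for
topographic maps; they carry no volume-conduction physics — the forward
model in :mod:`mupulse.simulate` only needs relative scalp distances to
build smooth source topographies and to define electrode rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Label -> (x, y) on the unit-circle scalp plane.  Extended 10-20 layout,
# FPz is the (implicit) recording reference and not a data channel.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.52),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.67, 0.28), "FC1": (-0.25, 0.27), "FC2": (0.25, 0.27),
    "FC6": (0.67, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.52, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.52, 0.0), "T8": (1.0, 0.0),
    "TP9": (-1.03, -0.33), "CP5": (-0.67, -0.28), "CP1": (-0.25, -0.27),
    "CP2": (0.25, -0.27), "CP6": (0.67, -0.28), "TP10": (1.03, -0.33),
    "P7": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.52),
    "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO9": (-0.55, -0.85), "O1": (-0.31, -0.95), "Oz": (0.0, -1.0),
    "O2": (0.31, -0.95), "PO10": (0.55, -0.85),
}

#: Electrode rows (anterior to posterior), used for topography criteria.
ROWS: dict[str, tuple[str, ...]] = {
    "frontopolar": ("Fp1", "Fp2"),
    "frontal": ("F7", "F3", "Fz", "F4", "F8"),
    "frontocentral": ("FC5", "FC1", "FC2", "FC6"),
    "central": ("T7", "C3", "Cz", "C4", "T8"),
    "centroparietal": ("TP9", "CP5", "CP1", "CP2", "CP6", "TP10"),
    "parietal": ("P7", "P3", "Pz", "P4", "P8"),
    "occipital": ("PO9", "O1", "Oz", "O2", "PO10"),
}

#: Rows counted as "frontal" for ocular-artifact topography checks.
FRONTAL_ROWS = ("frontopolar", "frontal")


@dataclass(frozen=True)
class Montage:
    """Channel labels and their 2-D scalp positions."""

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")
        for required in ("C3", "C4"):
            if required not in self.labels:
                raise ValueError(f"montage must contain {required}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def row_indices(self, row: str) -> list[int]:
        return [self.index(lbl) for lbl in ROWS[row] if lbl in self.labels]


def standard_montage() -> Montage:
    """The 32-channel extended 10-20 montage (FPz reference convention)."""
    labels = tuple(_POSITIONS)
    pos = np.array([_POSITIONS[lbl] for lbl in labels], dtype=float)
    return Montage(labels=labels, positions=pos)


def gaussian_topography(montage: Montage, center: np.ndarray | str,
                        spread: float = 0.35) -> np.ndarray:
    """Smooth scalp topography peaking at ``center`` (label or 2-D point).

    Returns a unit-peak weight vector over channels; ``spread`` is the
    Gaussian radius in scalp-plane units.
    """
    if isinstance(center, str):
        center = montage.position(center)
    d2 = np.sum((montage.positions - np.asarray(center, float)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * spread**2))
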