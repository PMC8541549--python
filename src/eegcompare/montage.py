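"""10-10 montages for the dry and gel electrode systems.

Both caps are 32-channel 10-10 layouts that overlap on 29 electrodes.
The gel cap additionally carries M1, POz and a recorded M2 (right mastoid)
channel; the dry cap additionally carries AFz, FT9 and FT10 and is recorded
against an external M2 electrode that is not a data channel. Positions are
taken from the standard 10-10 sphere and projected azimuthal-equidistantly
into the unit head disc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: the 29 electrodes common to both caps
SHARED_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: extra electrodes per system (gel records M2 as a data channel)
GEL_EXTRA: tuple[str, ...] = ("M1", "POz", "M2")
DRY_EXTRA: tuple[str, ...] = ("AFz", "FT9", "FT10")

#: frontal electrodes used by the blink-component frontality criterion
#: (prefrontal midline sites included where the cap provides them — blink
#: fields peak between the eyes)
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fpz", "Fp2", "AFz",
                                     "F7", "F3", "F4", "F8")

#: electrodes excluded from the 40 Hz-ASSR analysis (weak/absent response)
ASSR_EXCLUDED_CHANNELS: tuple[str, ...] = ("T7", "T8", "P7", "P8", "O1", "O2", "Oz")

REFERENCE_LABEL = "M2"


def canonical_label(label: str) -> str:
    """Canonicalize a 10-10 channel label (``FZ`` -> ``Fz``, ``FP1`` -> ``Fp1``)."""
    lab = label.strip().upper()
    if not lab:
        raise ValueError("empty channel label")
    if lab.startswith("FP"):
        lab = "Fp" + lab[2:]
    if lab.endswith("Z"):
        lab = lab[:-1] + "z"
    return lab


@dataclass
class Montage:
    """Electrode labels with 2D positions inside the unit head disc."""

    labels: list[str]
    positions: np.ndarray  # (n, 2), ||p|| <= 1
    name: str = "10-10"

    def __post_init__(self) -> None:
        self.labels = [canonical_label(l) for l in self.labels]
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 2):
            raise ValueError("one 2D position per label required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        r = np.linalg.norm(self.positions, axis=1)
        if np.any(r > 1 + 1e-9):
            raise ValueError("montage positions must lie in the unit head disc")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(canonical_label(label))

    def get_positions(self, labels) -> np.ndarray:
        return self.positions[[self.index(l) for l in labels]]

    def subset(self, labels) -> "Montage":
        labels = [canonical_label(l) for l in labels]
        return Montage(labels, self.get_positions(labels), name=self.name)


_POSITION_CACHE: dict[str, np.ndarray] = {}


def _standard_positions_2d() -> dict[str, np.ndarray]:
    """2D unit-disc positions for every label either cap uses.

    Spherical 10-10 positions come from mne's standard montage; the
    azimuthal-equidistant projection maps inclination from the vertex to
    radius, normalized so the lowest electrode (mastoid) sits on the rim.
    """
    if _POSITION_CACHE:
        return dict(_POSITION_CACHE)
    import mne

    wanted = list(SHARED_CHANNELS) + list(GEL_EXTRA) + list(DRY_EXTRA)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1020")
    pos3d = std.get_positions()["ch_pos"]
    xyz = np.array([pos3d[l] for l in wanted])
    r3 = np.linalg.norm(xyz, axis=1)
    incl = np.arccos(np.clip(xyz[:, 2] / r3, -1.0, 1.0))
    azim = np.arctan2(xyz[:, 0], xyz[:, 1])  # 0 at nose, positive to the right
    rad = incl / incl.max()
    pts = np.column_stack([rad * np.sin(azim), rad * np.cos(azim)])
    for lab, p in zip(wanted, pts):
        _POSITION_CACHE[lab] = p
    return dict(_POSITION_CACHE)


def make_montage(system: str) -> Montage:
    """Build the 32-channel montage of one recording system.

    Parameters
    ----------
    system : {"dry", "gel"}
        The gel montage includes M1, POz and M2; the dry montage includes
        AFz, FT9 and FT10. Both contain the 29 shared channels.
    """
    system = system.lower()
    if system not in ("dry", "gel"):
        raise ValueError(f"unknown system {system!r}: expected 'dry' or 'gel'")
    extra = DRY_EXTRA if system == "dry" else GEL_EXTRA
    labels = list(SHARED_CHANNELS) + list(extra)
    pos = _standard_positions_2d()
    return Montage(labels, np.array([pos[l] for l in labels]), name=f"10-10 ({system})")


def shared_montage() -> Montage:
    """Montage restricted to the 29 channels common to both systems."""
    pos = _standard_positions_2d()
    return Montage(list(SHARED_CHANNELS),
                   np.array([pos[l] for l in SHARED_CHANNELS]),
                   name="10-10 (shared)")
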