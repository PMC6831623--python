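"""Packaged idealized 10-20/10-10 electrode coordinate table.

The layout is the textbook spherical idealization: nasion, inion and the
preauricular points sit on the equator of the scalp sphere, the midline and
10%-ring electrodes at their standard arc fractions, and interior electrodes
at great-circle midpoints of their neighbours. Head frame: +x right,
+y anterior, +z vertex.
"""
from __future__ import annotations

import numpy as np

from ..core import ElectrodeMontage, HeadModel

# (label, inclination from vertex [deg], azimuth from +x toward +y [deg])
_ANGLE_TABLE: list[tuple[str, float, float]] = [
    # 10% outer ring (inclination 72 deg): ring angle alpha from the front
    # midline, azimuth = 90 + alpha (left hemisphere positive alpha).
    ("Fp1", 72.0, 108.0),
    ("Fp2", 72.0, 72.0),
    ("F7", 72.0, 144.0),
    ("F8", 72.0, 36.0),
    ("FT7", 72.0, 162.0),
    ("FT8", 72.0, 18.0),
    ("T7", 72.0, 180.0),
    ("T8", 72.0, 0.0),
    ("TP7", 72.0, -162.0),
    ("TP8", 72.0, -18.0),
    ("P7", 72.0, -144.0),
    ("P8", 72.0, -36.0),
    ("O1", 72.0, -108.0),
    ("O2", 72.0, -72.0),
    ("Oz", 72.0, -90.0),
    # midline
    ("Fz", 36.0, 90.0),
    ("FCz", 18.0, 90.0),
    ("Cz", 0.0, 90.0),
    ("CPz", 18.0, -90.0),
    ("Pz", 36.0, -90.0),
    # coronal arc through the ears
    ("C3", 36.0, 180.0),
    ("C4", 36.0, 0.0),
]

# interior electrodes: great-circle midpoints of two table entries
_MIDPOINTS: list[tuple[str, str, str]] = [
    ("F3", "Fz", "F7"),
    ("F4", "Fz", "F8"),
    ("FC3", "FCz", "FT7"),
    ("FC4", "FCz", "FT8"),
    ("CP3", "CPz", "TP7"),
    ("CP4", "CPz", "TP8"),
    ("P3", "Pz", "P7"),
    ("P4", "Pz", "P8"),
]

# canonical channel order (frontal to occipital, left to right)
_ORDER = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]


def _unit(incl_deg: float, az_deg: float) -> np.ndarray:
    t = np.deg2rad(incl_deg)
    a = np.deg2rad(az_deg)
    return np.array([np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t)])


def standard_montage_30(head_model: HeadModel | None = None) -> ElectrodeMontage:
    """The 30-channel 10-20 montage projected to the scalp sphere."""
    head = head_model or HeadModel()
    units: dict[str, np.ndarray] = {lab: _unit(t, a) for lab, t, a in _ANGLE_TABLE}
    for lab, a, b in _MIDPOINTS:
        v = units[a] + units[b]
        units[lab] = v / np.linalg.norm(v)
    pos = np.stack([units[lab] for lab in _ORDER]) * head.scalp_radius
    return ElectrodeMontage(labels=tuple(_ORDER), positions=pos)
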