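"""Standard 10-20 scalp montage used throughout the package.

Coordinates are a 2-D azimuthal projection of the standard electrode
positions onto the unit disc (x: left→right, y: back→front, Cz at the
origin).  They are only used for distance-weighted interpolation of bad
channels, so centimetre-accurate digitised positions are not required.
"""

from __future__ import annotations

import numpy as np

# 30-channel extended 10-20 layout (the cap used for the recordings this
# package targets has 32 connectors, two of which are reference/ground).
POSITIONS_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.309, 0.951), "Fp2": (0.309, 0.951),
    "AF3": (-0.250, 0.750), "AF4": (0.250, 0.750),
    "F7": (-0.809, 0.588), "F3": (-0.400, 0.520),
    "Fz": (0.000, 0.500), "F4": (0.400, 0.520), "F8": (0.809, 0.588),
    "FC5": (-0.700, 0.300), "FC1": (-0.250, 0.250),
    "FC2": (0.250, 0.250), "FC6": (0.700, 0.300),
    "T7": (-1.000, 0.000), "C3": (-0.500, 0.000), "Cz": (0.000, 0.000),
    "C4": (0.500, 0.000), "T8": (1.000, 0.000),
    "CP5": (-0.700, -0.300), "CP1": (-0.250, -0.250),
    "CP2": (0.250, -0.250), "CP6": (0.700, -0.300),
    "P7": (-0.809, -0.588), "P3": (-0.400, -0.520),
    "Pz": (0.000, -0.500), "P4": (0.400, -0.520), "P8": (0.809, -0.588),
    "O1": (-0.309, -0.951), "Oz": (0.000, -1.000), "O2": (0.309, -0.951),
}

DEFAULT_CHANNELS: list[str] = list(POSITIONS_2D)

# Homologous frontal pairs (left, right) for the asymmetry index.
FRONTAL_PAIRS: list[tuple[str, str]] = [
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
]

# Frontal subset over which global field power is computed.
FRONTAL_CHANNELS: list[str] = [
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
]


def electrode_distance(a: str, b: str) -> float:
    """Euclidean distance between two montage labels in projected space."""
    xa, ya = POSITIONS_2D[a]
    xb, yb = POSITIONS_2D[b]
    return float(np.hypot(xa - xb, ya - yb))
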