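"""32-channel cap montage: labels, 2-D head coordinates, spatial weights.

The recording montage is a standard 10-20 layout of a 32-channel sports EEG
cap with CPz as the online reference, leaving 31 signal electrodes.
Coordinates are schematic top-down head positions (x: left(-) to right(+),
y: posterior(-) to anterior(+), unit circle at the ear ring) used for
topography plots and for the anterior-posterior weighting of ocular signals.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

#: (x, y) schematic positions; y > 0 is anterior (toward the eyes).
ELECTRODE_POSITIONS: Dict[str, Tuple[float, float]] = {
    "Fp1": (-0.31, 0.95),
    "Fpz": (0.00, 1.00),
    "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59),
    "F3": (-0.36, 0.52),
    "Fz": (0.00, 0.50),
    "F4": (0.36, 0.52),
    "F8": (0.81, 0.59),
    "FC5": (-0.62, 0.28),
    "FC1": (-0.22, 0.26),
    "FC2": (0.22, 0.26),
    "FC6": (0.62, 0.28),
    "M1": (-1.05, -0.35),
    "T7": (-1.00, 0.00),
    "C3": (-0.50, 0.00),
    "Cz": (0.00, 0.00),
    "C4": (0.50, 0.00),
    "T8": (1.00, 0.00),
    "M2": (1.05, -0.35),
    "CP5": (-0.62, -0.28),
    "CP1": (-0.22, -0.26),
    "CP2": (0.22, -0.26),
    "CP6": (0.62, -0.28),
    "P7": (-0.81, -0.59),
    "P3": (-0.36, -0.52),
    "Pz": (0.00, -0.50),
    "P4": (0.36, -0.52),
    "P8": (0.81, -0.59),
    "POz": (0.00, -0.75),
    "O1": (-0.31, -0.95),
    "O2": (0.31, -0.95),
}

#: Signal-electrode labels in recording order (reference CPz excluded).
CHANNEL_LABELS: List[str] = list(ELECTRODE_POSITIONS)

#: Electrodes closest to the eyes; their mean is the blink/EOG proxy.
FRONTAL_PROXY_CHANNELS: Tuple[str, str] = ("Fp1", "Fp2")

#: Posterior (visual-cortex) sites used by the default encoding profiles.
POSTERIOR_CHANNELS: Tuple[str, ...] = ("P7", "P3", "Pz", "P4", "P8", "POz", "O1", "O2")

#: Anterior sites dominated by ocular signals.
FRONTAL_CHANNELS: Tuple[str, ...] = ("Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8")


def positions(labels: List[str] | None = None) -> np.ndarray:
    """(n, 2) array of schematic positions for the given labels."""
    labels = labels or CHANNEL_LABELS
    return np.array([ELECTRODE_POSITIONS[lab] for lab in labels], dtype=float)


def frontality(label: str) -> float:
    """Weight in [0, 1] for how strongly ocular potentials project to a site.

    Quadratic falloff from the forehead: 1 at Fpz, ~0 behind the vertex.
    """
    y = ELECTRODE_POSITIONS[label][1]
    return float(np.clip(y, 0.0, 1.0) ** 2)


def laterality(label: str) -> float:
    """Signed left(-)/right(+) coordinate, used to sign horizontal EOG."""
    return ELECTRODE_POSITIONS[label][0]


def posteriority(label: str) -> float:
    """Weight in [0, 1] increasing toward occipital sites (alpha dominance)."""
    y = ELECTRODE_POSITIONS[label][1]
    return float(np.clip(-y, 0.0, 1.0))


def most_anterior(labels: List[str], k: int = 2) -> List[str]:
    """The ``k`` most anterior labels (largest y), e.g. the blink proxy pair."""
    return sorted(labels, key=lambda lab: -ELECTRODE_POSITIONS[lab][1])[:k]
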