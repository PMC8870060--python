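"""Greenwood place-frequency mapping for CT-measured electrode positions.

The human cochlea maps position along the basilar membrane to characteristic
frequency following Greenwood's function ``F = 165.4 * (10^(2.1*x) - 0.88)``
with ``x`` the *relative distance from the apex* (x=0 at the apex gives
19.85 Hz, x=1 at the base ~20.7 kHz).  Measurements are often reported as
distances from the round window instead; :class:`ElectrodeGeometry` carries
the orientation explicitly and converts.  Comparing each electrode's
tonotopic frequency with the center frequency its processor actually assigns
quantifies the place-frequency mismatch a fitting tries to compensate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fmap_core import FrequencyMap

__all__ = [
    "GREENWOOD_A",
    "GREENWOOD_ALPHA",
    "GREENWOOD_K",
    "ElectrodeGeometry",
    "compare_center_frequencies",
    "electrode_tonotopic_map",
    "greenwood_frequency",
    "greenwood_position",
    "read_geometry_csv",
]

GREENWOOD_A = 165.4      # Hz
GREENWOOD_ALPHA = 2.1    # decades over the full cochlear length
GREENWOOD_K = 0.88       # low-frequency integration constant

_TOL = 1e-12


def greenwood_frequency(x_rel):
    """Characteristic frequency (Hz) at relative distance ``x_rel`` from the apex.

    ``F = 165.4 * (10^(2.1*x) - 0.88)``, strictly increasing on [0, 1]:
    F(0) = 19.85 Hz at the apex, F(1) ~ 20677 Hz at the base.  Accepts
    scalars or arrays; raises ``ValueError`` outside [0, 1].
    """
    x = np.asarray(x_rel, dtype=float)
    if np.any(x < -_TOL) or np.any(x > 1 + _TOL):
        raise ValueError("relative position must lie in [0, 1]")
    f = GREENWOOD_A * (10.0 ** (GREENWOOD_ALPHA * x) - GREENWOOD_K)
    return float(f) if np.isscalar(x_rel) else f


def greenwood_position(frequency_hz):
    """Inverse map: relative distance from the apex for a frequency in Hz.

    Closed form ``x = log10(F/165.4 + 0.88) / 2.1``; defined for frequencies
    between F(0) and F(1).
    """
    f = np.asarray(frequency_hz, dtype=float)
    lo, hi = greenwood_frequency(0.0), greenwood_frequency(1.0)
    if np.any(f < lo * (1 - 1e-9)) or np.any(f > hi * (1 + 1e-9)):
        raise ValueError(f"frequency outside the audible Greenwood range [{lo:.2f}, {hi:.0f}] Hz")
    x = np.log10(f / GREENWOOD_A + GREENWOOD_K) / GREENWOOD_ALPHA
    return float(x) if np.isscalar(frequency_hz) else x


@dataclass(frozen=True)
class ElectrodeGeometry:
    """CT-measured electrode positions along the basilar membrane.

    ``orientation`` states what the millimetre positions mean: distance from
    the apex (``from_apex``) or from the round window (``from_round_window``).
    Positions are apex-first along the array (electrode 1 most apical) and
    must be strictly monotone.
    """

    cochlea_length_mm: float
    electrode_positions_mm: tuple[float, ...]
    orientation: str = "from_apex"

    def __post_init__(self):
        if self.cochlea_length_mm <= 0:
            raise ValueError("cochlea length must be > 0 mm")
        if self.orientation not in ("from_apex", "from_round_window"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")
        pos = np.asarray(self.electrode_positions_mm, dtype=float)
        if pos.size == 0:
            raise ValueError("no electrode positions given")
        if np.any(pos < 0) or np.any(pos > self.cochlea_length_mm):
            raise ValueError("positions must lie within [0, cochlea length]")
        d = np.diff(pos)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("positions must be strictly monotone along the array")

    def converted(self, orientation: str) -> "ElectrodeGeometry":
        """Same geometry expressed in the other reference (an involution)."""
        if orientation == self.orientation:
            return self
        flipped = tuple(self.cochlea_length_mm - p
                        for p in self.electrode_positions_mm)
        return ElectrodeGeometry(self.cochlea_length_mm, flipped, orientation)

    def relative_from_apex(self) -> np.ndarray:
        pos = np.asarray(self.electrode_positions_mm, dtype=float)
        if self.orientation == "from_round_window":
            pos = self.cochlea_length_mm - pos
        return pos / self.cochlea_length_mm


def electrode_tonotopic_map(geometry: ElectrodeGeometry) -> np.ndarray:
    """Greenwood characteristic frequency of each electrode, in Hz.

    Normalizes the measured positions by the cochlear length, converts to the
    distance-from-apex convention, and applies the Greenwood function.
    Apical electrodes map to lower frequencies.
    """
    return greenwood_frequency(geometry.relative_from_apex())


def compare_center_frequencies(
    greenwood_hz,
    default_map: FrequencyMap,
    ea_map: FrequencyMap,
    center_method: str = "geometric",
) -> pd.DataFrame:
    """Per-electrode table: tonotopic vs default vs optimizer center frequency.

    Columns hold the three center frequencies plus pairwise log2 ratios and a
    boolean per electrode for whether the tonotopic (Greenwood) frequency
    exceeds the processor's allocation — the typical situation with partial
    electrode insertion.
    """
    if default_map.electrodes != ea_map.electrodes:
        raise ValueError("default and optimized maps live on different electrode sets")
    g = np.asarray(greenwood_hz, dtype=float)
    if g.size != len(default_map.electrodes):
        raise ValueError("one Greenwood frequency per active electrode required")
    fc_def = np.asarray(default_map.center_frequencies(center_method))
    fc_ea = np.asarray(ea_map.center_frequencies(center_method))
    return pd.DataFrame({
        "electrode": list(default_map.electrodes),
        "greenwood_fc_hz": g,
        "default_fc_hz": fc_def,
        "ea_fc_hz": fc_ea,
        "log2_default_vs_greenwood": np.log2(fc_def / g),
        "log2_ea_vs_greenwood": np.log2(fc_ea / g),
        "log2_ea_vs_default": np.log2(fc_ea / fc_def),
        "greenwood_above_default": g > fc_def,
        "greenwood_above_ea": g > fc_ea,
    })


def read_geometry_csv(path: str | Path) -> ElectrodeGeometry:
    """Read electrode geometry from CSV.

    Header comment lines carry the scalars, e.g.::

        # cochlea_length_mm: 33.0
        # orientation: from_apex
        electrode,distance_mm
        1,2.1
        ...
    """
    length = None
    orientation = "from_apex"
    rows = []
    lines = Path(path).read_text().splitlines()
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            key, _, val = s.lstrip("# ").partition(":")
            key = key.strip().lower()
            if key == "cochlea_length_mm":
                length = float(val)
            elif key == "orientation":
                orientation = val.strip()
            continue
        rows.append(s)
    if length is None:
        raise ValueError(f"{path}: missing '# cochlea_length_mm:' header")
    df = pd.read_csv(io.StringIO("\n".join(rows)))
    df = df.sort_values(df.columns[0])
    return ElectrodeGeometry(
        cochlea_length_mm=length,
        electrode_positions_mm=tuple(df[df.columns[1]].astype(float)),
        orientation=orientation,
    )
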