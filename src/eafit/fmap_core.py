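"""Frequency-allocation-map (fMAP) data model and constraint logic.

A cochlear implant assigns each active electrode a contiguous analysis band
``[f_low, f_high]`` of the acoustic spectrum, apex-first (electrode 1 carries
the lowest frequencies).  Fitting software quantizes band edges to a
brand-specific grid and enforces a minimum band width.  This module holds the
device description (:class:`DeviceProfile`), the map itself
(:class:`FrequencyMap`), the search box for the optimizer
(:class:`ExplorationDomain`), and the deterministic repair operator that turns
an arbitrary vector of proposed upper edges into a valid map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ConfigurationError",
    "ConstraintError",
    "DeviceProfile",
    "ExplorationDomain",
    "FrequencyMap",
    "Violation",
    "BUILTIN_PROFILES",
    "center_frequency",
    "chain_and_repair",
    "load_profile",
    "make_exploration_domain",
    "validate",
]

_GRID_TOL = 1e-6


class ConfigurationError(ValueError):
    """A device profile or derived object is internally inconsistent."""


class ConstraintError(ValueError):
    """No valid map exists for the requested edges; names the electrode."""

    def __init__(self, message: str, electrode: int | None = None):
        super().__init__(message)
        self.electrode = electrode


@dataclass(frozen=True)
class DeviceProfile:
    """Constraint environment of one implant: electrodes, grid, default map.

    ``default_bands`` is apex-first: ``default_bands[0]`` belongs to electrode
    1, the most apical contact (lowest frequencies).  All edges must lie on
    the device grid ``global_f_min + k * freq_step_hz``.
    """

    brand_label: str
    n_electrodes: int
    default_bands: tuple[tuple[float, float], ...]
    freq_step_hz: float
    min_band_width_hz: float
    deactivated: frozenset[int] = frozenset()
    global_f_min: float | None = None

    def __post_init__(self):
        if self.n_electrodes < 1:
            raise ConfigurationError("n_electrodes must be >= 1")
        if len(self.default_bands) != self.n_electrodes:
            raise ConfigurationError(
                f"expected {self.n_electrodes} default bands, "
                f"got {len(self.default_bands)}"
            )
        if self.freq_step_hz <= 0 or self.min_band_width_hz <= 0:
            raise ConfigurationError("grid step and min band width must be > 0")
        if self.global_f_min is None:
            object.__setattr__(self, "global_f_min", self.default_bands[0][0])
        elif abs(self.global_f_min - self.default_bands[0][0]) > _GRID_TOL:
            raise ConfigurationError(
                "global_f_min must equal the lower edge of the most apical band"
            )
        prev_high = None
        for e, (lo, hi) in enumerate(self.default_bands, start=1):
            if hi - lo < self.min_band_width_hz - _GRID_TOL:
                raise ConfigurationError(
                    f"default band of electrode {e} narrower than the minimum width"
                )
            if prev_high is not None and abs(lo - prev_high) > _GRID_TOL:
                raise ConfigurationError(
                    f"default bands not contiguous at electrode {e}"
                )
            if not self._on_grid(lo) or not self._on_grid(hi):
                raise ConfigurationError(
                    f"default band edge of electrode {e} is off the device grid"
                )
            prev_high = hi
        bad = {e for e in self.deactivated if not 1 <= e <= self.n_electrodes}
        if bad:
            raise ConfigurationError(f"deactivated electrodes out of range: {sorted(bad)}")
        if len(self.deactivated) == self.n_electrodes:
            raise ConfigurationError("all electrodes are deactivated")

    # -- grid arithmetic -----------------------------------------------------
    def _on_grid(self, f: float) -> bool:
        k = (f - self.global_f_min) / self.freq_step_hz
        return abs(k - round(k)) < _GRID_TOL

    def grid_floor(self, f: float) -> float:
        k = math.floor((f - self.global_f_min) / self.freq_step_hz + _GRID_TOL)
        return self.global_f_min + k * self.freq_step_hz

    def grid_ceil(self, f: float) -> float:
        k = math.ceil((f - self.global_f_min) / self.freq_step_hz - _GRID_TOL)
        return self.global_f_min + k * self.freq_step_hz

    def grid_round(self, f: float) -> float:
        k = round((f - self.global_f_min) / self.freq_step_hz)
        return self.global_f_min + k * self.freq_step_hz

    # -- active-array view ---------------------------------------------------
    @property
    def active_electrodes(self) -> tuple[int, ...]:
        return tuple(
            e for e in range(1, self.n_electrodes + 1) if e not in self.deactivated
        )

    def active_default_map(self) -> "FrequencyMap":
        """Default map re-chained over active electrodes only.

        Deactivated electrodes are excluded as a precondition; their spectral
        range is absorbed by chaining the remaining electrodes' default upper
        edges from the device's global minimum frequency.
        """
        highs = [self.default_bands[e - 1][1] for e in self.active_electrodes]
        bands = []
        prev = self.global_f_min
        for h in highs:
            bands.append((prev, h))
            prev = h
        return FrequencyMap(
            electrodes=self.active_electrodes,
            bands=tuple(bands),
            id="default",
            origin="default",
            generation=0,
        )

    def with_deactivated(self, deactivated: Iterable[int]) -> "DeviceProfile":
        return replace(self, deactivated=frozenset(deactivated))

    # -- serialization -------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "DeviceProfile":
        bands = tuple((float(lo), float(hi)) for lo, hi in d["default_bands"])
        indexing = d.get("indexing", "apex_first")
        n = int(d["n_electrodes"])
        deact = frozenset(int(e) for e in d.get("deactivated", ()))
        if indexing == "base_first":
            bands = tuple((lo, hi) for lo, hi in reversed(bands))
            deact = frozenset(n + 1 - e for e in deact)
        elif indexing != "apex_first":
            raise ConfigurationError(f"unknown indexing convention: {indexing!r}")
        return cls(
            brand_label=str(d["brand_label"]),
            n_electrodes=n,
            default_bands=bands,
            freq_step_hz=float(d["freq_step_hz"]),
            min_band_width_hz=float(d["min_band_width_hz"]),
            deactivated=deact,
            global_f_min=float(d["global_f_min"]) if "global_f_min" in d else None,
        )

    def to_dict(self) -> dict:
        return {
            "brand_label": self.brand_label,
            "n_electrodes": self.n_electrodes,
            "default_bands": [[lo, hi] for lo, hi in self.default_bands],
            "freq_step_hz": self.freq_step_hz,
            "min_band_width_hz": self.min_band_width_hz,
            "deactivated": sorted(self.deactivated),
            "global_f_min": self.global_f_min,
            "indexing": "apex_first",
        }


@dataclass
class FrequencyMap:
    """One candidate frequency allocation over the active electrodes.

    This is the individual the evolutionary search manipulates.  Bands are
    apex-first, contiguous and non-overlapping; ``score`` holds the word
    recognition score (out of ten) once the map has been tested.
    """

    electrodes: tuple[int, ...]
    bands: tuple[tuple[float, float], ...]
    id: str = ""
    origin: str = "child"  # default | parent | child
    generation: int = 0
    score: float | None = None
    creation_index: int = -1

    def __post_init__(self):
        if len(self.electrodes) != len(self.bands):
            raise ConfigurationError("one band per active electrode required")

    @property
    def f_high(self) -> tuple[float, ...]:
        return tuple(b[1] for b in self.bands)

    @property
    def f_low(self) -> tuple[float, ...]:
        return tuple(b[0] for b in self.bands)

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(hi - lo for lo, hi in self.bands)

    def center_frequencies(self, method: str = "geometric") -> tuple[float, ...]:
        return tuple(center_frequency(b, method=method) for b in self.bands)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "origin": self.origin,
            "generation": self.generation,
            "score": self.score,
            "electrodes": list(self.electrodes),
            "bands": [[lo, hi] for lo, hi in self.bands],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencyMap":
        return cls(
            electrodes=tuple(int(e) for e in d["electrodes"]),
            bands=tuple((float(lo), float(hi)) for lo, hi in d["bands"]),
            id=d.get("id", ""),
            origin=d.get("origin", "child"),
            generation=int(d.get("generation", 0)),
            score=d.get("score"),
        )

    def to_csv(self, path: str | Path) -> None:
        lines = ["electrode,f_low_hz,f_high_hz"]
        lines += [f"{e},{lo:g},{hi:g}" for e, (lo, hi) in zip(self.electrodes, self.bands)]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ExplorationDomain:
    """Admissible interval for each active electrode's upper band edge.

    Per electrode the upper edge may move between the default band's lower
    edge and 1.2 times the default upper edge (quantized down to the device
    grid), so neighbouring bands can widen, shrink or shift without ever
    overlapping once re-chained.
    """

    electrodes: tuple[int, ...]
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self):
        for e, (lo, hi) in zip(self.electrodes, self.intervals):
            if not lo < hi:
                raise ConfigurationError(
                    f"empty exploration interval for electrode {e}: ({lo}, {hi})"
                )

    @property
    def lo(self) -> tuple[float, ...]:
        return tuple(iv[0] for iv in self.intervals)

    @property
    def hi(self) -> tuple[float, ...]:
        return tuple(iv[1] for iv in self.intervals)


@dataclass(frozen=True)
class Violation:
    electrode: int
    rule: str
    observed: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"electrode {self.electrode}: {self.rule} ({self.observed})"


def make_exploration_domain(
    profile: DeviceProfile, expansion: float = 1.2
) -> ExplorationDomain:
    """Search box for the optimizer, from the active-array default map.

    Each electrode's upper edge ranges from its default lower edge up to
    ``expansion`` times its default upper edge, the ceiling quantized down to
    the device grid.
    """
    default = profile.active_default_map()
    intervals = []
    for lo, hi in default.bands:
        top = profile.grid_floor(expansion * hi)
        intervals.append((lo, top))
    return ExplorationDomain(electrodes=default.electrodes, intervals=tuple(intervals))


def chain_and_repair(
    f_high_vector: Sequence[float],
    profile: DeviceProfile,
    domain: ExplorationDomain,
    *,
    id: str = "",
    origin: str = "child",
    generation: int = 0,
) -> FrequencyMap:
    """Turn proposed upper edges into a valid map, apex to base.

    Each band's lower edge is chained from the previous band's upper edge
    (the most apical band starts at the device's global minimum).  The
    proposed upper edge is clamped into
    ``[max(f_low + min_width, domain.lo), domain.hi]`` and snapped to the
    device grid.  Processing apex-first resolves monotonicity violations
    introduced by crossover deterministically and perturbs apical bands least.

    Raises :class:`ConstraintError` naming the first electrode for which no
    feasible upper edge exists.
    """
    if len(f_high_vector) != len(domain.electrodes):
        raise ConstraintError(
            f"expected {len(domain.electrodes)} upper edges, got {len(f_high_vector)}"
        )
    prev = profile.global_f_min
    bands = []
    for e, v, (lo, hi) in zip(domain.electrodes, f_high_vector, domain.intervals):
        lower = profile.grid_ceil(max(prev + profile.min_band_width_hz, lo))
        upper = profile.grid_floor(hi)
        if lower > upper + _GRID_TOL:
            raise ConstraintError(
                f"no feasible upper edge for electrode {e}: "
                f"requires >= {lower} Hz but domain tops out at {upper} Hz",
                electrode=e,
            )
        x = profile.grid_round(min(max(float(v), lower), upper))
        x = min(max(x, lower), upper)  # rounding may not leave the bracket
        bands.append((prev, x))
        prev = x
    return FrequencyMap(
        electrodes=domain.electrodes,
        bands=tuple(bands),
        id=id,
        origin=origin,
        generation=generation,
    )


def center_frequency(band: tuple[float, float], method: str = "geometric") -> float:
    """Representative frequency of a band: geometric mean of its edges.

    The geometric mean is the standard single-number summary of a cochlear
    implant analysis channel; the arithmetic mean is available behind the
    ``method`` flag.
    """
    lo, hi = band
    if lo <= 0 or hi <= 0:
        raise ValueError(f"band edges must be positive, got ({lo}, {hi})")
    if hi < lo:
        raise ValueError(f"band edges out of order: ({lo}, {hi})")
    if method == "geometric":
        return math.sqrt(lo * hi)
    if method == "arithmetic":
        return 0.5 * (lo + hi)
    raise ValueError(f"unknown center-frequency method: {method!r}")


def validate(fmap: FrequencyMap, profile: DeviceProfile) -> list[Violation]:
    """Diagnostics, not exceptions: all rule violations of a map.

    Checks the active-electrode set, the pinned apical lower edge, band
    contiguity, minimum band width and grid quantization.  Returns an empty
    list iff the map is valid for the profile.
    """
    out: list[Violation] = []
    active = profile.active_electrodes
    if fmap.electrodes != active:
        out.append(
            Violation(0, "active-electrode set mismatch",
                      f"map has {fmap.electrodes}, profile expects {active}")
        )
        return out
    prev = profile.global_f_min
    for e, (lo, hi) in zip(fmap.electrodes, fmap.bands):
        if abs(lo - prev) > _GRID_TOL:
            out.append(Violation(e, "contiguity", f"f_low={lo}, expected {prev}"))
        if hi - lo < profile.min_band_width_hz - _GRID_TOL:
            out.append(
                Violation(e, "min band width",
                          f"width={hi - lo}, minimum {profile.min_band_width_hz}")
            )
        for edge in (lo, hi):
            if not profile._on_grid(edge):
                out.append(Violation(e, "quantization", f"edge {edge} off grid"))
        prev = hi
    return out


# -- shipped profiles --------------------------------------------------------

BUILTIN_PROFILES = ("medel12", "cochlear22", "ab16", "oticon20")


def load_profile(name_or_path: str | Path) -> DeviceProfile:
    """Load a device profile from a shipped name or a JSON file path.

    Shipped profiles: ``medel12``, ``cochlear22``, ``ab16``, ``oticon20``.
    They carry representative default band tables; clinical use supplies the
    device's real table as JSON in the same schema.
    """
    name = str(name_or_path)
    if name in BUILTIN_PROFILES:
        text = (
            resources.files("eafit").joinpath(f"data/profiles/{name}.json").read_text()
        )
    else:
        p = Path(name_or_path)
        if not p.exists():
            raise ConfigurationError(
                f"no such profile: {name!r} (builtins: {', '.join(BUILTIN_PROFILES)})"
            )
        text = p.read_text()
    return DeviceProfile.from_dict(json.loads(text))
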