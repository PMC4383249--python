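"""Body-temperature (Tb) forcing for the torpor-arousal cycle.

Hibernators cycle between long bouts of torpor, with Tb near ambient
(~4 degC here), and brief interbout arousals back to euthermia (37 degC).
This module builds the representative 12-day Tb trajectory that drives
the temperature-dependent transcript-kinetics model: a warm interbout
period, a slow entrance ramp, a 10-day torpor bout at the torpid
set-point, a rapid arousal ramp, and a warm remainder.

The profile is a uniform minute-resolution grid; downstream integration
treats Tb as constant within each grid cell.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Phase",
    "TorporCycleSpec",
    "BodyTempProfile",
    "build_profile",
    "temperature_at",
    "default_cycle_spec",
]

WARM_TB = 37.0
TORPID_TB = 4.0
TB_MIN, TB_MAX = 0.0, 40.0

PHASE_NAMES = ("warm", "entrance", "torpor", "arousal")
TRANSITION_SHAPES = ("linear", "exponential")

#: decay constant for the normalized exponential transition shape
_EXP_SHAPE_K = 3.0


@dataclass(frozen=True)
class Phase:
    """One segment of the torpor-arousal cycle.

    ``start_tb`` and ``end_tb`` are the body temperatures (degC) at the
    segment boundaries; ``shape`` controls how Tb moves between them.
    """

    name: str
    duration_min: float
    start_tb: float
    end_tb: float
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ConfigurationError(
                f"phase name {self.name!r} not one of {PHASE_NAMES}"
            )
        if not self.duration_min > 0:
            raise ConfigurationError("phase durations must be strictly positive")
        for tb in (self.start_tb, self.end_tb):
            if not (TB_MIN <= tb <= TB_MAX):
                raise ConfigurationError(
                    f"phase temperature {tb} degC outside [{TB_MIN}, {TB_MAX}]"
                )
        if self.shape not in TRANSITION_SHAPES:
            raise ConfigurationError(
                f"transition shape {self.shape!r} not one of {TRANSITION_SHAPES}"
            )

    def tb_at(self, u: np.ndarray | float) -> np.ndarray | float:
        """Tb at fractional position ``u`` in [0, 1] through the phase."""
        if self.shape == "linear":
            return self.start_tb + (self.end_tb - self.start_tb) * u
        # normalized exponential approach: reaches end_tb exactly at u = 1
        k = _EXP_SHAPE_K
        w = (1.0 - np.exp(-k * np.asarray(u, dtype=float))) / (1.0 - np.exp(-k))
        return self.start_tb + (self.end_tb - self.start_tb) * w


@dataclass(frozen=True)
class TorporCycleSpec:
    """Ordered list of phases making up one torpor-arousal cycle.

    Invariants: durations sum to ``total_duration_min`` (if given),
    temperatures are continuous across phase boundaries, and every Tb
    lies in [0, 40] degC.
    """

    phases: tuple[Phase, ...]
    total_duration_min: float | None = None

    def __post_init__(self) -> None:
        if not self.phases:
            raise ConfigurationError("cycle spec needs at least one phase")
        dur = float(sum(p.duration_min for p in self.phases))
        if self.total_duration_min is None:
            object.__setattr__(self, "total_duration_min", dur)
        elif abs(dur - self.total_duration_min) > 1e-9:
            raise ConfigurationError(
                f"phase durations sum to {dur} min, not the declared "
                f"total {self.total_duration_min} min"
            )
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(a.end_tb - b.start_tb) > 1e-9:
                raise ConfigurationError(
                    f"Tb discontinuity between phases {a.name!r} ({a.end_tb}) "
                    f"and {b.name!r} ({b.start_tb})"
                )

    @property
    def total_duration_days(self) -> float:
        return self.total_duration_min / 1440.0

    def phase_bounds(self) -> list[tuple[str, float, float]]:
        """(name, start_min, end_min) for each phase in order."""
        out, t0 = [], 0.0
        for p in self.phases:
            out.append((p.name, t0, t0 + p.duration_min))
            t0 += p.duration_min
        return out

    def phase_interval(self, name: str, which: str = "first") -> tuple[float, float]:
        """Time interval of the first (or last) phase with the given name."""
        hits = [(a, b) for n, a, b in self.phase_bounds() if n == name]
        if not hits:
            raise KeyError(f"no phase named {name!r}")
        return hits[0] if which == "first" else hits[-1]


def default_cycle_spec(
    torpid_tb: float = TORPID_TB,
    warm_tb: float = WARM_TB,
    entrance_h: float = 12.0,
    torpor_days: float = 10.0,
    arousal_h: float = 2.0,
    total_days: float = 12.0,
    shape: str = "linear",
) -> TorporCycleSpec:
    """Representative 12-day cycle: 12 h warm interbout, slow entrance
    ramp, 10 days of torpor at the torpid set-point, rapid 2 h arousal,
    warm remainder.  Entrance is much slower than arousal, matching
    hibernator physiology (cooling is passive, rewarming is driven by
    brown-fat thermogenesis).
    """
    warm1_h = 12.0
    used = warm1_h + entrance_h + torpor_days * 24.0 + arousal_h
    remainder_h = total_days * 24.0 - used
    if remainder_h <= 0:
        raise ConfigurationError("phase durations exceed the total cycle length")
    phases = (
        Phase("warm", warm1_h * 60, warm_tb, warm_tb),
        Phase("entrance", entrance_h * 60, warm_tb, torpid_tb, shape),
        Phase("torpor", torpor_days * 1440, torpid_tb, torpid_tb),
        Phase("arousal", arousal_h * 60, torpid_tb, warm_tb, shape),
        Phase("warm", remainder_h * 60, warm_tb, warm_tb),
    )
    return TorporCycleSpec(phases, total_days * 1440)


@dataclass(frozen=True)
class BodyTempProfile:
    """Tb evaluated on a uniform time grid spanning one cycle.

    ``time_min`` has ``total/spacing + 1`` points including both
    endpoints; ``tb`` holds the matching temperatures.
    """

    time_min: np.ndarray
    tb: np.ndarray
    grid_spacing_min: float
    spec: TorporCycleSpec = field(repr=False)

    @property
    def total_duration_min(self) -> float:
        return float(self.time_min[-1])

    def index_at(self, t: float) -> int:
        """Grid index for time ``t`` (nearest-left convention)."""
        if not (0.0 <= t <= self.total_duration_min + 1e-9):
            raise ValueError(
                f"t = {t} min outside profile span [0, {self.total_duration_min}]"
            )
        return min(int(t // self.grid_spacing_min), len(self.time_min) - 1)

    def temperature_at(self, t: float) -> float:
        return float(self.tb[self.index_at(t)])

    def time_below(self, threshold_tb: float) -> float:
        """Minutes of the cycle spent below ``threshold_tb``.

        Uses the same left-endpoint piecewise-constant convention as the
        kinetics integrator: each grid cell contributes its full spacing
        if Tb at its left endpoint is below the threshold.
        """
        return float(np.sum(self.tb[:-1] < threshold_tb) * self.grid_spacing_min)

    def end_of_torpor_min(self) -> float:
        """Final minute of the (last) torpor phase, before the arousal ramp."""
        return self.spec.phase_interval("torpor", which="last")[1]

    def to_tsv(self, path=None) -> str | None:
        buf = io.StringIO()
        buf.write("time_min\ttb_c\n")
        for t, tb in zip(self.time_min, self.tb):
            buf.write(f"{t:.6g}\t{tb:.6g}\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def build_profile(
    spec: TorporCycleSpec, grid_spacing_min: float = 1.0
) -> BodyTempProfile:
    """Evaluate a cycle spec on a uniform grid.

    ``grid_spacing_min`` must be positive and divide every phase
    duration so phase boundaries fall on grid points.
    """
    if not grid_spacing_min > 0:
        raise ValueError("grid spacing must be positive")
    times, temps = [], []
    for phase, (_, t0, t1) in zip(spec.phases, spec.phase_bounds()):
        n = phase.duration_min / grid_spacing_min
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"grid spacing {grid_spacing_min} min does not divide the "
                f"{phase.name!r} phase duration {phase.duration_min} min"
            )
        n = int(round(n))
        t = t0 + np.arange(n) * grid_spacing_min
        u = (t - t0) / phase.duration_min
        times.append(t)
        temps.append(np.asarray(phase.tb_at(u), dtype=float))
    times.append(np.array([spec.total_duration_min]))
    temps.append(np.array([spec.phases[-1].end_tb]))
    return BodyTempProfile(
        time_min=np.concatenate(times),
        tb=np.concatenate(temps),
        grid_spacing_min=float(grid_spacing_min),
        spec=spec,
    )


def temperature_at(profile: BodyTempProfile, t: float) -> float:
    """Tb at time ``t`` minutes (nearest-left grid convention)."""
    return profile.temperature_at(t)
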