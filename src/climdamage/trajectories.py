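"""Annual time-series containers shared by every stage of the pipeline.

A :class:`Trajectory` is a thin, validated wrapper around a pair of numpy
arrays (consecutive calendar years, one value per year).  Temperature and
sea-level trajectories carry extra labels (baseline period, spatial domain)
because downstream damage functions are only defined for specific
baseline/domain combinations and silent mismatches are the classic failure
mode of this kind of pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError, InvalidStateError

#: Default simulation grid used by the scenario generator.
START_YEAR = 2020
END_YEAR = 2300

#: Recognised temperature baselines.  "1850-1900" is the pre-industrial
#: convention of global emulators; "1986-2005" is the reference period the
#: damage functions are calibrated to.
BASELINE_PREINDUSTRIAL = "1850-1900"
BASELINE_MODERN = "1986-2005"


def default_years() -> np.ndarray:
    """The 2020-2300 annual grid (281 years)."""
    return np.arange(START_YEAR, END_YEAR + 1)


@dataclass(frozen=True)
class Trajectory:
    """Annual series of a quantity in declared units.

    Parameters
    ----------
    years
        Strictly increasing consecutive integers.
    values
        One finite value per year.
    units
        Free-form unit label carried through for reporting.
    """

    years: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1:
            raise InvalidArgumentError("years and values must be 1-D")
        if len(years) != len(values):
            raise InvalidArgumentError(
                f"length mismatch: {len(years)} years vs {len(values)} values"
            )
        if len(years) == 0:
            raise InvalidArgumentError("empty trajectory")
        if not np.all(np.diff(years) == 1):
            raise InvalidArgumentError("years must be consecutive integers")
        if not np.all(np.isfinite(values)):
            raise InvalidArgumentError("trajectory values must be finite")

    def __len__(self) -> int:
        return len(self.years)

    def at(self, year: int) -> float:
        """Value at a calendar year."""
        idx = year - int(self.years[0])
        if idx < 0 or idx >= len(self.years):
            raise InvalidArgumentError(f"year {year} outside grid "
                                       f"[{self.years[0]}, {self.years[-1]}]")
        return float(self.values[idx])

    def same_grid(self, other: "Trajectory") -> bool:
        return len(self.years) == len(other.years) and bool(
            np.all(self.years == other.years)
        )

    def with_values(self, values: np.ndarray) -> "Trajectory":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class TemperatureTrajectory(Trajectory):
    """Annual temperature anomaly with explicit baseline and domain labels.

    ``baseline`` is the averaging period the anomaly is referenced to and
    ``domain`` is "global" or "CONUS".  CONUS trajectories are only ever
    derived from modern-baselined global ones, which is enforced where the
    conversion happens.
    """

    units: str = "degC"
    baseline: str = BASELINE_PREINDUSTRIAL
    domain: str = "global"

    def __post_init__(self):
        super().__post_init__()
        if self.baseline not in (BASELINE_PREINDUSTRIAL, BASELINE_MODERN):
            raise InvalidArgumentError(f"unknown baseline {self.baseline!r}")
        if self.domain not in ("global", "CONUS"):
            raise InvalidArgumentError(f"unknown domain {self.domain!r}")


@dataclass(frozen=True)
class GMSLTrajectory(Trajectory):
    """Global mean sea level in cm above the year-2000 datum."""

    units: str = "cm"


def require_same_grid(*trajs: Trajectory) -> np.ndarray:
    """Assert all trajectories share one year grid; return it."""
    first = trajs[0]
    for t in trajs[1:]:
        if not first.same_grid(t):
            raise InvalidArgumentError("trajectories are on different year grids")
    return first.years
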