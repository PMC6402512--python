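"""Person-time accrual over fixed-width age bands (Lexis age axis only).

Each participant contributes follow-up time to the 5-year (by default)
age bands their interval [entry_age, exit_age) overlaps — delayed entry
means no time before entry_age, right censoring none after exit_age.
An event is counted once, in the band containing the exit age.

Bands are half-open [lower, upper) on the grid {origin + k·width}. An
event landing exactly on a band boundary belongs to the upper band
(half-open convention); that is the one case where a band can hold an
event while receiving no person-time from that subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import ConfigurationError


@dataclass
class AgeBand:
    """Half-open age interval [lower, upper) with accumulated exposure.

    ``age_time`` is the integral of age over the accumulated exposure,
    kept so a person-time-weighted mean age is available as an abscissa
    for the log-log fit.
    """

    lower: float
    upper: float
    person_years: float = 0.0
    events: int = 0
    age_time: float = 0.0

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def mean_age(self) -> float:
        """Person-time-weighted mean age of the accumulated exposure."""
        if self.person_years <= 0:
            return self.midpoint
        return self.age_time / self.person_years


@dataclass
class BandTable:
    """Sorted, contiguous collection of age bands on one grid."""

    bands: list[AgeBand]
    band_width: float
    origin: float

    def __post_init__(self) -> None:
        for a, b in zip(self.bands, self.bands[1:]):
            if not math.isclose(a.upper, b.lower, rel_tol=0, abs_tol=1e-9):
                raise ConfigurationError("bands must be contiguous and sorted")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lower": b.lower,
                "upper": b.upper,
                "person_years": b.person_years,
                "events": b.events,
                "rate": (b.events / b.person_years) if b.person_years > 0 else float("nan"),
            }
            for b in self.bands
        ]
        return pd.DataFrame(rows, columns=["lower", "upper", "person_years", "events", "rate"])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def accrue_person_time(
    cohort: CohortTable, band_width: float = 5.0, origin: float = 0.0
) -> BandTable:
    """Split every follow-up interval across the age-band grid.

    For each participant the interval [entry_age, exit_age) is
    intersected with each band; the intersection length accrues to that
    band's person-years.  If the participant has the event, one event is
    added to the band containing exit_age.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cannot accrue person-time for an empty cohort")
    if band_width <= 0:
        raise ConfigurationError("band_width must be positive")

    entry = cohort.frame["entry_age"].to_numpy(dtype=float)
    exit_ = cohort.frame["exit_age"].to_numpy(dtype=float)
    event = cohort.frame["event"].to_numpy(dtype=bool)

    # last band touched by exposure: the band containing exit, unless exit
    # sits exactly on a boundary (then the previous band)
    k_entry = np.floor((entry - origin) / band_width).astype(int)
    k_exit_py = np.ceil((exit_ - origin) / band_width).astype(int) - 1
    k_event = np.floor((exit_ - origin) / band_width).astype(int)

    k_min = int(k_entry.min())
    k_max = int(k_exit_py.max())
    if event.any():
        k_max = max(k_max, int(k_event[event].max()))

    bands: list[AgeBand] = []
    for k in range(k_min, k_max + 1):
        lo = origin + k * band_width
        hi = lo + band_width
        a = np.maximum(entry, lo)
        b = np.minimum(exit_, hi)
        overlap = np.maximum(b - a, 0.0)
        py = float(overlap.sum())
        # integral of age over each overlap: (b^2 - a^2) / 2
        mask = overlap > 0
        age_time = float((0.5 * (b[mask] ** 2 - a[mask] ** 2)).sum())
        bands.append(AgeBand(lo, hi, py, 0, age_time))

    ev_counts = np.bincount(k_event[event] - k_min, minlength=k_max - k_min + 1)
    for k, n in enumerate(ev_counts):
        bands[k].events = int(n)
    return BandTable(bands, band_width, origin)


def total_person_years(bands: BandTable | Sequence[AgeBand]) -> float:
    """Sum of person-years over all bands."""
    return float(sum(b.person_years for b in bands))


def total_events(bands: BandTable | Sequence[AgeBand]) -> int:
    return int(sum(b.events for b in bands))
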