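"""Daily GPS fix schedules.

A store-on-board GPS collar attempts a fixed set of location acquisitions per
day at programmed clock times.  The default schedule is seven attempts per day
-- every three hours through the night and every four hours through the day
(02:00, 05:00, 08:00, 12:00, 16:00, 19:00, 21:00) -- with the 21:00, 02:00 and
05:00 slots treated as night-time slots.

Schedule slots are *clock* times: the collar is programmed in local civil time
and no daylight-saving arithmetic is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["FixSchedule", "DEFAULT_SCHEDULE"]

_DEFAULT_SLOTS = (
    time(2, 0),
    time(5, 0),
    time(8, 0),
    time(12, 0),
    time(16, 0),
    time(19, 0),
    time(21, 0),
)
_DEFAULT_NIGHT = frozenset({time(21, 0), time(2, 0), time(5, 0)})


@dataclass(frozen=True)
class FixSchedule:
    """Programmed daily acquisition schedule of a GPS collar.

    Parameters
    ----------
    slot_times
        Ordered, unique daily clock times at which the collar attempts a fix.
    night_slots
        Subset of ``slot_times`` designated as night-time slots (used for the
        NIGHTPROP covariate).
    """

    slot_times: tuple[time, ...] = _DEFAULT_SLOTS
    night_slots: frozenset[time] = field(default_factory=lambda: _DEFAULT_NIGHT)

    def __post_init__(self) -> None:
        if not self.slot_times:
            raise ValueError("slot_times must be non-empty")
        if len(set(self.slot_times)) != len(self.slot_times):
            raise ValueError("slot_times must be unique")
        object.__setattr__(self, "slot_times", tuple(sorted(self.slot_times)))
        extra = set(self.night_slots) - set(self.slot_times)
        if extra:
            raise ValueError(f"night_slots not in slot_times: {sorted(extra)}")

    @property
    def n_per_day(self) -> int:
        return len(self.slot_times)

    # -- slot labels --------------------------------------------------------

    @staticmethod
    def label(t: time) -> str:
        return t.strftime("%H:%M")

    def is_night(self, t: time | None) -> bool:
        return t is not None and t in self.night_slots

    # -- slot assignment ----------------------------------------------------

    def assign_slot(
        self, ts: datetime, tolerance: timedelta = timedelta(minutes=30)
    ) -> tuple[time, date] | None:
        """Assign a timestamp to its nearest scheduled slot occurrence.

        Returns ``(slot_time, slot_date)`` when the nearest occurrence is
        within ``tolerance``, otherwise ``None`` (the fix is off-schedule).
        The slot date is the calendar date the occurrence falls on, which can
        differ from the fix's own date near midnight.
        """
        best: tuple[timedelta, time, date] | None = None
        for day_offset in (-1, 0, 1):
            d = ts.date() + timedelta(days=day_offset)
            for st in self.slot_times:
                occ = datetime.combine(d, st)
                delta = abs(occ - ts)
                if best is None or delta < best[0]:
                    best = (delta, st, d)
        assert best is not None
        if best[0] <= tolerance:
            return best[1], best[2]
        return None

    # -- slot enumeration ---------------------------------------------------

    def occurrences(self, start: datetime, end: datetime) -> list[datetime]:
        """All scheduled slot occurrences with start <= occurrence <= end."""
        if end < start:
            return []
        out: list[datetime] = []
        d = start.date()
        while d <= end.date():
            for st in self.slot_times:
                occ = datetime.combine(d, st)
                if start <= occ <= end:
                    out.append(occ)
            d += timedelta(days=1)
        return out

    def count_between(self, t1: datetime, t2: datetime) -> int:
        """Number of scheduled occurrences strictly between two timestamps."""
        if t2 < t1:
            t1, t2 = t2, t1
        eps = timedelta(microseconds=1)
        return len(self.occurrences(t1 + eps, t2 - eps))

    def occurrence_array(self, start: datetime, end: datetime) -> np.ndarray:
        return np.array(self.occurrences(start, end), dtype="datetime64[ns]")


DEFAULT_SCHEDULE = FixSchedule()


def parse_slot_times(values: Iterable[str]) -> tuple[time, ...]:
    """Parse ``HH:MM`` strings into schedule slot times."""
    out = []
    for v in values:
        out.append(time.fromisoformat(v))
    return tuple(out)


def slot_datetime(slot_time: time, slot_date: date) -> pd.Timestamp:
    return pd.Timestamp(datetime.combine(slot_date, slot_time))
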