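"""Month-precision study dates.

Cancer registries typically release the month and year of diagnosis but not
the day, so all temporal matching in this package happens on a *month index*
(``12*year + month - 1``).  Surrogate event records may carry a full date;
the day is kept only to break ties when selecting the first occurrence of an
indicator within a month, never to compute lags.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass
from functools import total_ordering

from .errors import ValidationError

_ISO_RE = re.compile(r"^(\d{4})-(\d{2})(?:-(\d{2}))?$")


@total_ordering
@dataclass(frozen=True)
class StudyDate:
    """A calendar date with an optional day component.

    Ordering is defined on ``(month_index, day)``: dates in earlier months
    sort first; within a month, a date *with* a day sorts before one without
    (deterministic first-occurrence selection), and days order naturally.
    """

    year: int
    month: int
    day: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.month <= 12):
            raise ValidationError(f"month must be in 1..12, got {self.month!r}")
        if self.day is not None:
            last = calendar.monthrange(self.year, self.month)[1]
            if not (1 <= self.day <= last):
                raise ValidationError(
                    f"day {self.day!r} invalid for {self.year:04d}-{self.month:02d}"
                )

    @property
    def month_index(self) -> int:
        """Months elapsed since year 0: ``12*year + (month - 1)``."""
        return 12 * self.year + self.month - 1

    def sort_key(self) -> tuple[int, int, int]:
        # absent day sorts after any present day within the same month
        if self.day is None:
            return (self.month_index, 1, 0)
        return (self.month_index, 0, self.day)

    def __lt__(self, other: "StudyDate") -> bool:
        if not isinstance(other, StudyDate):
            return NotImplemented
        return self.sort_key() < other.sort_key()

    def months_until(self, other: "StudyDate") -> int:
        """Signed whole-month difference ``other - self`` (days ignored)."""
        return other.month_index - self.month_index

    def add_months(self, n: int) -> "StudyDate":
        """Shift by ``n`` calendar months; the day component is dropped."""
        return StudyDate.from_month_index(self.month_index + n)

    @classmethod
    def from_month_index(cls, idx: int) -> "StudyDate":
        return cls(idx // 12, idx % 12 + 1)

    @classmethod
    def parse(cls, text: str) -> "StudyDate":
        """Parse an ISO-8601 ``YYYY-MM-DD`` or month-precision ``YYYY-MM`` string."""
        m = _ISO_RE.match(str(text).strip())
        if m is None:
            raise ValidationError(f"unparseable date {text!r} (expected YYYY-MM[-DD])")
        y, mo, d = m.groups()
        return cls(int(y), int(mo), int(d) if d is not None else None)

    def isoformat(self) -> str:
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def month_index(d: StudyDate) -> int:
    """Month index of a :class:`StudyDate` (functional form)."""
    if not isinstance(d, StudyDate):
        raise ValidationError(f"expected StudyDate, got {type(d).__name__}")
    return d.month_index
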