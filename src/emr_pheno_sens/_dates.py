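"""Calendar-date helpers.

All clinical dates in this package are day-resolution :class:`datetime.date`
values; age thresholds are computed by calendar arithmetic, not day counts,
so the adult filter is exact on birthdays.
"""

from __future__ import annotations

from datetime import date, timedelta


def add_years(d: date, years: int) -> date:
    """Shift a date by whole calendar years.

    Feb 29 anniversaries in non-leap years roll forward to Mar 1, the
    convention under which a person born Feb 29 turns 18 on Mar 1.
    """
    try:
        return d.replace(year=d.year + years)
    except ValueError:
        return date(d.year + years, 3, 1)


def eighteenth_birthday(birth_date: date) -> date:
    return add_years(birth_date, 18)


def uniform_date(rng, start: date, end: date) -> date:
    """Draw a day uniformly from [start, end] inclusive."""
    span = (end - start).days
    if span < 0:
        raise ValueError("empty date interval")
    return start + timedelta(days=int(rng.integers(0, span + 1)))
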