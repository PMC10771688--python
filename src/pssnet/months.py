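"""Calendar-month binning used pipeline-wide.

Months are represented as ``"YYYY-MM"`` string keys so they survive
delimited-text round trips unchanged. Two binning schemes are supported:

* ``"calendar"`` (default): a record dated day *d* of month *m* belongs to *m*.
* ``"mid-month"``: measurement months run from the 16th of one calendar month
  to the 15th of the next; a record dated on/after the 16th is assigned to the
  *following* calendar month's bin (the bin is labelled by the month in which
  it ends).
"""

from __future__ import annotations

import pandas as pd

SCHEMES = ("calendar", "mid-month")


def month_key(dates: pd.Series, scheme: str = "calendar") -> pd.Series:
    """Bin dates into month keys under the given scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown month scheme {scheme!r}; expected one of {SCHEMES}")
    dates = pd.to_datetime(dates)
    periods = dates.dt.to_period("M")
    if scheme == "mid-month":
        periods = periods.where(dates.dt.day < 16, periods + 1)
    return periods.astype(str)


def to_period(key: str) -> pd.Period:
    return pd.Period(key, freq="M")


def shift(key: str, k: int) -> str:
    """Month key ``k`` months after ``key`` (negative ``k`` shifts back)."""
    return str(to_period(key) + k)


def month_range(start: str, end: str) -> list[str]:
    """Inclusive list of month keys from ``start`` to ``end``."""
    return [str(p) for p in pd.period_range(start, end, freq="M")]


def month_index(key: str, origin: str) -> int:
    """1-based integer index of ``key`` relative to ``origin`` (origin -> 1)."""
    return (to_period(key) - to_period(origin)).n + 1


def month_end(key: str) -> pd.Timestamp:
    return to_period(key).end_time.normalize()


def month_start(key: str) -> pd.Timestamp:
    return to_period(key).start_time.normalize()
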