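"""Weekly season calendar for the survival model.

Seasons follow fixed calendar windows: spring Mar 1 - May 31, summer
Jun 1 - Jul 31, fall Aug 1 - Oct 31, winter the remainder (Nov 1 - end of
February).  A week is assigned to the season containing its midpoint date,
which also resolves leap-year edge weeks.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np

__all__ = ["SEASONS", "season_of_date", "week_dates", "week_seasons",
           "season_design"]

SEASONS = ("winter", "spring", "summer", "fall")
#: Season offset columns in the survival design (winter is the intercept).
OFFSET_SEASONS = ("spring", "summer", "fall")

N_WEEKS = 52


def season_of_date(d: date) -> str:
    key = (d.month, d.day)
    if (3, 1) <= key <= (5, 31):
        return "spring"
    if (6, 1) <= key <= (7, 31):
        return "summer"
    if (8, 1) <= key <= (10, 31):
        return "fall"
    return "winter"


def week_dates(start: date, n_weeks: int = N_WEEKS):
    """Start date of each weekly interval, weeks indexed 1..n_weeks."""
    return [start + timedelta(days=7 * (t - 1)) for t in range(1, n_weeks + 1)]


def week_seasons(start: date, n_weeks: int = N_WEEKS):
    """Season label per week (by week midpoint, day 4 of the interval)."""
    labels = [season_of_date(d + timedelta(days=3)) for d in week_dates(start, n_weeks)]
    if len(labels) != n_weeks:
        raise RuntimeError("season calendar does not cover the requested weeks")
    return labels


def season_design(labels) -> np.ndarray:
    """(n_weeks, 3) indicator matrix for (spring, summer, fall) offsets."""
    labels = list(labels)
    unknown = set(labels) - set(SEASONS)
    if unknown:
        raise ValueError(f"unknown season labels: {sorted(unknown)}")
    return np.column_stack([
        np.array([lab == s for lab in labels], dtype=float)
        for s in OFFSET_SEASONS
    ])
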