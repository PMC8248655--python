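"""Daily inspection priority lists under a capacity constraint.

Arrivals are ranked within each calendar day by PPP score (descending) and
the top ``capacity`` (default 6/day, a jurisdiction's inspection budget) are
selected.  Arrivals flagged as suspected noncompliant are always selected,
independent of score; by default they do not consume capacity.  Ties are
broken deterministically: score desc → discharge volume desc → arrival_id
ascending, so identical inputs always yield identical lists.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from typing import Iterable, Literal, Sequence

from .errors import ValidationError
from .scoring import ScoredArrival

logger = logging.getLogger(__name__)

Reason = Literal["score", "noncompliant"]

#: Default daily inspection capacity (California's ~25%-of-arrivals mandate
#: corresponds to about 6 vessels per day).
DEFAULT_CAPACITY = 6


@dataclasses.dataclass(frozen=True)
class PriorityEntry:
    rank: int
    scored: ScoredArrival
    reason: Reason


@dataclasses.dataclass(frozen=True)
class PriorityList:
    """One day's inspection priorities."""

    date: dt.date
    capacity: int
    entries: tuple[PriorityEntry, ...]
    excluded: tuple[ScoredArrival, ...]

    @property
    def selected(self) -> list[ScoredArrival]:
        return [e.scored for e in self.entries]


def _sort_key(s: ScoredArrival) -> tuple[float, float, str]:
    return (-s.ppp_score, -s.arrival.bwd_volume, s.arrival.arrival_id)


def rank_daily(
    scored: Iterable[ScoredArrival], date: dt.date
) -> list[ScoredArrival]:
    """Sort one day's scored arrivals by descending PPP score.

    All arrivals must share ``date``; mixed dates are an error because a
    daily ranking across days is meaningless.
    """
    items = list(scored)
    bad = sorted({s.arrival.arrival_date for s in items} - {date})
    if bad:
        raise ValidationError(
            f"rank_daily({date}): arrivals dated {', '.join(map(str, bad))} "
            "do not belong to this day"
        )
    return sorted(items, key=_sort_key)


def select_priorities(
    ranked: Sequence[ScoredArrival],
    capacity: int = DEFAULT_CAPACITY,
    noncompliant_ids: Iterable[str] = (),
    count_noncompliant: bool = False,
    date: dt.date | None = None,
) -> PriorityList:
    """Select a day's inspection priorities from a ranked list.

    Noncompliant arrivals (flagged on the record or listed in
    ``noncompliant_ids``) are selected first, independent of score.  By
    default they do not count against ``capacity``; ``count_noncompliant``
    switches to a strict-capacity mode where they do.  Unknown ids in
    ``noncompliant_ids`` are logged and ignored.
    """
    if capacity < 0:
        raise ValidationError(f"capacity must be >= 0, got {capacity}")
    ranked = list(ranked)
    flagged = set(noncompliant_ids)
    known = {s.arrival.arrival_id for s in ranked}
    unknown = flagged - known
    if unknown:
        logger.warning(
            "noncompliant ids not present in today's arrivals, ignored: %s",
            ", ".join(sorted(unknown)),
        )
    if date is None:
        date = ranked[0].arrival.arrival_date if ranked else dt.date.min

    def is_noncompliant(s: ScoredArrival) -> bool:
        return (not s.arrival.compliant) or s.arrival.arrival_id in flagged

    entries: list[PriorityEntry] = []
    overrides = [s for s in ranked if is_noncompliant(s)]
    remaining = [s for s in ranked if not is_noncompliant(s)]
    for s in overrides:
        entries.append(PriorityEntry(len(entries) + 1, s, "noncompliant"))
    budget = capacity - len(overrides) if count_noncompliant else capacity
    budget = max(budget, 0)
    for s in remaining[:budget]:
        entries.append(PriorityEntry(len(entries) + 1, s, "score"))
    excluded = tuple(remaining[budget:])
    return PriorityList(
        date=date, capacity=capacity, entries=tuple(entries), excluded=excluded
    )


def prioritize_daily(
    scored: Iterable[ScoredArrival],
    capacity: int = DEFAULT_CAPACITY,
    noncompliant_ids: Iterable[str] = (),
    count_noncompliant: bool = False,
) -> list[PriorityList]:
    """Group scored arrivals by calendar day and select priorities per day.

    Days are the calendar dates recorded on the arrivals (local to the
    jurisdiction); no timestamp arithmetic is performed.
    """
    flagged = set(noncompliant_ids)
    by_day: dict[dt.date, list[ScoredArrival]] = {}
    for s in scored:
        by_day.setdefault(s.arrival.arrival_date, []).append(s)
    lists = []
    for day in sorted(by_day):
        ranked = rank_daily(by_day[day], day)
        day_ids = {s.arrival.arrival_id for s in ranked}
        lists.append(
            select_priorities(
                ranked,
                capacity=capacity,
                noncompliant_ids=flagged & day_ids,
                count_noncompliant=count_noncompliant,
                date=day,
            )
        )
    return lists


def apply_first_arrival_policy(
    scored: Iterable[ScoredArrival],
) -> list[ScoredArrival]:
    """Keep only each vessel's chronologically first arrival.

    A repeat-visit policy: once a vessel has had its first arrival
    considered for priority inspection, its later arrivals are excluded
    from selection (they remain scored and reportable).  Chronology is by
    arrival date, then arrival_id for same-day repeats.
    """
    items = sorted(
        scored, key=lambda s: (s.arrival.arrival_date, s.arrival.arrival_id)
    )
    seen: set[str] = set()
    kept: list[ScoredArrival] = []
    for s in items:
        if s.arrival.vessel_id not in seen:
            seen.add(s.arrival.vessel_id)
            kept.append(s)
    return kept
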