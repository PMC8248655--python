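"""Exception hierarchy for the PPP model.

All errors raised by this package derive from :class:`PPPError` so callers
can catch the package's failures without catching unrelated ``ValueError``s.
"""

from __future__ import annotations


class PPPError(Exception):
    """Base class for all package errors."""


class DomainError(PPPError, ValueError):
    """An input value is outside the mathematical domain of an operation
    (nonpositive tonnage, negative area, niche proportion outside [0, 1))."""


class UnsupportedRouteError(PPPError, ValueError):
    """The requested computation route does not apply to this vessel type,
    e.g. the gross-tonnage regression asked for an ATB or barge+tug, whose
    wetted surface area must be computed directly from hull parameters."""


class ValidationError(PPPError, ValueError):
    """A record or configuration failed validation; the message lists the
    offending fields."""


class BaselineError(PPPError, ValueError):
    """A population baseline could not be computed (empty population, or no
    discharging arrivals under the selected median policy)."""


class ScoringError(PPPError, ValueError):
    """An individual arrival could not be scored.  Carries the arrival id so
    batch reports can point at the offending record."""

    def __init__(self, arrival_id: str, reason: str):
        self.arrival_id = arrival_id
        self.reason = reason
        super().__init__(f"arrival {arrival_id!r}: {reason}")


class AggregationError(PPPError, ValueError):
    """A grouping request referenced fields that do not exist."""
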