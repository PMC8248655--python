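"""Arrival records: one row per vessel arrival, validated on construction."""

from __future__ import annotations

import datetime as dt
from typing import Optional

import pydantic

from .errors import ValidationError
from .params import COMPOSITE_TYPES, VesselType, normalize_vessel_type


class HullParams(pydantic.BaseModel):
    """Hull dimensions and form coefficients for direct WSA computation.

    Lengths in metres; coefficients dimensionless in (0, 1];
    ``bulb_transverse_area`` (A_BT) in m², zero when there is no bulbous bow.
    """

    model_config = pydantic.ConfigDict(frozen=True)

    length_waterline: float = pydantic.Field(gt=0)
    beam: float = pydantic.Field(gt=0)
    draft: float = pydantic.Field(gt=0)
    midship_coeff: float = pydantic.Field(gt=0, le=1)
    block_coeff: float = pydantic.Field(gt=0, le=1)
    waterplane_coeff: float = pydantic.Field(gt=0, le=1)
    bulb_transverse_area: float = pydantic.Field(default=0.0, ge=0)


class VesselArrival(pydantic.BaseModel):
    """One vessel arrival.

    ``gross_tonnage`` drives the WSA regression for the six regression
    types.  ATB and barge+tug arrivals must instead carry, for each of the
    two components (barge and tug), either full hull parameters or a
    precomputed WSA — missing composite data is an error at scoring time,
    never silently defaulted.

    ``compliant`` is True unless the arrival has been flagged as suspected
    noncompliant, which makes it high priority regardless of score.
    """

    model_config = pydantic.ConfigDict(frozen=True)

    arrival_id: str
    vessel_id: str
    vessel_type: VesselType
    gross_tonnage: Optional[float] = None
    bwd_volume: float = pydantic.Field(ge=0)
    port: str
    arrival_date: dt.date
    compliant: bool = True
    hull: Optional[HullParams] = None
    precomputed_wsa: Optional[float] = pydantic.Field(default=None, gt=0)
    tug_hull: Optional[HullParams] = None
    tug_precomputed_wsa: Optional[float] = pydantic.Field(default=None, gt=0)

    @pydantic.field_validator("vessel_type", mode="before")
    @classmethod
    def _normalize_type(cls, v: object) -> VesselType:
        return normalize_vessel_type(v)  # type: ignore[arg-type]

    @pydantic.model_validator(mode="after")
    def _check_routes(self) -> "VesselArrival":
        if self.vessel_type in COMPOSITE_TYPES:
            if self.hull is None and self.precomputed_wsa is None:
                raise ValueError(
                    f"{self.vessel_type.value} arrival needs barge hull "
                    "parameters or a precomputed barge WSA"
                )
            if self.tug_hull is None and self.tug_precomputed_wsa is None:
                raise ValueError(
                    f"{self.vessel_type.value} arrival needs tug hull "
                    "parameters or a precomputed tug WSA"
                )
        else:
            if self.gross_tonnage is None or self.gross_tonnage <= 0:
                raise ValueError(
                    f"{self.vessel_type.value} arrival needs gross_tonnage > 0"
                )
        return self


def make_arrival(**fields: object) -> VesselArrival:
    """Construct a validated arrival, converting pydantic's validation
    failure into this package's :class:`ValidationError`."""
    try:
        return VesselArrival(**fields)  # type: ignore[arg-type]
    except pydantic.ValidationError as exc:
        raise ValidationError(str(exc)) from exc
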