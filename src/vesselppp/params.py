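"""Vessel-type vocabulary and per-type wetted-surface-area parameters.

Six commercial vessel types get a published power-law regression
``WSA = m * GT**b`` from gross tonnage to wetted surface area, plus a niche
proportion N_p (the fraction of WSA contributed by sea chests, rudders,
thruster tunnels and similar protected areas).  Articulated tug-barges (ATB)
and unmanned barge+tug pairs are too heterogeneous for a single regression;
their WSA is computed directly from hull dimensions, and each component
carries its own niche proportion (0.033 for the barge, 0.25 for the tug).

The packaged defaults are immutable; a user may load an override table from
a plain-text CSV (columns: type_code, m, b, niche_proportion).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import DomainError, ValidationError


class VesselType(str, enum.Enum):
    """Canonical vessel-type codes."""

    GENERAL = "general"
    PASSENGER = "passenger"
    RORO = "roro"
    BULKER = "bulker"
    CONTAINER = "container"
    TANKER = "tanker"
    ATB = "atb"
    BARGE_TUG = "barge_tug"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Types whose WSA comes from the GT power-law regression.
REGRESSION_TYPES = frozenset(
    {
        VesselType.GENERAL,
        VesselType.PASSENGER,
        VesselType.RORO,
        VesselType.BULKER,
        VesselType.CONTAINER,
        VesselType.TANKER,
    }
)

#: Types whose WSA is computed directly per component (barge and tug).
COMPOSITE_TYPES = frozenset({VesselType.ATB, VesselType.BARGE_TUG})

#: Niche proportions for the two components of a composite arrival.
BARGE_NICHE_PROPORTION = 0.033
TUG_NICHE_PROPORTION = 0.25

# Explicit, editable synonym map.  Lookup is case-insensitive and ignores
# surrounding whitespace; unmapped strings are an error, never a guess.
TYPE_ALIASES: dict[str, VesselType] = {
    "general": VesselType.GENERAL,
    "general cargo": VesselType.GENERAL,
    "cargo": VesselType.GENERAL,
    "passenger": VesselType.PASSENGER,
    "cruise": VesselType.PASSENGER,
    "roro": VesselType.RORO,
    "ro-ro": VesselType.RORO,
    "ro/ro": VesselType.RORO,
    "auto carrier": VesselType.RORO,
    "vehicle carrier": VesselType.RORO,
    "bulker": VesselType.BULKER,
    "bulk": VesselType.BULKER,
    "bulk carrier": VesselType.BULKER,
    "container": VesselType.CONTAINER,
    "containership": VesselType.CONTAINER,
    "tanker": VesselType.TANKER,
    "atb": VesselType.ATB,
    "articulated tug-barge": VesselType.ATB,
    "articulated tug barge": VesselType.ATB,
    "barge_tug": VesselType.BARGE_TUG,
    "barge+tug": VesselType.BARGE_TUG,
    "barge + tug": VesselType.BARGE_TUG,
    "unmanned barge": VesselType.BARGE_TUG,
    "unmanned barges + tug": VesselType.BARGE_TUG,
    "barge": VesselType.BARGE_TUG,
}


def normalize_vessel_type(raw: str | VesselType) -> VesselType:
    """Map a raw vessel-type string onto the canonical vocabulary.

    Raises :class:`ValidationError` for unmapped strings rather than
    guessing a type.
    """
    if isinstance(raw, VesselType):
        return raw
    key = str(raw).strip().lower()
    try:
        return TYPE_ALIASES[key]
    except KeyError:
        known = ", ".join(sorted(set(TYPE_ALIASES)))
        raise ValidationError(
            f"unknown vessel type {raw!r}; known names/aliases: {known}"
        ) from None


@dataclass(frozen=True)
class VesselTypeParams:
    """WSA parameters for one vessel type.

    For regression types, ``m`` and ``b`` define ``WSA = m * GT**b`` and
    ``niche_proportion`` is N_p.  For composite types (ATB, barge+tug) the
    regression fields are ``None`` and ``component_niches`` holds the
    (barge, tug) niche proportions.

    ``r_squared`` and ``n_obs`` record the provenance of a fitted
    regression; they do not enter any computation.
    """

    type_code: VesselType
    m: float | None = None
    b: float | None = None
    niche_proportion: float | None = None
    component_niches: tuple[float, float] | None = None
    r_squared: float | None = None
    n_obs: int | None = None

    def __post_init__(self) -> None:
        if self.type_code in REGRESSION_TYPES:
            if self.m is None or self.b is None or self.niche_proportion is None:
                raise ValidationError(
                    f"{self.type_code}: regression types require m, b and "
                    "niche_proportion"
                )
            if self.m <= 0:
                raise DomainError(f"{self.type_code}: m must be > 0, got {self.m}")
            if not 0 < self.b < 1:
                raise DomainError(
                    f"{self.type_code}: b must be in (0, 1), got {self.b}"
                )
            if not 0 <= self.niche_proportion < 1:
                raise DomainError(
                    f"{self.type_code}: niche_proportion must be in [0, 1), "
                    f"got {self.niche_proportion}"
                )
        else:
            if self.component_niches is None:
                raise ValidationError(
                    f"{self.type_code}: composite types require component_niches"
                )
            for p in self.component_niches:
                if not 0 <= p < 1:
                    raise DomainError(
                        f"{self.type_code}: component niche proportion must be "
                        f"in [0, 1), got {p}"
                    )

    @property
    def is_regression(self) -> bool:
        return self.type_code in REGRESSION_TYPES


ParamsTable = Mapping[VesselType, VesselTypeParams]


def default_params() -> dict[VesselType, VesselTypeParams]:
    """The packaged per-type parameter table (published values, as printed)."""
    rows = [
        VesselTypeParams(VesselType.GENERAL, 20.02, 0.5728, 0.09,
                         r_squared=0.907, n_obs=4172),
        VesselTypeParams(VesselType.PASSENGER, 5.46, 0.6951, 0.27,
                         r_squared=0.996, n_obs=2659),
        VesselTypeParams(VesselType.RORO, 25.04, 0.5309, 0.09,
                         r_squared=0.901, n_obs=1929),
        VesselTypeParams(VesselType.BULKER, 15.0, 0.6294, 0.07,
                         r_squared=0.988, n_obs=8804),
        VesselTypeParams(VesselType.CONTAINER, 10.66, 0.6501, 0.09,
                         r_squared=0.984, n_obs=3065),
        VesselTypeParams(VesselType.TANKER, 17.57, 0.6105, 0.08,
                         r_squared=0.988, n_obs=8292),
        VesselTypeParams(
            VesselType.ATB,
            component_niches=(BARGE_NICHE_PROPORTION, TUG_NICHE_PROPORTION),
        ),
        VesselTypeParams(
            VesselType.BARGE_TUG,
            component_niches=(BARGE_NICHE_PROPORTION, TUG_NICHE_PROPORTION),
        ),
    ]
    return {p.type_code: p for p in rows}


def load_params(path: str | Path) -> dict[VesselType, VesselTypeParams]:
    """Load a parameter override table from CSV.

    Expected columns: ``type_code, m, b, niche_proportion``.  Rows for
    composite types may leave m/b empty and give two niche proportions
    separated by ``+`` (e.g. ``0.033+0.25``).  Types absent from the file
    keep their packaged defaults.
    """
    table = default_params()
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"type_code", "m", "b", "niche_proportion"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{path}: parameter table must have columns {sorted(required)}"
            )
        for row in reader:
            code = normalize_vessel_type(row["type_code"])
            niche_raw = (row["niche_proportion"] or "").strip()
            if code in COMPOSITE_TYPES:
                parts = [float(x) for x in niche_raw.split("+")] if niche_raw else []
                if len(parts) != 2:
                    raise ValidationError(
                        f"{path}: composite type {code} needs two niche "
                        "proportions 'barge+tug'"
                    )
                table[code] = VesselTypeParams(
                    code, component_niches=(parts[0], parts[1])
                )
            else:
                table[code] = VesselTypeParams(
                    code,
                    m=float(row["m"]),
                    b=float(row["b"]),
                    niche_proportion=float(niche_raw),
                )
    return table


def write_params(table: ParamsTable, path: str | Path) -> None:
    """Write a parameter table as CSV (inverse of :func:`load_params`)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["type_code", "m", "b", "niche_proportion"])
        for code in VesselType:
            p = table.get(code)
            if p is None:
                continue
            if p.is_regression:
                writer.writerow([code.value, p.m, p.b, p.niche_proportion])
            else:
                bn, tn = p.component_niches  # type: ignore[misc]
                writer.writerow([code.value, "", "", f"{bn}+{tn}"])
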