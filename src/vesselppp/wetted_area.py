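"""Wetted surface area (WSA) and total wetted surface area (TWSA).

Two routes produce a hull's wetted surface area:

* the per-type power law ``WSA = m * GT**b`` fitted on large national
  arrival datasets (six commercial types), and
* direct evaluation from hull dimensions with the Holtrop-style formula

  .. math::

     S = L(2T + B)\\sqrt{C_m}\\,(0.453 + 0.4425 C_b - 0.2862 C_m
         - 0.003467\\,B/T + 0.3696 C_{wp}) + 2.38\\,A_{BT}/C_b

  used for ATBs and unmanned barge+tug pairs, whose hull forms are too
  variable for one regression.

TWSA augments WSA by the niche-area proportion: ``TWSA = WSA * (1 + N_p)``.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import DomainError, UnsupportedRouteError, ValidationError
from .params import (
    BARGE_NICHE_PROPORTION,
    COMPOSITE_TYPES,
    TUG_NICHE_PROPORTION,
    ParamsTable,
    VesselType,
    VesselTypeParams,
)
from .records import HullParams, VesselArrival

AtbNicheMode = Literal["per_component", "summed"]


def estimate_wsa_from_gt(gross_tonnage: float, params: VesselTypeParams) -> float:
    """Estimate wetted surface area (m²) from gross tonnage.

    Applies the type-specific power law ``m * GT**b``; strictly increasing
    in GT.  Only valid for the six regression types — composite types must
    go through :func:`compute_direct_wsa`.
    """
    if params.type_code in COMPOSITE_TYPES:
        raise UnsupportedRouteError(
            f"{params.type_code.value} has no GT regression; compute each "
            "component's WSA directly (compute_direct_wsa) instead"
        )
    if gross_tonnage is None or gross_tonnage <= 0:
        raise DomainError(f"gross tonnage must be > 0, got {gross_tonnage}")
    return params.m * gross_tonnage ** params.b  # type: ignore[operator]


def compute_direct_wsa(hull: HullParams) -> float:
    """Compute wetted surface area (m²) directly from hull parameters."""
    if hull is None:
        raise ValidationError("hull parameters are required for direct WSA")
    L, B, T = hull.length_waterline, hull.beam, hull.draft
    cm, cb, cwp = hull.midship_coeff, hull.block_coeff, hull.waterplane_coeff
    bracket = (
        0.453
        + 0.4425 * cb
        - 0.2862 * cm
        - 0.003467 * B / T
        + 0.3696 * cwp
    )
    area = L * (2.0 * T + B) * math.sqrt(cm) * bracket
    area += 2.38 * hull.bulb_transverse_area / cb
    if area <= 0:
        raise DomainError(
            f"hull parameters give nonpositive WSA ({area:.3g} m²); check inputs"
        )
    return area


def compute_twsa(wsa: float, niche_proportion: float) -> float:
    """Total wetted surface area: ``WSA * (1 + N_p)``; always ≥ WSA."""
    if wsa <= 0:
        raise DomainError(f"wsa must be > 0, got {wsa}")
    if not 0 <= niche_proportion < 1:
        raise DomainError(
            f"niche_proportion must be in [0, 1), got {niche_proportion}"
        )
    return wsa * (1.0 + niche_proportion)


def compute_twsa_composite(
    barge_wsa: float,
    tug_wsa: float,
    barge_niche: float = BARGE_NICHE_PROPORTION,
    tug_niche: float = TUG_NICHE_PROPORTION,
    mode: AtbNicheMode = "per_component",
) -> float:
    """TWSA of a two-component (barge + tug) arrival.

    ``per_component`` (default) applies each niche proportion to its own
    component: ``barge_wsa*(1+0.033) + tug_wsa*(1+0.25)``.  ``summed``
    applies the summed proportion to the combined WSA:
    ``(barge_wsa + tug_wsa) * (1 + 0.033 + 0.25)``.
    """
    if barge_wsa <= 0 or tug_wsa <= 0:
        raise DomainError(
            "both barge and tug WSA must be > 0 "
            f"(got barge={barge_wsa}, tug={tug_wsa})"
        )
    if mode == "per_component":
        return compute_twsa(barge_wsa, barge_niche) + compute_twsa(tug_wsa, tug_niche)
    if mode == "summed":
        return compute_twsa(barge_wsa + tug_wsa, barge_niche + tug_niche)
    raise ValidationError(f"unknown ATB niche mode {mode!r}")


def arrival_twsa(
    arrival: VesselArrival,
    table: ParamsTable,
    atb_niche_mode: AtbNicheMode = "per_component",
) -> float:
    """Resolve one arrival to its TWSA via the route its type requires."""
    params = table.get(arrival.vessel_type)
    if params is None:
        raise ValidationError(
            f"no parameters for vessel type {arrival.vessel_type.value!r}"
        )
    if arrival.vessel_type in COMPOSITE_TYPES:
        barge_wsa = (
            arrival.precomputed_wsa
            if arrival.precomputed_wsa is not None
            else compute_direct_wsa(arrival.hull)
        )
        tug_wsa = (
            arrival.tug_precomputed_wsa
            if arrival.tug_precomputed_wsa is not None
            else compute_direct_wsa(arrival.tug_hull)
        )
        bn, tn = params.component_niches  # type: ignore[misc]
        return compute_twsa_composite(
            barge_wsa, tug_wsa, bn, tn, mode=atb_niche_mode
        )
    wsa = estimate_wsa_from_gt(arrival.gross_tonnage, params)
    return compute_twsa(wsa, params.niche_proportion)  # type: ignore[arg-type]


def refit_regression(
    observations: Iterable[tuple[float, float]] | Sequence[tuple[float, float]],
    type_code: VesselType = VesselType.GENERAL,
    niche_proportion: float = 0.0,
) -> VesselTypeParams:
    """Fit ``WSA = m * GT**b`` to (GT, WSA) pairs by least squares on logs.

    Returns a :class:`VesselTypeParams` carrying the fitted ``m`` and ``b``
    and the log–log fit's r².  Intended for jurisdictions refitting the
    power law to their own fleet; the packaged coefficients are not
    re-derived by this package.
    """
    obs = list(observations)
    if len(obs) < 3:
        raise ValidationError(
            f"need at least 3 (GT, WSA) pairs to fit, got {len(obs)}"
        )
    gt = np.asarray([p[0] for p in obs], dtype=float)
    wsa = np.asarray([p[1] for p in obs], dtype=float)
    if np.any(gt <= 0) or np.any(wsa <= 0):
        raise ValidationError("all GT and WSA values must be positive")
    x, y = np.log(gt), np.log(wsa)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return VesselTypeParams(
        type_code,
        m=float(np.exp(intercept)),
        b=float(slope),
        niche_proportion=niche_proportion,
        r_squared=r2,
        n_obs=len(obs),
    )
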