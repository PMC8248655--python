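"""Synthetic multi-year vessel-arrival populations.

Emulates the statistical structure the PPP model assumes so that every
pipeline stage is testable without any external dataset:

* a vessel-type mix defaulting to the proportions of a real one-year
  California arrival population (counts per type: barge+tug 382, general
  227, RO-RO 951, ATB 303, container 3608, tanker 2194, passenger 628,
  bulker 1135);
* per-type log-normal gross-tonnage distributions (tonnage is strongly
  right-skewed within a type);
* zero-inflated discharge volumes: most arrivals discharge no ballast; a
  per-type probability gates a log-normal volume;
* a vessel pool smaller than the arrival count, so repeat visits by the
  same vessel occur (as in real arrival data, where unique vessels number
  far fewer than arrivals);
* multiple ports with weights, calendar dates over a configurable range,
  and a small noncompliance rate.

This is a structural emulation, not a statistical fit to any real dataset.
"""

from __future__ import annotations

import datetime as dt
import math
import statistics
from typing import Optional

import numpy as np
import pydantic

from .errors import ValidationError
from .params import COMPOSITE_TYPES, VesselType
from .records import VesselArrival

#: Default type mix (relative arrival weights).
DEFAULT_TYPE_WEIGHTS: dict[VesselType, float] = {
    VesselType.BARGE_TUG: 382,
    VesselType.GENERAL: 227,
    VesselType.RORO: 951,
    VesselType.ATB: 303,
    VesselType.CONTAINER: 3608,
    VesselType.TANKER: 2194,
    VesselType.PASSENGER: 628,
    VesselType.BULKER: 1135,
}

#: Per-type gross tonnage: (median GT, sigma of log).  Chosen as typical of
#: the mixed deep-sea fleet calling at large west-coast ports.
DEFAULT_GT_DIST: dict[VesselType, tuple[float, float]] = {
    VesselType.GENERAL: (9_000, 0.60),
    VesselType.PASSENGER: (90_000, 0.35),
    VesselType.RORO: (55_000, 0.20),
    VesselType.BULKER: (33_000, 0.35),
    VesselType.CONTAINER: (55_000, 0.55),
    VesselType.TANKER: (30_000, 0.40),
}

#: Per-component WSA (m²) for composite types: (median, sigma of log),
#: barge first, then tug.
DEFAULT_COMPOSITE_WSA: dict[VesselType, tuple[tuple[float, float],
                                              tuple[float, float]]] = {
    VesselType.ATB: ((3_000, 0.30), (500, 0.25)),
    VesselType.BARGE_TUG: ((2_500, 0.30), (450, 0.25)),
}

#: Discharge model per type: (probability of any discharge,
#: median volume given discharge in m³, sigma of log volume).
DEFAULT_DISCHARGE: dict[VesselType, tuple[float, float, float]] = {
    VesselType.GENERAL: (0.30, 1_500, 0.9),
    VesselType.PASSENGER: (0.30, 1_000, 0.8),
    VesselType.RORO: (0.20, 1_500, 0.8),
    VesselType.BULKER: (0.70, 15_000, 0.8),
    VesselType.CONTAINER: (0.25, 2_000, 1.0),
    VesselType.TANKER: (0.50, 8_000, 0.9),
    VesselType.ATB: (0.40, 2_000, 0.8),
    VesselType.BARGE_TUG: (0.10, 500, 0.8),
}

DEFAULT_PORT_WEIGHTS: dict[str, float] = {
    "Los Angeles": 0.28,
    "Long Beach": 0.24,
    "Oakland": 0.20,
    "San Francisco": 0.07,
    "Richmond": 0.06,
    "Benicia": 0.04,
    "Stockton": 0.04,
    "San Diego": 0.04,
    "Hueneme": 0.03,
}


class FleetConfig(pydantic.BaseModel):
    """Configuration of a synthetic arrival population."""

    model_config = pydantic.ConfigDict(frozen=True)

    n_arrivals: int = pydantic.Field(default=9_428, gt=0)
    start_date: dt.date = dt.date(2018, 1, 1)
    end_date: dt.date = dt.date(2018, 12, 31)
    type_weights: dict[VesselType, float] = pydantic.Field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    gt_dist: dict[VesselType, tuple[float, float]] = pydantic.Field(
        default_factory=lambda: dict(DEFAULT_GT_DIST)
    )
    composite_wsa: dict[
        VesselType, tuple[tuple[float, float], tuple[float, float]]
    ] = pydantic.Field(default_factory=lambda: dict(DEFAULT_COMPOSITE_WSA))
    discharge: dict[VesselType, tuple[float, float, float]] = pydantic.Field(
        default_factory=lambda: dict(DEFAULT_DISCHARGE)
    )
    port_weights: dict[str, float] = pydantic.Field(
        default_factory=lambda: dict(DEFAULT_PORT_WEIGHTS)
    )
    noncompliance_rate: float = pydantic.Field(default=0.01, ge=0, le=1)
    #: unique vessels per type ≈ vessel_pool_factor × expected arrivals of
    #: that type (floor 1), so repeat visits occur.
    vessel_pool_factor: float = pydantic.Field(default=0.30, gt=0, le=1)
    seed: int = 0

    @pydantic.model_validator(mode="after")
    def _check(self) -> "FleetConfig":
        if self.start_date > self.end_date:
            raise ValueError("start_date must not exceed end_date")
        w = list(self.type_weights.values())
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("type weights must be non-negative, not all zero")
        for t, (p, med, sig) in self.discharge.items():
            if not 0 <= p <= 1 or med <= 0 or sig <= 0:
                raise ValueError(f"invalid discharge model for {t}")
        if not self.port_weights or sum(self.port_weights.values()) <= 0:
            raise ValueError("port weights must be positive")
        return self


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def generate_fleet(config: Optional[FleetConfig] = None,
                   seed: Optional[int] = None) -> list[VesselArrival]:
    """Generate a synthetic arrival population.

    Deterministic in ``(config, seed)``; ``seed`` overrides ``config.seed``
    when given.  Output is sorted by arrival date then arrival id.
    """
    if config is None:
        config = FleetConfig()
    if not isinstance(config, FleetConfig):
        raise ValidationError(f"expected FleetConfig, got {type(config)!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    types = [t for t, w in config.type_weights.items() if w > 0]
    weights = np.array([config.type_weights[t] for t in types], dtype=float)
    probs = weights / weights.sum()

    ports = list(config.port_weights)
    pw = np.array([config.port_weights[p] for p in ports], dtype=float)
    pw = pw / pw.sum()

    # Build per-type vessel pools: each vessel keeps a fixed size between
    # visits, so repeat arrivals share GT/WSA.
    pools: dict[VesselType, list[dict]] = {}
    vessel_counter = 0
    for t, p in zip(types, probs):
        n_vessels = max(1, round(config.vessel_pool_factor * p * config.n_arrivals))
        pool = []
        for _ in range(n_vessels):
            vessel_counter += 1
            vid = f"IMO{9_000_000 + vessel_counter}"
            if t in COMPOSITE_TYPES:
                (bmed, bsig), (tmed, tsig) = config.composite_wsa[t]
                pool.append(
                    {
                        "vessel_id": vid,
                        "wsa": _lognormal(rng, bmed, bsig),
                        "tug_wsa": _lognormal(rng, tmed, tsig),
                    }
                )
            else:
                med, sig = config.gt_dist[t]
                pool.append({"vessel_id": vid, "gt": _lognormal(rng, med, sig)})
        pools[t] = pool

    span = (config.end_date - config.start_date).days + 1
    arrivals: list[VesselArrival] = []
    type_idx = rng.choice(len(types), size=config.n_arrivals, p=probs)
    day_offsets = rng.integers(0, span, size=config.n_arrivals)
    port_idx = rng.choice(len(ports), size=config.n_arrivals, p=pw)
    order = np.argsort(day_offsets, kind="stable")
    for i, j in enumerate(order):
        t = types[type_idx[j]]
        vessel = pools[t][int(rng.integers(0, len(pools[t])))]
        p_disc, vmed, vsig = config.discharge[t]
        bwd = _lognormal(rng, vmed, vsig) if rng.random() < p_disc else 0.0
        fields: dict = {
            "arrival_id": f"A{i + 1:06d}",
            "vessel_id": vessel["vessel_id"],
            "vessel_type": t,
            "bwd_volume": bwd,
            "port": ports[port_idx[j]],
            "arrival_date": config.start_date + dt.timedelta(days=int(day_offsets[j])),
            "compliant": bool(rng.random() >= config.noncompliance_rate),
        }
        if t in COMPOSITE_TYPES:
            fields["precomputed_wsa"] = vessel["wsa"]
            fields["tug_precomputed_wsa"] = vessel["tug_wsa"]
        else:
            fields["gross_tonnage"] = vessel["gt"]
        arrivals.append(VesselArrival(**fields))
    return arrivals


# ---------------------------------------------------------------------------
# Naive oracle: a deliberately separate, straight-line re-implementation of
# the TWSA and PPP formulas using only the standard library, kept independent
# of wetted_area/scoring so it can serve as a cross-check in tests.
# ---------------------------------------------------------------------------

_NAIVE_PARAMS = {
    "general": (20.02, 0.5728, 0.09),
    "passenger": (5.46, 0.6951, 0.27),
    "roro": (25.04, 0.5309, 0.09),
    "bulker": (15.0, 0.6294, 0.07),
    "container": (10.66, 0.6501, 0.09),
    "tanker": (17.57, 0.6105, 0.08),
}


def _naive_twsa(a: VesselArrival) -> float:
    t = a.vessel_type.value
    if t in ("atb", "barge_tug"):
        return a.precomputed_wsa * (1 + 0.033) + a.tug_precomputed_wsa * (1 + 0.25)
    m, b, np_ = _NAIVE_PARAMS[t]
    return m * math.pow(a.gross_tonnage, b) * (1 + np_)


def generate_known_answer_set(
    config: Optional[FleetConfig] = None, seed: Optional[int] = None
) -> tuple[list[VesselArrival], list[dict]]:
    """Generate arrivals plus independently computed expected scores.

    The expected values use the naive oracle above with the arrivals
    themselves as the baseline population (discharging-only discharge
    median, per-arrival basis), for dual-implementation testing.
    """
    arrivals = generate_fleet(config, seed)
    twsa = {a.arrival_id: _naive_twsa(a) for a in arrivals}
    discharges = sorted(a.bwd_volume for a in arrivals if a.bwd_volume > 0)
    if not discharges:
        raise ValidationError(
            "known-answer set needs at least one discharging arrival"
        )
    med_bwd = statistics.median(discharges)
    med_twsa = statistics.median(sorted(twsa.values()))
    expected = []
    for a in arrivals:
        bw = a.bwd_volume / med_bwd
        bf = twsa[a.arrival_id] / med_twsa
        expected.append(
            {
                "arrival_id": a.arrival_id,
                "twsa": twsa[a.arrival_id],
                "bw_component": bw,
                "bf_component": bf,
                "ppp_score": bw + bf,
                "med_bwd": med_bwd,
                "med_twsa": med_twsa,
            }
        )
    return arrivals, expected
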