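"""Population baselines and per-arrival potential propagule pressure scores.

The PPP score of an arrival is the sum of two median-normalized,
dimensionless components:

    score = BWD / medBWD  +  TWSA / medTWSA

where the medians come from a representative historical population (e.g.
several years of arrivals).  An arrival sitting exactly at both population
medians scores exactly 2; an arrival discharging no ballast scores its
biofouling component alone.

Median policies
---------------
Most arrivals discharge no ballast at all, so the all-arrival median
discharge can be 0, which would break the normalization.  The default
policy therefore takes the discharge median over discharging arrivals only;
an ``all`` policy (median over every arrival, erroring loudly if it is 0)
is selectable.  Independently, "median individual vessel value" may be read
per arrival (default: every arrival is one observation) or per unique
vessel (median over each vessel's own median).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import statistics
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import BaselineError, PPPError, ScoringError
from .params import ParamsTable, default_params
from .records import VesselArrival
from .wetted_area import AtbNicheMode, arrival_twsa

DischargePolicy = Literal["discharging", "all"]
VesselBasis = Literal["arrival", "vessel"]


@dataclasses.dataclass(frozen=True)
class MedianPolicy:
    """How the population medians are formed."""

    discharge: DischargePolicy = "discharging"
    basis: VesselBasis = "arrival"


@dataclasses.dataclass(frozen=True)
class Baseline:
    """Population medians used to normalize the two PPP components."""

    med_bwd: float
    med_twsa: float
    window_start: dt.date
    window_end: dt.date
    n_arrivals: int
    n_discharging: int
    policy: MedianPolicy = MedianPolicy()

    def __post_init__(self) -> None:
        if self.med_bwd <= 0 or self.med_twsa <= 0:
            raise BaselineError(
                "baseline medians must be strictly positive "
                f"(med_bwd={self.med_bwd}, med_twsa={self.med_twsa})"
            )
        if self.window_start > self.window_end:
            raise BaselineError("window_start must not exceed window_end")
        if self.n_discharging > self.n_arrivals:
            raise BaselineError("n_discharging cannot exceed n_arrivals")

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to a small JSON document so a jurisdiction can freeze
        and version its baseline."""
        doc = {
            "med_bwd_m3": self.med_bwd,
            "med_twsa_m2": self.med_twsa,
            "window_start": self.window_start.isoformat(),
            "window_end": self.window_end.isoformat(),
            "n_arrivals": self.n_arrivals,
            "n_discharging": self.n_discharging,
            "policy": {
                "discharge": self.policy.discharge,
                "basis": self.policy.basis,
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Baseline":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            med_bwd=doc["med_bwd_m3"],
            med_twsa=doc["med_twsa_m2"],
            window_start=dt.date.fromisoformat(doc["window_start"]),
            window_end=dt.date.fromisoformat(doc["window_end"]),
            n_arrivals=doc["n_arrivals"],
            n_discharging=doc["n_discharging"],
            policy=MedianPolicy(**doc["policy"]),
        )


@dataclasses.dataclass(frozen=True)
class ScoredArrival:
    """An arrival together with its TWSA and PPP score decomposition."""

    arrival: VesselArrival
    twsa: float
    bw_component: float
    bf_component: float
    ppp_score: float

    @property
    def arrival_id(self) -> str:
        return self.arrival.arrival_id


@dataclasses.dataclass
class BatchResult:
    """Result of scoring a batch: scored arrivals in input order plus the
    per-arrival failures that were collected instead of aborting."""

    scored: list[ScoredArrival]
    failures: list[ScoringError]


def _median_for(
    values: Sequence[tuple[str, float]],
    basis: VesselBasis,
) -> float:
    """Median of (vessel_id, value) observations under the chosen basis."""
    if basis == "arrival":
        return statistics.median(v for _, v in values)
    per_vessel: dict[str, list[float]] = {}
    for vid, v in values:
        per_vessel.setdefault(vid, []).append(v)
    return statistics.median(
        statistics.median(vs) for vs in per_vessel.values()
    )


def compute_baseline(
    population: Iterable[VesselArrival],
    policy: MedianPolicy = MedianPolicy(),
    table: ParamsTable | None = None,
    atb_niche_mode: AtbNicheMode = "per_component",
) -> Baseline:
    """Compute population medians of ballast discharge and TWSA.

    ``med_twsa`` is the median per-arrival TWSA over the whole population;
    ``med_bwd`` follows the discharge policy.  Errors rather than silently
    substituting a fallback when the policy yields no usable median.
    """
    pop = list(population)
    if not pop:
        raise BaselineError("population is empty")
    table = table if table is not None else default_params()

    twsa_obs = [
        (a.vessel_id, arrival_twsa(a, table, atb_niche_mode)) for a in pop
    ]
    n_discharging = sum(1 for a in pop if a.bwd_volume > 0)
    if policy.discharge == "discharging":
        bwd_obs = [(a.vessel_id, a.bwd_volume) for a in pop if a.bwd_volume > 0]
        if not bwd_obs:
            raise BaselineError(
                "no arrivals with positive discharge: the 'discharging' "
                "median policy has no observations"
            )
    else:
        bwd_obs = [(a.vessel_id, a.bwd_volume) for a in pop]
    med_bwd = _median_for(bwd_obs, policy.basis)
    if med_bwd <= 0:
        raise BaselineError(
            f"median discharge is {med_bwd} under policy "
            f"discharge={policy.discharge!r}, basis={policy.basis!r}; "
            "a positive median is required for normalization"
        )
    med_twsa = _median_for(twsa_obs, policy.basis)
    dates = [a.arrival_date for a in pop]
    return Baseline(
        med_bwd=med_bwd,
        med_twsa=med_twsa,
        window_start=min(dates),
        window_end=max(dates),
        n_arrivals=len(pop),
        n_discharging=n_discharging,
        policy=policy,
    )


def score_arrival(
    arrival: VesselArrival,
    baseline: Baseline,
    table: ParamsTable | None = None,
    atb_niche_mode: AtbNicheMode = "per_component",
) -> ScoredArrival:
    """Score one arrival against a baseline.

    Raises :class:`ScoringError` (carrying the arrival id) when the arrival
    cannot be resolved to a TWSA.
    """
    table = table if table is not None else default_params()
    try:
        twsa = arrival_twsa(arrival, table, atb_niche_mode)
    except PPPError as exc:
        raise ScoringError(arrival.arrival_id, str(exc)) from exc
    bw = arrival.bwd_volume / baseline.med_bwd
    bf = twsa / baseline.med_twsa
    return ScoredArrival(
        arrival=arrival,
        twsa=twsa,
        bw_component=bw,
        bf_component=bf,
        ppp_score=bw + bf,
    )


def score_batch(
    arrivals: Iterable[VesselArrival],
    baseline: Baseline,
    table: ParamsTable | None = None,
    atb_niche_mode: AtbNicheMode = "per_component",
    strict: bool = False,
) -> BatchResult:
    """Score a batch, preserving input order.

    Per-arrival failures are collected into the result's ``failures`` list;
    ``strict=True`` re-raises the first failure instead.
    """
    table = table if table is not None else default_params()
    scored: list[ScoredArrival] = []
    failures: list[ScoringError] = []
    for a in arrivals:
        try:
            scored.append(score_arrival(a, baseline, table, atb_niche_mode))
        except ScoringError as exc:
            if strict:
                raise
            failures.append(exc)
    return BatchResult(scored=scored, failures=failures)
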