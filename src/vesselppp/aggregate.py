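"""Cumulative PPP scores by port, vessel type and time period.

Because the PPP score is additive in its two components, summing scores
within a group decomposes exactly into a summed ballast-water part and a
summed biofouling part, which is how one locates where — and through which
vector — potential propagule pressure concentrates.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AggregationError, DomainError
from .scoring import ScoredArrival

#: Grouping fields users may request, and how each is derived.
GROUPABLE_FIELDS = ("port", "vessel_type", "year", "month", "quarter", "date")


@dataclasses.dataclass(frozen=True)
class GroupScore:
    """Cumulative PPP for one grouping key."""

    key: tuple
    n_arrivals: int
    cum_bw: float
    cum_bf: float
    cum_total: float
    mean_score: float
    se_score: float


def _frame(
    scored: Iterable[ScoredArrival],
    port_complexes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    rows = []
    for s in scored:
        a = s.arrival
        port = a.port
        if port_complexes:
            port = port_complexes.get(port, port)
        rows.append(
            {
                "port": port,
                "vessel_type": a.vessel_type.value,
                "date": a.arrival_date,
                "year": a.arrival_date.year,
                "month": f"{a.arrival_date.year}-{a.arrival_date.month:02d}",
                "quarter": f"{a.arrival_date.year}Q"
                f"{(a.arrival_date.month - 1) // 3 + 1}",
                "bw": s.bw_component,
                "bf": s.bf_component,
                "score": s.ppp_score,
            }
        )
    return pd.DataFrame(rows)


def cumulative_scores(
    scored: Iterable[ScoredArrival],
    group_by: Sequence[str] | str,
    port_complexes: Mapping[str, str] | None = None,
) -> list[GroupScore]:
    """Sum scores and components over a grouping.

    ``group_by`` names one or more of :data:`GROUPABLE_FIELDS`.  An optional
    ``port_complexes`` map collapses ports into reporting complexes (e.g.
    Los Angeles and Long Beach reported jointly) before grouping.  Results
    are ordered by descending cumulative total, then key.
    """
    if isinstance(group_by, str):
        group_by = [g.strip() for g in group_by.split(",") if g.strip()]
    group_by = list(group_by)
    unknown = [g for g in group_by if g not in GROUPABLE_FIELDS]
    if unknown or not group_by:
        raise AggregationError(
            f"unknown grouping field(s) {unknown or group_by}; "
            f"available: {', '.join(GROUPABLE_FIELDS)}"
        )
    df = _frame(scored, port_complexes)
    if df.empty:
        return []
    out: list[GroupScore] = []
    for key, grp in df.groupby(group_by, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        sd = float(grp["score"].std(ddof=1)) if n > 1 else 0.0
        out.append(
            GroupScore(
                key=tuple(key),
                n_arrivals=n,
                cum_bw=float(grp["bw"].sum()),
                cum_bf=float(grp["bf"].sum()),
                cum_total=float(grp["score"].sum()),
                mean_score=float(grp["score"].mean()),
                se_score=sd / math.sqrt(n),
            )
        )
    out.sort(key=lambda g: (-g.cum_total, g.key))
    return out


def component_shares(group: GroupScore) -> tuple[float, float]:
    """Fractions of a group's cumulative score from ballast water and from
    biofouling; the two always sum to 1."""
    if group.cum_total <= 0:
        raise DomainError(
            f"group {group.key}: shares undefined for cum_total="
            f"{group.cum_total}"
        )
    return group.cum_bw / group.cum_total, group.cum_bf / group.cum_total


def min_arrival_filter(
    groups: Iterable[GroupScore], threshold: int
) -> list[GroupScore]:
    """Drop groups with fewer than ``threshold`` arrivals (e.g. ports with
    too few calls to compare meaningfully)."""
    if threshold < 0:
        raise DomainError(f"threshold must be >= 0, got {threshold}")
    return [g for g in groups if g.n_arrivals >= threshold]


def groups_to_frame(groups: Iterable[GroupScore], group_by: Sequence[str] | str
                    ) -> pd.DataFrame:
    """Tabulate GroupScores for writing as delimited text."""
    if isinstance(group_by, str):
        group_by = [g.strip() for g in group_by.split(",") if g.strip()]
    rows = []
    for g in groups:
        row = dict(zip(group_by, g.key))
        row.update(
            n_arrivals=g.n_arrivals,
            cum_bw=g.cum_bw,
            cum_bf=g.cum_bf,
            cum_total=g.cum_total,
            mean_score=g.mean_score,
            se_score=g.se_score,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def plot_port_type_summary(
    scored: Iterable[ScoredArrival],
    out_path: str,
    min_arrivals: int = 0,
    port_complexes: Mapping[str, str] | None = None,
) -> None:
    """Render a port × vessel-type bubble chart of cumulative PPP with
    stacked component bars in the margins (a compact regional summary)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = min_arrival_filter(
        cumulative_scores(scored, ["port", "vessel_type"], port_complexes), 0
    )
    ports = min_arrival_filter(
        cumulative_scores(scored, ["port"], port_complexes), min_arrivals
    )
    keep = {p.key[0] for p in ports}
    cells = [c for c in cells if c.key[0] in keep]
    types = cumulative_scores(scored, ["vessel_type"])
    port_order = [p.key[0] for p in ports]
    type_order = [t.key[0] for t in types]

    fig, ax = plt.subplots(figsize=(1.2 * len(port_order) + 3,
                                    0.6 * len(type_order) + 2))
    max_total = max((c.cum_total for c in cells), default=1.0)
    for c in cells:
        x = port_order.index(c.key[0])
        y = type_order.index(c.key[1])
        ax.scatter(x, y, s=2000 * c.cum_total / max_total, alpha=0.5,
                   color="tab:blue")
    ax.set_xticks(range(len(port_order)), port_order, rotation=45, ha="right")
    ax.set_yticks(range(len(type_order)), type_order)
    ax.set_xlabel("port")
    ax.set_ylabel("vessel type")
    ax.set_title("Cumulative PPP score (bubble area ∝ cumulative score)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
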