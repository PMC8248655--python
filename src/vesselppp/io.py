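"""Reading and writing arrival tables and results.

Canonical on-disk format is comma-separated UTF-8 text with ISO-8601 dates.
Spreadsheet (.xlsx) input is supported read-only for compatibility with
ballast-reporting templates.  Row validation is collected into a report;
invalid rows are dropped with logged reasons, never silently coerced.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pydantic
import yaml

from .aggregate import cumulative_scores, groups_to_frame, min_arrival_filter
from .errors import ValidationError
from .params import ParamsTable, default_params, load_params
from .prioritize import DEFAULT_CAPACITY, PriorityList, prioritize_daily
from .records import HullParams, VesselArrival
from .scoring import (
    Baseline,
    BatchResult,
    MedianPolicy,
    ScoredArrival,
    compute_baseline,
    score_batch,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "arrival_id",
    "vessel_id",
    "vessel_type",
    "gross_tonnage",
    "bwd_volume",
    "port",
    "arrival_date",
    "compliant",
)

OPTIONAL_COLUMNS = (
    "precomputed_wsa",
    "tug_precomputed_wsa",
    "length_waterline",
    "beam",
    "draft",
    "midship_coeff",
    "block_coeff",
    "waterplane_coeff",
    "bulb_transverse_area",
    "tug_length_waterline",
    "tug_beam",
    "tug_draft",
    "tug_midship_coeff",
    "tug_block_coeff",
    "tug_waterplane_coeff",
    "tug_bulb_transverse_area",
)

#: Header-name aliases (lower-cased, stripped) → canonical column.
DEFAULT_COLUMN_ALIASES: dict[str, str] = {
    "arrival id": "arrival_id",
    "vessel id": "vessel_id",
    "imo": "vessel_id",
    "imo number": "vessel_id",
    "vessel name": "vessel_id",
    "vessel type": "vessel_type",
    "type": "vessel_type",
    "gt": "gross_tonnage",
    "gross tonnage": "gross_tonnage",
    "bwd": "bwd_volume",
    "bwd volume": "bwd_volume",
    "ballast water discharge": "bwd_volume",
    "discharge volume": "bwd_volume",
    "discharge volume (m3)": "bwd_volume",
    "arrival port": "port",
    "port of arrival": "port",
    "date": "arrival_date",
    "arrival date": "arrival_date",
    "compliance": "compliant",
    "wsa": "precomputed_wsa",
    "barge wsa": "precomputed_wsa",
    "tug wsa": "tug_precomputed_wsa",
}

_HULL_FIELDS = (
    "length_waterline",
    "beam",
    "draft",
    "midship_coeff",
    "block_coeff",
    "waterplane_coeff",
    "bulb_transverse_area",
)

_TRUE_STRINGS = {"true", "t", "yes", "y", "1"}
_FALSE_STRINGS = {"false", "f", "no", "n", "0"}


@dataclasses.dataclass(frozen=True)
class ArrivalTableSchema:
    """How to interpret an arrivals table: column aliases and date format."""

    aliases: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COLUMN_ALIASES)
    )
    date_format: Optional[str] = None  # None → ISO-8601 / pandas inference


@dataclasses.dataclass
class RowProblem:
    row: int
    arrival_id: Optional[str]
    reason: str


@dataclasses.dataclass
class ValidationReport:
    n_rows: int
    n_valid: int
    problems: list[RowProblem]


def _canonical_columns(
    columns: Sequence[str], schema: ArrivalTableSchema
) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = str(col).strip().lower()
        canon = schema.aliases.get(key, key.replace(" ", "_"))
        mapping[col] = canon
    return mapping


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return True  # unflagged → compliant
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValueError(f"unparseable compliance flag {value!r}")


def _opt_float(row: pd.Series, col: str) -> Optional[float]:
    if col not in row or pd.isna(row[col]) or str(row[col]).strip() == "":
        return None
    return float(row[col])


def _hull_from_row(row: pd.Series, prefix: str = "") -> Optional[HullParams]:
    vals = {f: _opt_float(row, prefix + f) for f in _HULL_FIELDS}
    present = {k: v for k, v in vals.items() if v is not None}
    if not present:
        return None
    missing = [f for f in _HULL_FIELDS[:-1] if vals[f] is None]  # A_BT optional
    if missing:
        raise ValueError(
            f"incomplete {prefix or 'barge '}hull parameters; missing: "
            + ", ".join(missing)
        )
    vals.setdefault("bulb_transverse_area", 0.0)
    return HullParams(**{k: (v if v is not None else 0.0) for k, v in vals.items()})


def read_arrivals(
    path: str | Path,
    schema: ArrivalTableSchema | None = None,
    sheet: int | str = 0,
) -> tuple[list[VesselArrival], ValidationReport]:
    """Read and validate an arrivals table (CSV/TSV or .xlsx).

    Returns the validated arrivals plus a report of dropped rows.  Missing
    required columns are fatal; a missing discharge value on a row is
    treated as 0 m³ with a logged warning (no report of discharge is read
    as no discharge).
    """
    schema = schema or ArrivalTableSchema()
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"arrivals file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, comment="#")
    df = df.rename(columns=_canonical_columns(df.columns, schema))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {', '.join(missing)} "
            f"(after alias resolution)"
        )

    arrivals: list[VesselArrival] = []
    problems: list[RowProblem] = []
    for idx, row in df.iterrows():
        arrival_id = str(row["arrival_id"]) if not pd.isna(row["arrival_id"]) else None
        try:
            bwd = row["bwd_volume"]
            if pd.isna(bwd) or str(bwd).strip() == "":
                logger.warning(
                    "row %s (%s): missing discharge volume treated as 0 m³",
                    idx, arrival_id,
                )
                bwd = 0.0
            raw_date = row["arrival_date"]
            if isinstance(raw_date, (dt.date, dt.datetime, pd.Timestamp)):
                date = pd.Timestamp(raw_date).date()
            elif schema.date_format:
                date = dt.datetime.strptime(
                    str(raw_date).strip(), schema.date_format
                ).date()
            else:
                date = pd.Timestamp(str(raw_date).strip()).date()
            fields: dict = {
                "arrival_id": arrival_id,
                "vessel_id": str(row["vessel_id"]),
                "vessel_type": str(row["vessel_type"]),
                "gross_tonnage": _opt_float(row, "gross_tonnage"),
                "bwd_volume": float(bwd),
                "port": str(row["port"]).strip(),
                "arrival_date": date,
                "compliant": _parse_bool(row["compliant"]),
                "precomputed_wsa": _opt_float(row, "precomputed_wsa"),
                "tug_precomputed_wsa": _opt_float(row, "tug_precomputed_wsa"),
                "hull": _hull_from_row(row),
                "tug_hull": _hull_from_row(row, prefix="tug_"),
            }
            arrivals.append(VesselArrival(**fields))
        except pydantic.ValidationError as exc:
            reason = "; ".join(
                f"{'.'.join(map(str, e['loc'])) or 'record'}: {e['msg']}"
                for e in exc.errors()
            )
            problems.append(RowProblem(int(idx), arrival_id, reason))
            logger.warning("row %s (%s) dropped: %s", idx, arrival_id, reason)
        except (ValueError, ValidationError) as exc:
            reason = str(exc).splitlines()[0]
            problems.append(RowProblem(int(idx), arrival_id, reason))
            logger.warning("row %s (%s) dropped: %s", idx, arrival_id, reason)
    report = ValidationReport(
        n_rows=len(df), n_valid=len(arrivals), problems=problems
    )
    return arrivals, report


def arrivals_to_frame(arrivals: Iterable[VesselArrival]) -> pd.DataFrame:
    rows = []
    for a in arrivals:
        row = {
            "arrival_id": a.arrival_id,
            "vessel_id": a.vessel_id,
            "vessel_type": a.vessel_type.value,
            "gross_tonnage": a.gross_tonnage,
            "bwd_volume": a.bwd_volume,
            "port": a.port,
            "arrival_date": a.arrival_date.isoformat(),
            "compliant": a.compliant,
            "precomputed_wsa": a.precomputed_wsa,
            "tug_precomputed_wsa": a.tug_precomputed_wsa,
        }
        for prefix, hull in (("", a.hull), ("tug_", a.tug_hull)):
            if hull is not None:
                for f in _HULL_FIELDS:
                    row[prefix + f] = getattr(hull, f)
        rows.append(row)
    return pd.DataFrame(rows)


def write_arrivals(arrivals: Iterable[VesselArrival], path: str | Path) -> None:
    """Write arrivals in the canonical CSV format."""
    df = arrivals_to_frame(arrivals)
    df.to_csv(path, index=False)


def scores_to_frame(scored: Iterable[ScoredArrival]) -> pd.DataFrame:
    rows = []
    for s in scored:
        a = s.arrival
        rows.append(
            {
                "arrival_id": a.arrival_id,
                "vessel_id": a.vessel_id,
                "vessel_type": a.vessel_type.value,
                "port": a.port,
                "arrival_date": a.arrival_date.isoformat(),
                "gross_tonnage": a.gross_tonnage,
                "bwd_volume": a.bwd_volume,
                "compliant": a.compliant,
                "twsa": s.twsa,
                "bw_component": s.bw_component,
                "bf_component": s.bf_component,
                "ppp_score": s.ppp_score,
            }
        )
    return pd.DataFrame(rows)


def write_scores(
    scored: Iterable[ScoredArrival],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        scores_to_frame(scored).to_csv(fh, index=False)


def priority_lists_to_frame(lists: Iterable[PriorityList]) -> pd.DataFrame:
    rows = []
    for pl in lists:
        for e in pl.entries:
            a = e.scored.arrival
            rows.append(
                {
                    "date": pl.date.isoformat(),
                    "rank": e.rank,
                    "arrival_id": a.arrival_id,
                    "vessel_id": a.vessel_id,
                    "vessel_type": a.vessel_type.value,
                    "port": a.port,
                    "ppp_score": e.scored.ppp_score,
                    "bw_component": e.scored.bw_component,
                    "bf_component": e.scored.bf_component,
                    "reason": e.reason,
                }
            )
    return pd.DataFrame(rows)


def write_priority_lists(
    lists: Iterable[PriorityList],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        priority_lists_to_frame(lists).to_csv(fh, index=False)


def format_daily_report(pl: PriorityList) -> str:
    """Human-readable report for one day's priority list."""
    lines = [
        f"Inspection priorities for {pl.date.isoformat()} "
        f"(capacity {pl.capacity}/day)",
    ]
    for e in pl.entries:
        a = e.scored.arrival
        flag = "  [NONCOMPLIANT]" if e.reason == "noncompliant" else ""
        lines.append(
            f"  {e.rank:>2}. {a.arrival_id}  {a.vessel_id:<12} "
            f"{a.vessel_type.value:<10} {a.port:<14} "
            f"PPP={e.scored.ppp_score:6.2f} "
            f"(BW={e.scored.bw_component:.2f}, BF={e.scored.bf_component:.2f})"
            f"{flag}"
        )
    if pl.excluded:
        lines.append(f"  ({len(pl.excluded)} arrivals below capacity threshold)")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Pipeline configuration and end-to-end driver
# ---------------------------------------------------------------------------


class PipelineConfig(pydantic.BaseModel):
    """Tunable knobs of the end-to-end workflow."""

    capacity: int = DEFAULT_CAPACITY
    median_discharge_policy: str = "discharging"  # or "all"
    median_basis: str = "arrival"  # or "vessel"
    atb_niche_mode: str = "per_component"  # or "summed"
    count_noncompliant_against_capacity: bool = False
    first_arrival_only: bool = False
    min_arrivals: int = 0
    group_by: str = "port,vessel_type"
    params_path: Optional[str] = None
    port_complexes: dict[str, str] = pydantic.Field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def median_policy(self) -> MedianPolicy:
        return MedianPolicy(
            discharge=self.median_discharge_policy,  # type: ignore[arg-type]
            basis=self.median_basis,  # type: ignore[arg-type]
        )

    def params_table(self) -> ParamsTable:
        if self.params_path:
            return load_params(self.params_path)
        return default_params()


@dataclasses.dataclass
class PipelineResult:
    baseline: Baseline
    batch: BatchResult
    priority_lists: list[PriorityList]
    group_scores: list
    config_hash: str


def run_pipeline(
    population: Iterable[VesselArrival] | str | Path,
    arrivals: Iterable[VesselArrival] | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run baseline → scoring → prioritization → aggregation end to end.

    ``population`` and ``arrivals`` may be file paths or in-memory lists.
    When ``out_dir`` is given, all four artifacts are written there as
    delimited text / JSON, each stamped with the config hash and the
    baseline provenance window.
    """
    config = config or PipelineConfig()
    if isinstance(population, (str, Path)):
        population, _ = read_arrivals(population)
    if isinstance(arrivals, (str, Path)):
        arrivals, _ = read_arrivals(arrivals)
    population = list(population)
    arrivals = list(arrivals)

    table = config.params_table()
    policy = config.median_policy()
    mode = config.atb_niche_mode
    baseline = compute_baseline(population, policy, table, mode)  # type: ignore[arg-type]
    batch = score_batch(arrivals, baseline, table, mode)  # type: ignore[arg-type]
    pool = batch.scored
    if config.first_arrival_only:
        from .prioritize import apply_first_arrival_policy

        pool = apply_first_arrival_policy(pool)
    lists = prioritize_daily(
        pool,
        capacity=config.capacity,
        count_noncompliant=config.count_noncompliant_against_capacity,
    )
    groups = min_arrival_filter(
        cumulative_scores(
            batch.scored, config.group_by, config.port_complexes or None
        ),
        config.min_arrivals,
    )
    chash = config.config_hash()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        provenance = (
            f"config_hash={chash} baseline_window="
            f"{baseline.window_start.isoformat()}/{baseline.window_end.isoformat()}"
        )
        baseline.to_json(out / "baseline.json")
        write_scores(batch.scored, out / "scores.csv", provenance)
        write_priority_lists(lists, out / "priority_lists.csv", provenance)
        with (out / "group_scores.csv").open("w") as fh:
            fh.write(f"# {provenance}\n")
            groups_to_frame(groups, config.group_by).to_csv(fh, index=False)
        if batch.failures:
            with (out / "scoring_failures.txt").open("w") as fh:
                for f in batch.failures:
                    fh.write(f"{f.arrival_id}\t{f.reason}\n")
    return PipelineResult(
        baseline=baseline,
        batch=batch,
        priority_lists=lists,
        group_scores=groups,
        config_hash=chash,
    )
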