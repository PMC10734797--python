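"""Delimited-table readers/writers for the engine's input and output schemas.

All tables are UTF-8 CSV with a header row; dates are ISO-8601 strings;
EDSS scores are serialized with one fractional digit.  Readers validate the
schema and return either plain DataFrames or the engine's domain objects.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import pandas as pd

from .catalog import normalize_code, split_qualifier
from .engine import ClaimEvent, CoverageInterval, FlaggedIndex, PedssResult

__all__ = [
    "SchemaError",
    "read_table",
    "read_events",
    "read_coverage",
    "read_deaths",
    "read_measures",
    "events_by_patient",
    "coverage_by_patient",
    "write_results",
    "write_cohort_tables",
]


class SchemaError(ValueError):
    """An input table does not match its documented schema."""


_SCHEMAS = {
    "events": ["patient_id", "date", "code_system", "code", "setting", "qualifier"],
    "coverage": ["patient_id", "start", "end"],
    "deaths": ["patient_id", "date"],
    "measures": ["patient_id", "date", "score"],
    "index_dates": ["patient_id", "date"],
}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one of the documented tables, checking required columns."""
    required = _SCHEMAS[kind]
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for a {kind} table")
    for col in ("date", "start", "end"):
        if col in df.columns:
            try:
                df[col] = pd.to_datetime(df[col], format="ISO8601").dt.date
            except Exception as exc:
                raise SchemaError(
                    f"{path}: column {col!r} must hold ISO-8601 dates: {exc}"
                ) from exc
    return df


def read_events(path: str | Path) -> list[ClaimEvent]:
    df = read_table(path, "events")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        code, qualifier = split_qualifier(str(row.code))
        qualifier_col = getattr(row, "qualifier", None)
        if isinstance(qualifier_col, str) and qualifier_col.strip():
            qualifier = qualifier_col.strip()
        try:
            events.append(
                ClaimEvent(
                    patient_id=str(row.patient_id),
                    date=row.date,
                    code_system=str(row.code_system).strip(),
                    code=normalize_code(code, str(row.code_system).strip()),
                    setting=str(row.setting).strip(),
                    qualifier=qualifier or "none",
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return events


def events_by_patient(events: Sequence[ClaimEvent]) -> dict[str, list[ClaimEvent]]:
    out: dict[str, list[ClaimEvent]] = {}
    for e in events:
        out.setdefault(e.patient_id, []).append(e)
    return out


def read_coverage(path: str | Path) -> dict[str, list[CoverageInterval]]:
    df = read_table(path, "coverage")
    return coverage_by_patient(
        CoverageInterval(str(r.patient_id), r.start, r.end)
        for r in df.itertuples(index=False)
    )


def coverage_by_patient(intervals) -> dict[str, list[CoverageInterval]]:
    out: dict[str, list[CoverageInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.patient_id, []).append(iv)
    return out


def read_deaths(path: str | Path) -> dict[str, dt.date]:
    df = read_table(path, "deaths")
    return {str(r.patient_id): r.date for r in df.itertuples(index=False)}


def read_measures(path: str | Path) -> pd.DataFrame:
    df = read_table(path, "measures")
    df["score"] = df["score"].astype(float)
    return df


def write_results(
    results: Sequence[PedssResult],
    flagged: Sequence[FlaggedIndex],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the proxy-score results table and the flagged-index table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_path = out_dir / "pedss_results.csv"
    flagged_path = out_dir / "flagged.csv"
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "index_date": r.index_date.isoformat(),
                "pedss": r.pedss,
                "fired_clause": r.fired_clause,
            }
            for r in results
        ],
        columns=["patient_id", "index_date", "pedss", "fired_clause"],
    ).to_csv(results_path, index=False)
    pd.DataFrame(
        [
            {
                "patient_id": f.patient_id,
                "index_date": f.index_date.isoformat(),
                "reason": f.reason,
            }
            for f in flagged
        ],
        columns=["patient_id", "index_date", "reason"],
    ).to_csv(flagged_path, index=False)
    return results_path, flagged_path


def _iso_dates(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("date", "start", "end"):
        if col in df.columns:
            df[col] = df[col].map(lambda d: d.isoformat())
    return df


def write_cohort_tables(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort's four tables in the engine's input schema."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("measures", "events", "coverage", "deaths"):
        df = _iso_dates(getattr(cohort, name))
        if name == "measures":
            df["score"] = df["score"].map(lambda s: f"{s:.1f}")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
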