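"""CSV schemas and the packaged study census table.

Life-history CSV columns: individual_id, sex, birth_date, entry_date,
entry_stage, exit_date, exit_cause, calving_dates (semicolon-separated
ISO-8601 dates); empty string means unknown/none.

Census CSV columns: year, pfc, the six sex-by-stage counts, and per-cell
import/export annotations, mirroring the published demographic history of
the study population (Great Fish River Reserve, 1986-2008).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import importlib.resources
import json
import platform
from pathlib import Path

import pandas as pd

from .life_history import CENSUS_COLUMNS, LifeHistoryRecord

LIFE_HISTORY_COLUMNS = [
    "individual_id",
    "sex",
    "birth_date",
    "entry_date",
    "entry_stage",
    "exit_date",
    "exit_cause",
    "calving_dates",
]


def _parse_date(s) -> dt.date | None:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return None
    return dt.date.fromisoformat(str(s))


def read_life_history(path) -> list[LifeHistoryRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(LIFE_HISTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"life-history CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        calvings = tuple(
            dt.date.fromisoformat(c)
            for c in str(row["calving_dates"]).split(";")
            if c.strip()
        )
        records.append(
            LifeHistoryRecord(
                individual_id=row["individual_id"],
                sex=row["sex"],
                birth_date=_parse_date(row["birth_date"]),
                entry_date=_parse_date(row["entry_date"]),
                entry_stage=row["entry_stage"],
                exit_date=_parse_date(row["exit_date"]),
                exit_cause=row["exit_cause"] or None,
                calving_dates=calvings,
            )
        )
    return records


def write_life_history(records, path) -> None:
    rows = [
        {
            "individual_id": r.individual_id,
            "sex": r.sex,
            "birth_date": r.birth_date.isoformat() if r.birth_date else "",
            "entry_date": r.entry_date.isoformat(),
            "entry_stage": r.entry_stage,
            "exit_date": r.exit_date.isoformat() if r.exit_date else "",
            "exit_cause": r.exit_cause or "",
            "calving_dates": ";".join(c.isoformat() for c in r.calving_dates),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=LIFE_HISTORY_COLUMNS).to_csv(path, index=False)


def read_census(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("year")
    missing = set(CENSUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"census CSV missing columns: {sorted(missing)}")
    return df[list(CENSUS_COLUMNS)]


def write_census(census: pd.DataFrame, path) -> None:
    census.reset_index().to_csv(path, index=False)


def read_rainfall(path) -> pd.Series:
    """Rainfall CSV: columns year, rain_mm."""
    df = pd.read_csv(path)
    if not {"year", "rain_mm"} <= set(df.columns):
        raise ValueError("rainfall CSV needs columns: year, rain_mm")
    return df.set_index("year")["rain_mm"].astype(float)


def load_study_census() -> pd.DataFrame:
    """The packaged 1986-2008 census table of the study population."""
    ref = importlib.resources.files("rhinopfc.data") / "gfrr_census.csv"
    with importlib.resources.as_file(ref) as p:
        return read_census(p)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, command: str, config: dict, inputs=(), seed=None) -> None:
    """Reproducibility manifest for one CLI run."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "seed": seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp": dt.datetime.now(dt.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


__all__ = [
    "LIFE_HISTORY_COLUMNS",
    "read_life_history",
    "write_life_history",
    "read_census",
    "write_census",
    "read_rainfall",
    "load_study_census",
    "file_digest",
    "write_manifest",
]
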