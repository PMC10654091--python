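"""Tabular IO helpers and report-only input validation."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exposure import EXPOSURE_COLUMNS, ROUTES
from .titers import TITER_COLUMNS


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def validate_inputs(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Schema-check input tables and report violations (never raises).

    ``paths`` maps table kind (``titers``, ``exposures``, ``samples``,
    ``features_*``, ``metabolites``) to file paths. Returns one row per
    violation with columns ``table, row, problem`` (row numbers are
    0-based data rows).
    """
    problems: list[dict] = []

    def note(table, row, problem):
        problems.append(dict(table=str(table), row=row, problem=problem))

    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            note(kind, -1, "file not found")
            continue
        df = read_tsv(path)
        if kind == "titers":
            missing = [c for c in TITER_COLUMNS if c not in df.columns]
            if missing:
                note(kind, -1, f"missing columns {missing}")
                continue
            dup = df.duplicated(subset=["subject_id", "antigen", "timepoint"])
            for i in df.index[dup]:
                note(kind, int(i), "duplicate (subject, antigen, timepoint)")
            for i in df.index[df["value"] < 0]:
                note(kind, int(i), f"negative titer value {df.loc[i, 'value']}")
        elif kind == "exposures":
            missing = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
            if missing:
                note(kind, -1, f"missing columns {missing}")
                continue
            for i in df.index[~df["route"].isin(ROUTES)]:
                note(kind, int(i), f"unknown route {df.loc[i, 'route']!r}")
            for i in df.index[df["duration_days"] < 1]:
                note(kind, int(i), "duration_days < 1")
            for i in df.index[df["start_day"] < 0]:
                note(kind, int(i), "start_day < 0")
        elif kind == "samples":
            for col in ("sample_id", "subject_id", "age_days", "sample_type"):
                if col not in df.columns:
                    note(kind, -1, f"missing column {col!r}")
        elif kind.startswith("features"):
            num = df.select_dtypes("number")
            neg = num < 0
            if neg.any().any():
                for i in df.index[neg.any(axis=1)]:
                    cols = list(num.columns[neg.loc[i]])
                    note(kind, int(i), f"negative count in {cols[:3]}")
    return pd.DataFrame(problems, columns=["table", "row", "problem"])
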