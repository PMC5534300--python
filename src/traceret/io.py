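"""Delimited-table and config I/O.

Subject tables are CSV/TSV with autodetected delimiters; decimal commas
are accepted and normalized to dots.  Column names follow the
``height / weight / daily_diuresis / water_<El> / serum_<El> /
urine_<El>`` convention and can be remapped via a config block.
"""

from __future__ import annotations

import csv
from typing import Mapping, Optional

import pandas as pd
import yaml

from traceret.core import SubjectRecord, TraceElement

__all__ = ["read_subject_table", "subjects_to_frame", "load_yaml", "save_yaml"]

ANTHRO_COLUMNS = ("height", "weight", "daily_diuresis")


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(payload: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_subject_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    decimal_comma: bool = False,
) -> list[SubjectRecord]:
    """Read subjects from a delimited text table.

    ``column_map`` maps canonical names (e.g. ``height``, ``water_Zn``)
    to the file's actual column names.  Missing serum/urine columns are
    allowed (the cascade stage can fill them in); missing
    anthropometrics are not.
    """
    try:
        df = pd.read_csv(
            path,
            sep=None,
            engine="python",
            decimal="," if decimal_comma else ".",
            comment="#",
        )
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, csv.Error) as exc:
        raise IOError(f"cannot read subject table {path}: {exc}") from exc

    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})

    missing = [c for c in ANTHRO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table {path} lacks required columns: {missing}")

    records = []
    for i, row in df.iterrows():
        water, serum, urine = {}, {}, {}
        for el in TraceElement:
            for store, comp in ((water, "water"), (serum, "serum"), (urine, "urine")):
                col = f"{comp}_{el.value}"
                if col in df.columns and pd.notna(row[col]):
                    store[el] = float(row[col])
        records.append(
            SubjectRecord(
                height=float(row["height"]),
                weight=float(row["weight"]),
                daily_diuresis=float(row["daily_diuresis"]),
                water_conc=water,
                serum_conc=serum or None,
                urine_conc=urine or None,
                subject_id=str(row["subject_id"]) if "subject_id" in df.columns else f"S{i:05d}",
            )
        )
    return records


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten subjects to the canonical wide table layout."""
    rows = []
    for i, s in enumerate(subjects):
        row = {
            "subject_id": s.subject_id or f"S{i:05d}",
            "height": s.height,
            "weight": s.weight,
            "daily_diuresis": s.daily_diuresis,
        }
        for el, v in s.water_conc.items():
            row[f"water_{el.value}"] = v
        for store, comp in ((s.serum_conc, "serum"), (s.urine_conc, "urine")):
            if store:
                for el, v in store.items():
                    row[f"{comp}_{el.value}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
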