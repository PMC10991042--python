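"""Reading and writing single-case series and result tables."""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .series import ABSeries, RawRecord, make_equidistant

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "load_fitnet_example",
    "result_to_json",
]

DEFAULT_MISSING = ("", "NA", "NaN", "nan")


def read_series_csv(
    path: str | Path,
    time_col: str = "time",
    phase_col: str = "phase",
    y_col: str = "y",
    missing: Sequence[str] = DEFAULT_MISSING,
) -> list[RawRecord]:
    """Parse a delimited file with time-marker, phase and outcome columns.

    Outcome fields matching one of ``missing`` become missing values; phase
    labels are upper-cased.  Unparseable rows raise with their row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (time_col, phase_col, y_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} not found")
    records = []
    missing_set = {m.lower() for m in missing}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        raw_t = getattr(row, time_col).strip()
        raw_p = getattr(row, phase_col).strip().upper()
        raw_y = getattr(row, y_col).strip()
        try:
            t = int(raw_t)
        except ValueError as exc:
            raise ValueError(f"{path}, row {i}: bad time marker {raw_t!r}") from exc
        if raw_p not in ("A", "B"):
            raise ValueError(f"{path}, row {i}: bad phase label {raw_p!r}")
        if raw_y.lower() in missing_set:
            y = math.nan
        else:
            try:
                y = float(raw_y)
            except ValueError as exc:
                raise ValueError(f"{path}, row {i}: bad outcome {raw_y!r}") from exc
        records.append(RawRecord(t, raw_p, y))
    if not records:
        raise ValueError(f"{path}: no data rows")
    return records


def write_series_csv(series: ABSeries, path: str | Path) -> None:
    """Write an equidistant series back out; missing outcomes become ``NA``."""
    df = pd.DataFrame(
        {
            "time": series.time,
            "phase": series.phase,
            "y": ["NA" if not math.isfinite(v) else _fmt(v) for v in series.y],
        }
    )
    df.to_csv(path, index=False)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def fitnet_records() -> list[RawRecord]:
    """The packaged worked-example records: 37 weekly fatigue (CIS-8) scores
    of one adolescent observed before and during internet-based CBT; week 22
    was not observed, so the raw table is not equidistant."""
    ref = resources.files("pdt.data").joinpath("fitnet_plus.csv")
    with resources.as_file(ref) as p:
        return read_series_csv(p)


def load_fitnet_example() -> ABSeries:
    """The worked-example series in equidistant form (week 22 inserted as missing)."""
    return make_equidistant(fitnet_records())


def result_to_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
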