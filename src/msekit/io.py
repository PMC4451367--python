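"""Plain-text readers and writers.

The interchange format is a single numeric column (optionally a delimited
multi-column file with a column selector), with ``#``-prefixed header lines
carrying ``key=value`` metadata such as the sampling interval ``dt``.
Output tables are TSV with a commented configuration header, or JSON with
an explicit ``{"config": ..., "records": [...]}`` layout.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .signals import TimeSeries

__all__ = ["read_series", "write_series", "write_table", "read_table"]

_META_RE = re.compile(r"([A-Za-z_][\w.]*)\s*=\s*(\S+)")


def read_series(
    path: Union[str, Path],
    column: int = 0,
    comment_char: str = "#",
    label: Optional[str] = None,
) -> TimeSeries:
    """Read a numeric series from a text file, one row per sample.

    Header lines starting with ``comment_char`` are scanned for
    ``key=value`` pairs; a ``dt`` key sets the sampling interval.
    Non-numeric data rows raise with their 1-based line number.
    """
    path = Path(path)
    meta: Dict[str, str] = {}
    values: List[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(comment_char):
                for k, v in _META_RE.findall(line[len(comment_char):]):
                    meta[k] = v
                continue
            fields = re.split(r"[,\s;]+", line)
            if column >= len(fields):
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} column(s), "
                    f"need column {column}"
                )
            try:
                values.append(float(fields[column]))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {fields[column]!r} on line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path}: no data rows found")
    dt = float(meta.get("dt", 1.0))
    return TimeSeries(values, dt=dt, label=label if label is not None else path.stem)


def write_series(x: TimeSeries, path: Union[str, Path],
                 meta: Optional[Mapping[str, object]] = None) -> None:
    """Write a series as one value per line with a ``#`` metadata header."""
    path = Path(path)
    header = {"dt": x.dt, "label": x.label, "n": len(x)}
    if x.seed is not None:
        header["seed"] = x.seed
    if meta:
        header.update(meta)
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        for v in x.values:
            fh.write(f"{float(v)!r}\n")


def write_table(
    records: Union[Sequence[Mapping[str, object]], pd.DataFrame],
    path: Union[str, Path],
    format: str = "tsv",
    config: Optional[Mapping[str, object]] = None,
) -> None:
    """Write tabular results as TSV (with a commented config header) or JSON."""
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    cfg = dict(config or {})
    if format == "tsv":
        with open(path, "w") as fh:
            for k, v in cfg.items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif format == "json":
        payload = {"config": cfg, "records": df.to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (either format)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        payload = json.loads(text)
        return pd.DataFrame(payload["records"])
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
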