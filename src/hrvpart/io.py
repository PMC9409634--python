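"""Plain-text interchange formats.

RR/NN series travel as one interval (milliseconds) per line; blank lines
and ``#`` comments are ignored.  Cohort tables are ordinary CSV read into
pandas.  Results are JSON with sorted keys so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "read_rr",
    "write_rr",
    "read_cohort",
    "write_cohort",
    "write_results",
]


def read_rr(path: str | Path) -> np.ndarray:
    """Read an RR-interval file (ms per line) into a float array.

    Raises :class:`ParseError` (with the 1-based line number) on a value
    that is not a number or is not strictly positive.
    """
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                v = float(line)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: not a number: {line!r}", line=lineno
                ) from None
            if not v > 0:
                raise ParseError(
                    f"{path}: line {lineno}: RR interval must be > 0 ms, got {v}",
                    line=lineno,
                )
            values.append(v)
    return np.asarray(values, dtype=float)


def write_rr(path: str | Path, intervals) -> None:
    intervals = np.asarray(intervals, dtype=float)
    with open(path, "w") as fh:
        for v in intervals:
            fh.write(f"{v:.6f}\n")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_results(obj, path: str | Path) -> None:
    """Serialize a result mapping to JSON deterministically (sorted keys)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
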