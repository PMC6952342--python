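"""Reading and writing curve tables, parameter files and JSON reports.

Curve tables are plain CSV (comma, dot decimal, UTF-8) with headers
``C_Pa`` and ``A_umol_m2_s`` and an optional ``state`` column.  Parameter
files are flat JSON or YAML whose keys match the FvCBParams field names
exactly; unknown keys are rejected.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .errors import CurveFormatError
from .fitting import ResponseCurve
from .params import Frame, FvCBParams, LimitationState

__all__ = ["read_curve", "write_curve", "read_params", "write_json"]

logger = logging.getLogger("fvcbgeom")

C_COLUMN = "C_Pa"
A_COLUMN = "A_umol_m2_s"
STATE_COLUMN = "state"


def read_curve(path: Union[str, Path], frame: Frame) -> ResponseCurve:
    """Load a response curve from CSV.

    Fails hard with the offending row number on non-numeric cells and on
    duplicate C values; rows arriving out of order are sorted with a logged
    warning.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise CurveFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in (C_COLUMN, A_COLUMN):
        if col not in table.columns:
            raise CurveFormatError(
                f"{path}: missing required column {col!r}; "
                f"found {list(table.columns)}"
            )
    numeric = {}
    for col in (C_COLUMN, A_COLUMN):
        parsed = pd.to_numeric(table[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            raise CurveFormatError(
                f"{path}: non-numeric value in column {col!r} at data row "
                f"{int(bad[0]) + 1}: {table[col].iloc[bad[0]]!r}"
            )
        numeric[col] = parsed.to_numpy(dtype=float)

    C, A = numeric[C_COLUMN], numeric[A_COLUMN]
    if np.unique(C).size != C.size:
        dup = C[pd.Series(C).duplicated().to_numpy()][0]
        raise CurveFormatError(f"{path}: duplicate C value {dup:g} Pa")

    states = None
    if STATE_COLUMN in table.columns:
        states = [
            LimitationState(s) if isinstance(s, str) and s in ("c", "j", "p") else None
            for s in table[STATE_COLUMN]
        ]

    order = np.argsort(C)
    if not np.array_equal(order, np.arange(C.size)):
        logger.warning("%s: C values not sorted; sorting ascending", path)
        C, A = C[order], A[order]
        if states is not None:
            states = [states[i] for i in order]

    return ResponseCurve(
        C=C,
        A=A,
        frame=Frame(frame),
        states=states,
        meta={"path": str(path), "frame": Frame(frame).value},
    )


def write_curve(curve: ResponseCurve, path: Union[str, Path]) -> None:
    """Write a response curve to CSV (roundtrips with :func:`read_curve`)."""
    data = {C_COLUMN: curve.C, A_COLUMN: curve.A}
    if curve.states is not None:
        data[STATE_COLUMN] = [
            s.value if s is not None else "" for s in curve.states
        ]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_params(path: Union[str, Path]) -> FvCBParams:
    """Load a parameter set from flat JSON or YAML (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        mapping = yaml.safe_load(text)
    else:
        mapping = json.loads(text)
    if not isinstance(mapping, dict):
        raise CurveFormatError(f"{path}: expected a flat mapping of parameters")
    return FvCBParams.from_mapping(mapping)


def write_json(obj: dict, path: Union[str, Path]) -> None:
    """Serialise a report dict to JSON with stable key order."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
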