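"""CSV/JSON/YAML readers and writers.

Titrations travel as two-column CSV (``quencher_conc_M,intensity``; header
required, molar concentrations, period decimal separator). Fit results are
JSON objects that always carry both point estimates and uncertainty fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .inference import CalibrationResult, OrientationFit
from .models import TitrationSeries

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "calibration_to_dict",
    "orientation_to_dict",
    "write_json",
    "write_manifest",
]

REQUIRED_COLUMNS = ("quencher_conc_M", "intensity")


class TitrationFormatError(ValueError):
    """Malformed titration file; the message names the offending row."""


def read_titration_csv(path: Union[str, Path], sample_id: str | None = None) -> TitrationSeries:
    """Parse a titration CSV into a validated :class:`TitrationSeries`.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TitrationFormatError(
            f"{path.name}: missing required column(s) {missing}; "
            f"expected header {list(REQUIRED_COLUMNS)}"
        )
    for col in REQUIRED_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise TitrationFormatError(
                f"{path.name}: malformed numeric value in column {col!r} "
                f"at data row {bad[0] + 1} ({df[col].iloc[bad[0]]!r})"
            )
        df[col] = vals
    q = df["quencher_conc_M"].to_numpy(float)
    inten = df["intensity"].to_numpy(float)
    neg = np.nonzero(q < 0)[0]
    if neg.size:
        raise TitrationFormatError(
            f"{path.name}: negative quencher concentration at data row {neg[0] + 1}"
        )
    nonpos = np.nonzero(inten <= 0)[0]
    if nonpos.size:
        raise TitrationFormatError(
            f"{path.name}: non-positive intensity at data row {nonpos[0] + 1}"
        )
    _, counts = np.unique(q, return_counts=True)
    if np.any(counts > 1):
        dup_val = np.unique(q)[counts > 1][0]
        row = int(np.nonzero(q == dup_val)[0][1]) + 1
        raise TitrationFormatError(
            f"{path.name}: duplicate quencher concentration {dup_val!r} at data row {row}"
        )
    if not np.any(q == 0.0):
        raise TitrationFormatError(f"{path.name}: no zero-quencher baseline")
    return TitrationSeries(
        sample_id=sample_id or path.stem,
        points=list(zip(q.tolist(), inten.tolist())),
    )


def write_titration_csv(series: TitrationSeries, path: Union[str, Path]) -> None:
    """Write a series as CSV; round-trips through :func:`read_titration_csv`."""
    df = pd.DataFrame(series.points, columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")


def calibration_to_dict(result: CalibrationResult) -> dict:
    return {
        "Kq_hat_per_M": result.Kq_hat,
        "Kq_stderr_per_M": result.Kq_stderr,
        "intercept": result.intercept,
        "r_squared": result.r_squared,
        "n_points": result.n_points,
        "residuals": [float(r) for r in result.residuals],
    }


def orientation_to_dict(fit: OrientationFit) -> dict:
    d = dataclasses.asdict(fit)
    return {
        "x_hat": d["x_hat"],
        "x_stderr": d["x_stderr"],
        "ci_low": d["ci_low"],
        "ci_high": d["ci_high"],
        "Kq_used_per_M": d["Kq_used"],
        "rss": d["rss"],
        "converged": d["converged"],
        "clipped": d["clipped"],
        "warnings": d["warnings"],
    }


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_manifest(params: dict, path: Union[str, Path]) -> None:
    """YAML manifest recording every generating parameter and seed."""
    Path(path).write_text(yaml.safe_dump(params, sort_keys=True))
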