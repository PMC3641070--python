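"""Readers and writers for force-plate exports and result bundles.

Input is delimited text (CSV/TSV, e.g. a Bioware-style export) with a
configurable column map; output is a JSON result bundle (losslessly
round-trippable) or a flat CSV row for batch concatenation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .cop_signal import CopTrajectory

__all__ = [
    "ColumnMap",
    "read_trajectory",
    "write_result",
    "read_result",
    "result_bundle",
    "write_batch_csv",
]

logger = logging.getLogger(__name__)

_RESULT_FIELDS = [
    "source",
    "seed",
    "speed_mm_s",
    "area_mm2",
    "alpha_short",
    "alpha_long",
    "alpha_global",
    "crossover_samples",
    "crossover_ms",
    "single_slope",
    "no_distinct_regimes",
]


@dataclass
class ColumnMap:
    """How to find COP coordinates in a delimited text export.

    Columns may be referenced by header name (str) or 0-based position
    (int).  ``scale_to_mm`` converts the file's length unit to mm (1000
    for meters, 10 for cm).
    """

    x: str | int = "x"
    y: str | int = "y"
    time: str | int | None = None
    delimiter: str = ","
    decimal: str = "."
    skip_rows: int = 0
    scale_to_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("x and y columns must be distinct")
        if not (self.scale_to_mm > 0):
            raise ValueError("scale_to_mm must be positive")


def _column(df: pd.DataFrame, ref: str | int, path: str, role: str) -> np.ndarray:
    if isinstance(ref, int):
        if ref >= df.shape[1]:
            raise ValueError(
                f"{path}: {role} column index {ref} out of range "
                f"({df.shape[1]} columns)"
            )
        return df.iloc[:, ref].to_numpy(dtype=float)
    if ref not in df.columns:
        raise ValueError(
            f"{path}: {role} column '{ref}' not found; columns are "
            f"{list(df.columns)}"
        )
    return df[ref].to_numpy(dtype=float)


def read_trajectory(
    path: str | Path,
    sample_rate: float,
    column_map: ColumnMap | None = None,
) -> CopTrajectory:
    """Read a COP trajectory from a delimited text file.

    Rows with non-finite coordinates are dropped with a logged count.  If
    a time column is mapped, the median sampling interval is checked
    against ``sample_rate`` to within 1%.
    """
    cmap = column_map or ColumnMap()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path}: no such file")
    header = "infer" if isinstance(cmap.x, str) or isinstance(cmap.y, str) else None
    df = pd.read_csv(
        path,
        sep=cmap.delimiter,
        decimal=cmap.decimal,
        skiprows=cmap.skip_rows,
        header=header,
    )
    x = _column(df, cmap.x, str(path), "x")
    y = _column(df, cmap.y, str(path), "y")
    t = None
    if cmap.time is not None:
        t = _column(df, cmap.time, str(path), "time")

    ok = np.isfinite(x) & np.isfinite(y)
    if t is not None:
        ok &= np.isfinite(t)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d non-finite rows", path, n_dropped)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError(f"{path}: fewer than 2 valid samples after cleaning")

    if t is not None:
        dt = float(np.median(np.diff(t[ok])))
        if dt <= 0:
            raise ValueError(f"{path}: time column is not increasing")
        implied = 1.0 / dt
        if abs(implied - sample_rate) > 0.01 * sample_rate:
            raise ValueError(
                f"{path}: time column implies {implied:.6g} Hz but "
                f"sample_rate={sample_rate:g} Hz (>1% mismatch)"
            )
    return CopTrajectory(
        x=x * cmap.scale_to_mm,
        y=y * cmap.scale_to_mm,
        sample_rate=sample_rate,
        meta={"source": str(path), "dropped_rows": n_dropped},
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_bundle(
    summary: Any = None,
    scaling: Any = None,
    curve: Any = None,
    config: Any = None,
    seed: int | None = None,
    source: str | None = None,
    extra: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Assemble an analysis result into a JSON-serializable bundle."""
    from . import __version__

    bundle: dict[str, Any] = {"software_version": __version__}
    if source is not None:
        bundle["source"] = source
    if seed is not None:
        bundle["seed"] = int(seed)
    if summary is not None:
        bundle["summary"] = _jsonable(summary)
    if scaling is not None:
        bundle["scaling"] = _jsonable(scaling)
    if curve is not None:
        bundle["curve"] = _jsonable(curve)
    if config is not None:
        bundle["config"] = _jsonable(config)
    if extra:
        bundle.update(_jsonable(extra))
    return bundle


def write_result(bundle: dict[str, Any], path: str | Path, format: str = "json") -> None:
    """Write a result bundle as canonical JSON or a flat CSV row.

    JSON uses sorted keys and shortest round-trip float representation,
    so write -> read -> write is byte-identical.
    """
    path = Path(path)
    if format == "json":
        text = json.dumps(_jsonable(bundle), sort_keys=True, indent=2)
        path.write_text(text + "\n")
    elif format == "csv":
        write_batch_csv([bundle], path)
    else:
        raise ValueError("format must be 'json' or 'csv'")


def _flat_row(bundle: dict[str, Any]) -> dict[str, Any]:
    summary = bundle.get("summary", {}) or {}
    scaling = bundle.get("scaling", {}) or {}
    return {
        "source": bundle.get("source", ""),
        "seed": bundle.get("seed", ""),
        "speed_mm_s": summary.get("speed", np.nan),
        "area_mm2": summary.get("area", np.nan),
        "alpha_short": scaling.get("alpha_short", np.nan),
        "alpha_long": scaling.get("alpha_long", np.nan),
        "alpha_global": scaling.get("alpha_global", np.nan),
        "crossover_samples": scaling.get("crossover_scale", np.nan),
        "crossover_ms": scaling.get("crossover_ms", np.nan),
        "single_slope": scaling.get("single_slope", False),
        "no_distinct_regimes": scaling.get("no_distinct_regimes", False),
    }


def write_batch_csv(bundles: list[dict[str, Any]], path: str | Path) -> None:
    """One flat CSV row per trial, fixed column order, for concatenation."""
    rows = pd.DataFrame([_flat_row(b) for b in bundles], columns=_RESULT_FIELDS)
    rows.to_csv(path, index=False)


def read_result(path: str | Path) -> dict[str, Any]:
    """Read back a JSON result bundle."""
    return json.loads(Path(path).read_text())
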