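"""Readers, writers and analysis configuration.

Coordinate tables are delimited text (comma or tab, header row) or XLSX
sheets with one x and one y column in planar meters. Windows come from the
study-plot presets or explicit dimensions; by default the window is anchored
at (floor(min x), floor(min y)) of the data because deposited coordinate
files rarely state their origin, and a strict mode requires an explicit
origin instead.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .comparisons import InfiltrationSummary, SizeComparison
from .errors import (
    FCSpatError,
    GeographicCoordinatesError,
    ImplausibleExtentError,
    MissingColumnError,
    UnparseableRowError,
    WriteFailureError,
)
from .nn import ClarkEvansResult
from .patterns import ObservationWindow, PointPattern, make_pattern
from .secondorder import EnvelopeResult

__all__ = [
    "AnalysisConfig",
    "read_points_table",
    "write_report",
    "envelope_frame",
    "reproduce_survey_table",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline settings; the defaults are the study's analysis settings
    (999 CSR realizations for the Clark-Evans test at alpha 0.05, rank-5
    envelopes of 199 simulations)."""

    nn_n_sim: int = 999
    alpha: float = 0.05
    envelope_statistic: str = "g"
    envelope_n_sim: int = 199
    envelope_rank: int = 5
    correction: str = "translation"
    bandwidth: float | str = "auto"
    seed: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_table(path: Path, sheet, delimiter) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=delimiter)


def _numeric_column(df: pd.DataFrame, name: str, path: Path) -> np.ndarray:
    if name not in df.columns:
        raise MissingColumnError(
            f"{path.name}: column {name!r} not found; available: {list(df.columns)}"
        )
    col = pd.to_numeric(df[name], errors="coerce")
    bad = col.isna() & df[name].notna()
    if bad.any():
        # +2: header line plus 1-based numbering, matching what an editor shows
        rows = (np.nonzero(bad.to_numpy())[0] + 2).tolist()
        raise UnparseableRowError(
            f"{path.name}: non-numeric {name!r} value(s) at file row(s) {rows[:10]}"
        )
    if col.isna().any():
        rows = (np.nonzero(col.isna().to_numpy())[0] + 2).tolist()
        raise UnparseableRowError(
            f"{path.name}: missing {name!r} value(s) at file row(s) {rows[:10]}"
        )
    return col.to_numpy(dtype=float)


def _looks_geographic(x: np.ndarray, y: np.ndarray, window: ObservationWindow) -> bool:
    span = max(x.max() - x.min(), y.max() - y.min())
    in_degree_range = (
        np.abs(x).max() <= 180.0 and np.abs(y).max() <= 90.0 and span < 2.0
    )
    return in_degree_range and window.shorter_side > 50.0


def read_points_table(
    path,
    x_column: str = "x",
    y_column: str = "y",
    sheet=None,
    delimiter: str | None = None,
    window: ObservationWindow | None = None,
    label: str = "",
    anchor: str = "floor_min",
    extent_tolerance: float = 0.05,
    allow_empty: bool = False,
) -> PointPattern:
    """Read a coordinate table and return a validated :class:`PointPattern`.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file or XLSX workbook.
    x_column, y_column : str
        Names of the coordinate columns (meters).
    sheet : str, int or None
        Sheet to read from a workbook (first sheet when None).
    delimiter : str or None
        Field separator for text files (inferred from the suffix when None).
    window : ObservationWindow or None
        Declared window. When None, a tight window spanning the data
        bounding box (floored/ceiled to whole meters) is used.
    anchor : {"floor_min", "origin"}
        "floor_min" re-anchors the declared window at (floor(min x),
        floor(min y)) of the data; "origin" keeps the window exactly as
        declared (strict mode).
    extent_tolerance : float
        Raise ``ImplausibleExtentError`` when the data bounding box exceeds
        the declared window dimensions by more than this fraction.
    """
    path = Path(path)
    df = _load_table(path, sheet, delimiter)
    x = _numeric_column(df, x_column, path)
    y = _numeric_column(df, y_column, path)
    pts = np.column_stack([x, y])

    if pts.shape[0] == 0:
        if window is None:
            raise ImplausibleExtentError(f"{path.name}: no rows and no window given")
        return make_pattern(pts, window, label=label, allow_empty=allow_empty)

    if window is None:
        win = ObservationWindow(
            x_min=math.floor(x.min()),
            y_min=math.floor(y.min()),
            width=max(math.ceil(x.max()) - math.floor(x.min()), 1.0),
            height=max(math.ceil(y.max()) - math.floor(y.min()), 1.0),
        )
    else:
        if _looks_geographic(x, y, window):
            raise GeographicCoordinatesError(
                f"{path.name}: coordinates look like lon/lat degrees; project "
                "to planar meters (e.g. UTM) before analysis"
            )
        span_x = x.max() - x.min()
        span_y = y.max() - y.min()
        if (span_x > window.width * (1 + extent_tolerance)
                or span_y > window.height * (1 + extent_tolerance)):
            raise ImplausibleExtentError(
                f"{path.name}: data spans {span_x:.1f} x {span_y:.1f} m but the "
                f"declared window is {window.width:.0f} x {window.height:.0f} m"
            )
        if anchor == "floor_min":
            win = window.anchored_at(math.floor(x.min()), math.floor(y.min()))
        elif anchor == "origin":
            win = window
        else:
            raise ValueError("anchor must be 'floor_min' or 'origin'")
        # numerical safety: points may overhang a floored anchor by < 1 m
        if not win.contains(pts).all():
            pad_x = max(0.0, x.max() - win.x_max)
            pad_y = max(0.0, y.max() - win.y_max)
            if max(pad_x, pad_y) > window.shorter_side * extent_tolerance:
                raise ImplausibleExtentError(
                    f"{path.name}: points overhang the anchored window by "
                    f"{max(pad_x, pad_y):.1f} m"
                )
            win = ObservationWindow(
                win.x_min, win.y_min,
                win.width + math.ceil(pad_x), win.height + math.ceil(pad_y),
            )
    return make_pattern(pts, win, label=label or path.stem, allow_empty=allow_empty)


def envelope_frame(result: EnvelopeResult) -> pd.DataFrame:
    """Curve table for an envelope: r, observed, lower, upper, theoretical."""
    est = result.estimate
    return pd.DataFrame(
        {
            "r": est.grid.r,
            "observed": est.values,
            "lower": result.lower,
            "upper": result.upper,
            "theoretical": est.theoretical,
        }
    )


def _envelope_meta(res: EnvelopeResult) -> dict:
    est = res.estimate
    return {
        "statistic": est.statistic_name,
        "n_sim": res.n_sim,
        "rank": res.rank,
        "seed": res.seed,
        "edge_correction": est.edge_correction,
        "bandwidth": est.bandwidth,
        "classification": res.classification,
        "excursions": [
            {"r_start": e.r_start, "r_end": e.r_end, "sign": e.sign}
            for e in res.excursions
        ],
    }


def write_report(results, out_dir, config: AnalysisConfig | None = None) -> list[Path]:
    """Write a result collection to ``out_dir``.

    Produces ``summary.csv`` (one row per Clark-Evans result, survey-table
    columns), ``report.json`` (full precision plus seeds and settings), and
    one ``curves_<label>.csv`` per envelope result. Returns written paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise WriteFailureError(str(exc)) from exc

    if not results:
        raise ValueError("write_report needs a non-empty result collection")

    written: list[Path] = []
    rows, meta_records = [], []
    env_count = 0
    for res in results:
        if isinstance(res, ClarkEvansResult):
            rows.append(res.to_row())
            meta_records.append(
                {"type": "clark_evans", **dataclasses.asdict(res)}
            )
        elif isinstance(res, EnvelopeResult):
            env_count += 1
            label = res.estimate.statistic_name + "_" + (
                "".join(c if c.isalnum() else "_" for c in (res.classification or ""))
                or str(env_count)
            )
            curve_path = out_dir / f"curves_{label}_{env_count}.csv"
            envelope_frame(res).to_csv(curve_path, index=False)
            written.append(curve_path)
            meta_records.append({"type": "envelope", **_envelope_meta(res)})
        elif isinstance(res, SizeComparison):
            meta_records.append({"type": "size_comparison", **dataclasses.asdict(res)})
        elif isinstance(res, InfiltrationSummary):
            meta_records.append(
                {
                    "type": "infiltration",
                    "region": res.region,
                    "position": res.position,
                    "mean": res.mean,
                    "median": res.median,
                    "n": res.n,
                    "times": res.times.tolist(),
                }
            )
        else:
            raise TypeError(f"unsupported result type {type(res).__name__}")

    if rows:
        summary_path = out_dir / "summary.csv"
        pd.DataFrame(rows).to_csv(summary_path, index=False)
        written.append(summary_path)

    meta = {
        "config": (config or AnalysisConfig()).to_dict(),
        "results": meta_records,
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(_jsonable(meta), indent=2))
    written.append(json_path)
    return written


def reproduce_survey_table(
    data,
    x_column: str = "x",
    y_column: str = "y",
    n_sim: int = 999,
    seed: int = 0,
    sheet_map: dict | None = None,
) -> list[dict]:
    """Re-analyze the deposited coordinate workbook row by row.

    Matches each published per-plot row to a workbook sheet (by fuzzy name
    match, or via ``sheet_map``), runs the Clark-Evans pipeline with the
    study settings, and returns one record per row holding the recomputed
    values, the published reference, and their deltas. Rows whose sheet
    cannot be found or parsed carry an ``"error"`` key instead.
    """
    import openpyxl

    from .nn import clark_evans_test
    from .patterns import window_preset
    from .reference_values import PUBLISHED_TABLE1

    data = Path(data)
    wb = openpyxl.load_workbook(data, read_only=True)
    sheets = wb.sheetnames
    wb.close()
    sheet_map = sheet_map or {}

    def match_sheet(label: str) -> str | None:
        if label in sheet_map:
            return sheet_map[label]
        tokens = label.lower().replace("-", "").split()
        for name in sheets:
            flat = name.lower().replace("-", "").replace("_", " ")
            if all(tok in flat for tok in tokens):
                return name
        return None

    records: list[dict] = []
    for i, ref in enumerate(PUBLISHED_TABLE1):
        rec: dict = {"reference": dict(ref)}
        sheet = match_sheet(ref["label"])
        if sheet is None:
            rec["error"] = "no matching sheet"
            records.append(rec)
            continue
        plot = ref["label"].split()[0]
        try:
            pattern = read_points_table(
                data, x_column=x_column, y_column=y_column, sheet=sheet,
                window=window_preset(plot), label=ref["label"],
            )
            res = clark_evans_test(pattern, n_sim=n_sim, seed=seed + i)
        except FCSpatError as exc:
            rec["error"] = str(exc)
            records.append(rec)
            continue
        row = res.to_row()
        rec["computed"] = row
        rec["result"] = res
        rec["delta"] = {
            "n": row["n"] - ref["n"],
            "mean_nn_m": row["mean_nn_m"] - ref["mean_nn_m"],
            "cv_nn_pct": row["cv_nn_pct"] - ref["cv_nn_pct"],
            "clark_evans_R": row["clark_evans_R"] - ref["clark_evans_R"],
            "pattern_match": row["pattern"] == ref["pattern"],
        }
        records.append(rec)
    return records


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
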