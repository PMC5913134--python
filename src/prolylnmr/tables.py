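"""Readers and writers for intensity tables, titration tables, Sparky peak
lists, and JSON result reports.

All file-level units follow reporting conventions: mixing times in ms,
concentrations in uM, shifts in ppm.  Conversion to the internal unit
system (seconds) happens here and only here.  Parsers reject malformed
input with the offending location; they never silently coerce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exchange import IntensityCurve
from .titration import TitrationPoint, TitrationSeries

__all__ = [
    "PeakTable",
    "read_intensity_table",
    "write_intensity_table",
    "read_titration_table",
    "write_titration_table",
    "read_sparky_peaklist",
    "write_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

_INTENSITY_COLS = ["mixing_time_ms", "I_cc", "I_tt", "I_ct", "I_tc"]
_TITRATION_COLS = ["peak_id", "ligand_total_uM", "protein_total_uM", "w1_ppm", "w2_ppm"]


@dataclass
class PeakTable:
    """Rows of (assignment, w1 ppm, w2 ppm, height) from a Sparky list."""

    assignments: list[str]
    w1: np.ndarray
    w2: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.assignments)) != len(self.assignments):
            raise ValueError("assignment labels must be unique per table")
        if not (np.all(np.isfinite(self.w1)) and np.all(np.isfinite(self.w2))):
            raise ValueError("shifts must be finite")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def _read_delimited(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header has {list(df.columns)}")
    numeric = [c for c in required if c != "peak_id"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            rows = bad or df.index[coerced.isna()].tolist()
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: non-numeric or empty cell in column {col!r}, "
                             f"line(s) {[i + 2 for i in rows]}")
        df[col] = coerced
    return df


def read_intensity_table(path: str | Path) -> IntensityCurve:
    """Read a ROESY intensity table (times in ms) into an IntensityCurve (s)."""
    df = _read_delimited(path, _INTENSITY_COLS)
    t_ms = df["mixing_time_ms"].to_numpy()
    dup = pd.Series(t_ms).duplicated()
    if dup.any():
        lines = [i + 2 for i in df.index[dup].tolist()]
        raise ValueError(f"{path}: duplicate mixing time at line(s) {lines}")
    order = np.argsort(t_ms)
    return IntensityCurve(
        mixing_times=t_ms[order] / 1e3,
        I_cc=df["I_cc"].to_numpy()[order], I_tt=df["I_tt"].to_numpy()[order],
        I_ct=df["I_ct"].to_numpy()[order], I_tc=df["I_tc"].to_numpy()[order])


def write_intensity_table(curve: IntensityCurve, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "mixing_time_ms": curve.mixing_times * 1e3,
        "I_cc": curve.I_cc, "I_tt": curve.I_tt,
        "I_ct": curve.I_ct, "I_tc": curve.I_tc})
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_titration_table(path: str | Path) -> TitrationSeries:
    """Read a long-format titration table into a TitrationSeries.

    Columns: peak_id, ligand_total_uM, protein_total_uM, w1_ppm (15N),
    w2_ppm (1H).  One row per peak per titration point.
    """
    df = _read_delimited(path, _TITRATION_COLS)
    points = []
    for (lig, prot), grp in df.groupby(["ligand_total_uM", "protein_total_uM"]):
        if grp["peak_id"].duplicated().any():
            dup_ids = grp.loc[grp["peak_id"].duplicated(), "peak_id"].tolist()
            raise ValueError(f"{path}: duplicate peak id(s) {dup_ids} at ligand_total={lig}")
        shifts = {str(r.peak_id): (float(r.w2_ppm), float(r.w1_ppm))
                  for r in grp.itertuples()}
        points.append(TitrationPoint(protein_total=float(prot), ligand_total=float(lig),
                                     shifts=shifts))
    return TitrationSeries(points=points)


def write_titration_table(series: TitrationSeries, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for pt in series.points:
        for pid, (dH, dN) in sorted(pt.shifts.items()):
            rows.append({"peak_id": pid, "ligand_total_uM": pt.ligand_total,
                         "protein_total_uM": pt.protein_total,
                         "w1_ppm": dN, "w2_ppm": dH})
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_sparky_peaklist(path: str | Path) -> PeakTable:
    """Read a Sparky "Assignment w1 w2 Data Height" peak list."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split()
    if "Assignment" not in header or "w1" not in header or "w2" not in header:
        raise ValueError(f"{path}: expected header with Assignment, w1, w2; got {lines[0]!r}")
    if "Height" not in header:
        raise ValueError(f"{path}: missing Height column in header {lines[0]!r}")
    assignments, w1, w2, heights = [], [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
        try:
            w1.append(float(parts[1]))
            w2.append(float(parts[2]))
            heights.append(float(parts[-1]))
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value on line {lineno}: {line!r}") from exc
        assignments.append(parts[0])
    return PeakTable(assignments=assignments, w1=np.array(w1), w2=np.array(w2),
                     heights=np.array(heights))


def write_report(payload: dict, json_path: str | Path,
                 text_path: str | Path | None = None) -> None:
    """Write a result report as JSON (and optionally a flat key: value text)."""
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if text_path is not None:
        lines = [f"{k}: {v}" for k, v in _flatten(payload)]
        Path(text_path).write_text("\n".join(lines) + "\n")


def _flatten(d: dict, prefix: str = ""):
    for k, v in sorted(d.items()):
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, key + ".")
        else:
            yield key, v
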