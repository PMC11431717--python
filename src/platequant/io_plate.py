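"""Reading, validating and writing plate-reader runs and plate layouts.

The canonical interchange format is tidy CSV with columns
``well,time_min,od`` (one row per reading).  A wide dialect — one ``time_min``
column plus one column per well — is accepted for convenience and produces an
identical :class:`PlateRun`.  Layouts are CSV tables mapping wells to sample,
dilution exponent, replicate and role.

Times are minutes from run start, stored exactly as parsed; no sampling grid
is assumed.  OD readings are used as-is (no pathlength correction); blank
handling is downstream.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, LayoutError

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

LAYOUT_ROLES = ("sample", "blank", "reference")


@dataclass
class WellSeries:
    """One well's OD time series.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"A1"``.
    times : ndarray
        Minutes from run start, strictly increasing.
    od : ndarray
        Optical density at 660 nm, same length as ``times``, finite and >= 0.
    """

    well_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.od.ndim != 1:
            raise DataError(f"well {self.well_id}: times and od must be 1-D")
        if len(self.times) != len(self.od):
            raise DataError(f"well {self.well_id}: times and od lengths differ")
        if len(self.times) < 2:
            raise DataError(f"well {self.well_id}: need at least 2 readings")
        if not np.all(np.diff(self.times) > 0):
            raise DataError(f"well {self.well_id}: times not strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise DataError(f"well {self.well_id}: non-finite OD reading")
        if np.any(self.od < 0):
            raise DataError(f"well {self.well_id}: negative OD reading")

    def __len__(self):
        return len(self.times)


@dataclass
class PlateRun:
    """A validated collection of well series sharing one time grid."""

    wells: dict[str, WellSeries]
    interval_minutes: float = 0.0
    duration_minutes: float = 0.0
    wavelength_nm: float = 660.0
    temperature_C: Optional[float] = None

    def __post_init__(self):
        if not self.wells:
            raise DataError("plate run contains no wells")
        grids = [ws.times for ws in self.wells.values()]
        ref = grids[0]
        for ws in self.wells.values():
            if len(ws.times) != len(ref) or not np.array_equal(ws.times, ref):
                raise DataError(
                    f"well {ws.well_id}: time grid differs from other wells"
                )
        diffs = np.diff(ref)
        if self.interval_minutes == 0.0:
            self.interval_minutes = float(np.median(diffs))
        if self.duration_minutes == 0.0:
            self.duration_minutes = float(ref[-1])

    @property
    def times(self) -> np.ndarray:
        return next(iter(self.wells.values())).times

    def __contains__(self, well_id):
        return well_id in self.wells

    def __getitem__(self, well_id) -> WellSeries:
        return self.wells[well_id]


@dataclass
class LayoutEntry:
    well: str
    sample_id: str
    dilution_exponent: Optional[int]
    replicate: int
    role: str = "sample"
    strain_preset: Optional[str] = None
    inoculum_volume_uL: float = 5.0


@dataclass
class PlateLayout:
    """Mapping of wells to sample/dilution/replicate/role metadata."""

    entries: dict[str, LayoutEntry] = field(default_factory=dict)

    def __post_init__(self):
        for well, e in self.entries.items():
            if e.role not in LAYOUT_ROLES:
                raise LayoutError(
                    f"well {well}: unknown role {e.role!r}; allowed roles: "
                    + ", ".join(LAYOUT_ROLES)
                )
            if e.role == "blank" and e.dilution_exponent is not None:
                raise LayoutError(f"well {well}: blank wells carry no dilution_exponent")
            if e.dilution_exponent is not None and e.dilution_exponent > 0:
                raise LayoutError(
                    f"well {well}: dilution_exponent must be <= 0 "
                    f"(got {e.dilution_exponent})"
                )
            if not e.inoculum_volume_uL > 0:
                raise LayoutError(f"well {well}: inoculum_volume_uL must be > 0")

    def __contains__(self, well_id):
        return well_id in self.entries

    def __getitem__(self, well_id) -> LayoutEntry:
        return self.entries[well_id]

    def wells_for(self, sample_id: str, role: str = "sample") -> list[LayoutEntry]:
        return [
            e
            for e in self.entries.values()
            if e.sample_id == sample_id and e.role == role
        ]

    def sample_ids(self) -> list[str]:
        seen = []
        for e in self.entries.values():
            if e.role == "sample" and e.sample_id not in seen:
                seen.append(e.sample_id)
        return seen


def _run_from_long(df: pd.DataFrame) -> PlateRun:
    dup = df.duplicated(subset=["well", "time_min"])
    if dup.any():
        bad = df.loc[dup, "well"].iloc[0]
        raise DataError(f"duplicate (well, time_min) reading for well {bad}")
    wells = {}
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise DataError(f"well {well}: time_min not strictly increasing")
        wells[str(well)] = WellSeries(str(well), t, grp["od"].to_numpy(dtype=float))
    lengths = {len(ws) for ws in wells.values()}
    if len(lengths) > 1:
        raise DataError("ragged wells: series lengths differ across wells")
    return PlateRun(wells)


def read_plate_csv(path: str | os.PathLike) -> PlateRun:
    """Read a plate run from tidy long CSV (``well,time_min,od``) or from
    wide CSV (a time column plus one column per well).

    Both dialects yield identical :class:`PlateRun` structures.
    """
    # round_trip float parsing keeps write->read bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise FormatError(f"{path}: empty plate file")
    cols = list(df.columns)
    if {"well", "time_min", "od"}.issubset(cols):
        return _run_from_long(df[["well", "time_min", "od"]])
    # wide dialect: first column is time, remaining columns are wells
    time_col = next(
        (c for c in cols if str(c).lower() in ("time_min", "time", "minutes")), None
    )
    well_cols = [c for c in cols if c != time_col and _WELL_RE.match(str(c))]
    if time_col is None or not well_cols:
        raise FormatError(
            f"{path}: expected columns well,time_min,od (long) or a time column "
            "plus well columns like A1..H12 (wide)"
        )
    long = df.melt(
        id_vars=[time_col], value_vars=well_cols, var_name="well", value_name="od"
    ).rename(columns={time_col: "time_min"})
    return _run_from_long(long[["well", "time_min", "od"]])


def write_plate_csv(run: PlateRun, path: str | os.PathLike) -> None:
    """Write a run as tidy long CSV. Uses shortest-repr floats so a
    write/read round trip reproduces times and OD bit-identically."""
    with open(path, "w") as fh:
        fh.write("well,time_min,od\n")
        for well in sorted(run.wells):
            ws = run.wells[well]
            for t, od in zip(ws.times, ws.od):
                fh.write(f"{well},{float(t)!r},{float(od)!r}\n")


def read_layout(path: str | os.PathLike) -> PlateLayout:
    """Read a plate layout CSV with columns
    ``well,sample_id,dilution_exponent,replicate,role`` and optional
    ``strain_preset`` and ``inoculum_volume_uL``."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise LayoutError(f"{path}: empty layout file") from None
    if df.empty:
        raise LayoutError(f"{path}: layout has no rows")
    required = {"well", "sample_id", "dilution_exponent", "replicate", "role"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"{path}: missing layout columns: {sorted(missing)}")
    entries: dict[str, LayoutEntry] = {}
    for _, row in df.iterrows():
        well = str(row["well"])
        if well in entries:
            raise LayoutError(f"well {well} referenced twice in layout")
        exp = row["dilution_exponent"]
        exp = None if pd.isna(exp) else int(exp)
        vol = row.get("inoculum_volume_uL", 5.0)
        vol = 5.0 if pd.isna(vol) else float(vol)
        preset = row.get("strain_preset")
        preset = None if (preset is None or pd.isna(preset)) else str(preset)
        entries[well] = LayoutEntry(
            well=well,
            sample_id=str(row["sample_id"]),
            dilution_exponent=exp,
            replicate=int(row["replicate"]),
            role=str(row["role"]),
            strain_preset=preset,
            inoculum_volume_uL=vol,
        )
    return PlateLayout(entries)


def write_layout(layout: PlateLayout, path: str | os.PathLike) -> None:
    rows = []
    for e in layout.entries.values():
        rows.append(
            {
                "well": e.well,
                "sample_id": e.sample_id,
                "dilution_exponent": e.dilution_exponent,
                "replicate": e.replicate,
                "role": e.role,
                "strain_preset": e.strain_preset,
                "inoculum_volume_uL": e.inoculum_volume_uL,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class Finding:
    well: str
    code: str  # "ok" | "missing-from-layout" | "layout-without-data" | "info"
    message: str


def validate_run(run: PlateRun, layout: PlateLayout) -> list[Finding]:
    """Cross-check a run against a layout.  Never raises; returns findings
    for wells present in only one of the two, plus informational notes for
    blank wells.  Inputs are not mutated."""
    findings: list[Finding] = []
    for well in sorted(run.wells):
        if well not in layout:
            findings.append(
                Finding(well, "missing-from-layout", f"well {well} has data but no layout entry")
            )
        elif layout[well].role == "blank":
            findings.append(Finding(well, "info", f"well {well} is a blank"))
    for well in sorted(layout.entries):
        if well not in run:
            findings.append(
                Finding(well, "layout-without-data", f"well {well} in layout but absent from run")
            )
    return findings


def results_to_json(results: dict, path: str | os.PathLike) -> None:
    """Write an analysis result document (keyed by sample) as JSON,
    atomically (write-then-rename)."""
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def well_names(n: int) -> list[str]:
    """First ``n`` well identifiers: 96-well coordinates in row-major order
    (A1..A12, B1..) and, beyond one physical plate, generic W0097.. names
    (simulated multi-plate runs)."""
    rows = "ABCDEFGH"
    return [
        f"{rows[i // 12]}{i % 12 + 1}" if i < 96 else f"W{i + 1:04d}"
        for i in range(n)
    ]
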