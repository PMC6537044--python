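"""Data model and text I/O for screen plates, dose matrices, and tumor-growth tables.

The in-memory containers are thin dataclasses around :class:`pandas.DataFrame`
(long-format well tables, growth tables) or :class:`numpy.ndarray` grids
(dose matrices).  All readers consume plain delimited text as exported by
plate readers / LIMS spreadsheets; all writers round-trip losslessly for
text-representable values.

Conventions
-----------
* Plate coordinates are 1-based; alphanumeric well names (``A01`` .. ``P24``)
  are accepted on input and normalized to ``(row, col)`` integers.
* Viability is stored internally as a fraction in ``[0, 1]`` relative to the
  double-vehicle anchor; percent inputs are converted at the boundary.
* Missing wells are tolerated (and excluded from robust statistics
  downstream), never imputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROLE_COMPOUND",
    "ROLE_VEHICLE",
    "ROLE_ANCHOR",
    "ARM_SINGLE",
    "ARM_COMBO",
    "PLATE_COLUMNS",
    "PlateSet",
    "DoseMatrix",
    "GrowthTable",
    "well_to_rowcol",
    "rowcol_to_well",
    "read_plate_table",
    "read_dose_matrix",
    "read_growth_table",
]

ROLE_COMPOUND = "compound"
ROLE_VEHICLE = "vehicle_control"
ROLE_ANCHOR = "anchor_control"
VALID_ROLES = frozenset({ROLE_COMPOUND, ROLE_VEHICLE, ROLE_ANCHOR})

ARM_SINGLE = "single"
ARM_COMBO = "combo_with_anchor"
VALID_ARMS = frozenset({ARM_SINGLE, ARM_COMBO})

#: canonical long-format column order for plate tables
PLATE_COLUMNS = [
    "plate_id",
    "replicate",
    "row",
    "col",
    "compound_id",
    "role",
    "arm",
    "concentration_um",
    "signal",
]

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


def well_to_rowcol(well: str) -> tuple[int, int]:
    """Convert an alphanumeric well name (``A01``) to 1-based ``(row, col)``."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"unrecognized well name: {well!r}")
    row = ord(m.group(1).upper()) - ord("A") + 1
    col = int(m.group(2))
    if col < 1:
        raise ValueError(f"well column must be >= 1: {well!r}")
    return row, col


def rowcol_to_well(row: int, col: int) -> str:
    """Convert 1-based ``(row, col)`` to an alphanumeric well name."""
    if not (1 <= row <= 16):
        raise ValueError(f"row {row} outside A..P")
    return f"{chr(ord('A') + row - 1)}{col:02d}"


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class PlateParseError(ValueError):
    """A row of an input table failed to parse (message carries line numbers)."""


@dataclass
class PlateSet:
    """A set of screening plates in long format.

    Parameters
    ----------
    wells
        Long-format table with the :data:`PLATE_COLUMNS` columns.  Control
        wells carry NaN ``compound_id``/``concentration_um``.
    n_rows, n_cols
        Plate geometry (16 x 24 for a 384-well plate).
    min_vehicle_wells
        Minimum number of vehicle-control wells required per
        (plate, replicate); screens rely on these for QC even though the
        robust scoring chain references treated wells.
    """

    wells: pd.DataFrame
    n_rows: int = 16
    n_cols: int = 24
    min_vehicle_wells: int = 8

    def __post_init__(self) -> None:
        df = self.wells
        missing = [c for c in PLATE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"plate table missing column(s): {', '.join(missing)}")
        self.wells = df = df.reset_index(drop=True)
        self._validate(df)

    def _validate(self, df: pd.DataFrame) -> None:
        bad_role = set(df["role"].unique()) - VALID_ROLES
        if bad_role:
            raise ValueError(f"unknown well role(s): {sorted(bad_role)}")
        bad_arm = set(df["arm"].unique()) - VALID_ARMS
        if bad_arm:
            raise ValueError(f"unknown arm(s): {sorted(bad_arm)}")
        if (df["signal"] < 0).any():
            n = int((df["signal"] < 0).sum())
            raise ValueError(f"{n} well(s) have negative signal")
        out_r = ~df["row"].between(1, self.n_rows)
        out_c = ~df["col"].between(1, self.n_cols)
        if out_r.any() or out_c.any():
            raise ValueError(
                f"{int((out_r | out_c).sum())} well(s) outside the "
                f"{self.n_rows}x{self.n_cols} geometry"
            )
        key = ["plate_id", "replicate", "row", "col"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise ValueError(
                f"duplicate well address {tuple(first)} "
                f"({int(dup.sum())} duplicated well(s) in total)"
            )
        veh = df[df["role"] == ROLE_VEHICLE]
        if veh["compound_id"].notna().any() or veh["concentration_um"].notna().any():
            raise ValueError("vehicle_control wells must not carry compound_id/concentration")
        counts = veh.groupby(["plate_id", "replicate"]).size()
        all_plates = df.groupby(["plate_id", "replicate"]).size()
        short = all_plates.index.difference(counts[counts >= self.min_vehicle_wells].index)
        if self.min_vehicle_wells > 0 and len(short) > 0:
            raise ValueError(
                f"plate/replicate {list(short)[:3]} carry fewer than "
                f"{self.min_vehicle_wells} vehicle_control wells"
            )

    @property
    def replicates(self) -> list[int]:
        return sorted(self.wells["replicate"].unique())

    @property
    def plate_ids(self) -> list:
        return sorted(self.wells["plate_id"].unique())

    def __len__(self) -> int:
        return len(self.wells)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateSet):
            return NotImplemented
        a = self.wells[PLATE_COLUMNS].sort_values(PLATE_COLUMNS[:4]).reset_index(drop=True)
        b = other.wells[PLATE_COLUMNS].sort_values(PLATE_COLUMNS[:4]).reset_index(drop=True)
        return (self.n_rows, self.n_cols) == (other.n_rows, other.n_cols) and a.equals(b)

    def write_csv(self, path: str | Path) -> None:
        out = self.wells[PLATE_COLUMNS].copy()
        out.insert(2, "well", [rowcol_to_well(r, c) for r, c in zip(out["row"], out["col"])])
        out.drop(columns=["row", "col"]).to_csv(path, index=False, float_format="%.17g")


def read_plate_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
    *,
    n_rows: int = 16,
    n_cols: int = 24,
    min_vehicle_wells: int = 8,
    sep: str = ",",
) -> PlateSet:
    """Read a long-format plate table from delimited text.

    ``schema`` maps canonical column names to the file's column names, e.g.
    ``{"signal": "lum"}``.  Well position may be given either as a ``well``
    column (``A01``) or as ``row``/``col`` integer columns.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    schema = schema or {}
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)

    if "well" in df.columns and not {"row", "col"} <= set(df.columns):
        rc = [well_to_rowcol(w) for w in df["well"]]
        df["row"] = [r for r, _ in rc]
        df["col"] = [c for _, c in rc]
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"plate table {path} missing column(s): {', '.join(missing)} "
            f"(schema mapping: {schema or 'none'})"
        )

    for col in ("signal", "concentration_um"):
        # python float() is correctly rounded, so text round-trips bit-exactly
        parsed = np.empty(len(df))
        bad_lines = []
        for i, x in enumerate(df[col]):
            if x is None or (isinstance(x, float) and np.isnan(x)) or str(x).strip() == "":
                parsed[i] = np.nan
                continue
            try:
                parsed[i] = float(x)
            except ValueError:
                bad_lines.append(i + 2)  # +2: header + 1-based
        if bad_lines:
            raise PlateParseError(
                f"non-numeric {col} at line(s) {bad_lines[:5]}"
                + (" ..." if len(bad_lines) > 5 else "")
            )
        df[col] = parsed
    for col in ("row", "col", "replicate"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    # empty-string compound ids on control rows -> NaN
    df["compound_id"] = df["compound_id"].replace("", np.nan)
    return PlateSet(df[PLATE_COLUMNS], n_rows=n_rows, n_cols=n_cols,
                    min_vehicle_wells=min_vehicle_wells)


@dataclass
class DoseMatrix:
    """A two-drug checkerboard viability grid.

    ``viability[i, j]`` is the fraction of double-vehicle viability observed
    at ``doses_a[i]`` of drug A combined with ``doses_b[j]`` of drug B.  Both
    ladders ascend and include the zero dose; the ``(0, 0)`` cell is the
    normalization anchor and equals 1 by construction.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    replicate_id: int = 1

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if d.ndim != 1 or len(d) < 2:
                raise ValueError(f"{name} must be a 1-D ladder with >= 2 doses")
            if not np.all(np.diff(d) > 0):
                raise ValueError(f"{name} must strictly ascend")
            if d[0] != 0:
                raise ValueError(f"{name} must start at the zero dose")
        if self.viability.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError(
                f"viability grid {self.viability.shape} does not match ladders "
                f"({len(self.doses_a)}, {len(self.doses_b)})"
            )
        if not np.isclose(self.viability[0, 0], 1.0, atol=1e-6):
            raise ValueError("missing (0,0) anchor: viability at double vehicle must be 1")

    @property
    def inhibition(self) -> np.ndarray:
        """Fraction affected, ``1 - viability``."""
        return 1.0 - self.viability

    def margin_a(self) -> tuple[np.ndarray, np.ndarray]:
        """Drug-A single-agent ladder: (doses_a, viability at dose_b = 0)."""
        return self.doses_a, self.viability[:, 0]

    def margin_b(self) -> tuple[np.ndarray, np.ndarray]:
        return self.doses_b, self.viability[0, :]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DoseMatrix):
            return NotImplemented
        return (
            (self.drug_a, self.drug_b, self.replicate_id)
            == (other.drug_a, other.drug_b, other.replicate_id)
            and np.array_equal(self.doses_a, other.doses_a)
            and np.array_equal(self.doses_b, other.doses_b)
            and np.allclose(self.viability, other.viability, atol=1e-12)
        )

    def to_long(self) -> pd.DataFrame:
        ia, ib = np.meshgrid(np.arange(len(self.doses_a)), np.arange(len(self.doses_b)),
                             indexing="ij")
        return pd.DataFrame(
            {
                "dose_a": self.doses_a[ia.ravel()],
                "dose_b": self.doses_b[ib.ravel()],
                "viability": self.viability.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        """Write as a grid: row index = doses_a, column header = doses_b."""
        pd.DataFrame(self.viability, index=self.doses_a, columns=self.doses_b).to_csv(
            path, index_label="dose_a\\dose_b", float_format="%.17g"
        )


def read_dose_matrix(
    path: str | Path,
    *,
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
    percent: bool = False,
    replicate_id: int = 1,
) -> DoseMatrix:
    """Read a dose matrix from grid or long-format CSV.

    Grid format: first column holds the drug-A ladder, header row the drug-B
    ladder.  Long format: columns ``dose_a, dose_b, viability``.  With
    ``percent=True``, values are interpreted as percent viability and
    converted to fractions.
    """
    head = pd.read_csv(path, nrows=1)
    if {"dose_a", "dose_b", "viability"} <= set(head.columns):
        long = pd.read_csv(path, float_precision="round_trip")
        piv = long.pivot(index="dose_a", columns="dose_b", values="viability")
        if piv.isna().any().any():
            raise ValueError(f"ragged dose matrix in {path}: missing cells after pivot")
        doses_a, doses_b = piv.index.to_numpy(float), piv.columns.to_numpy(float)
        grid = piv.to_numpy(float)
    else:
        raw = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if raw.isna().any().any():
            raise ValueError(f"ragged dose matrix grid in {path}")
        doses_a = raw.index.to_numpy(float)
        doses_b = raw.columns.to_numpy(float)
        grid = raw.to_numpy(float)
    if percent:
        grid = grid / 100.0
    return DoseMatrix(drug_a, drug_b, doses_a, doses_b, grid, replicate_id=replicate_id)


GROWTH_COLUMNS = ["animal_id", "group", "day", "volume_mm3"]
GROUP_CONTROL = "control"
GROUP_TREATED = "treated"


@dataclass
class GrowthTable:
    """Longitudinal xenograft tumor volumes.

    Day 1 is randomization (treatment start); every animal must carry a
    day-1 baseline, which anchors the relative tumor volume (RTV).
    """

    records: pd.DataFrame
    baseline_day: int = 1

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"growth table missing column(s): {', '.join(missing)}")
        self.records = df = df.reset_index(drop=True)
        if (df["volume_mm3"] <= 0).any():
            raise ValueError("tumor volumes must be positive")
        groups = set(df["group"].unique())
        if not groups <= {GROUP_CONTROL, GROUP_TREATED}:
            raise ValueError(f"groups must be {{control, treated}}, got {sorted(groups)}")
        if groups != {GROUP_CONTROL, GROUP_TREATED}:
            raise ValueError("both control and treated groups must be non-empty")
        has_baseline = df[df["day"] == self.baseline_day]["animal_id"].unique()
        orphans = set(df["animal_id"].unique()) - set(has_baseline)
        if orphans:
            raise ValueError(
                f"animal(s) missing day-{self.baseline_day} baseline: {sorted(orphans)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrowthTable):
            return NotImplemented
        key = ["animal_id", "day"]
        a = self.records[GROWTH_COLUMNS].sort_values(key).reset_index(drop=True)
        b = other.records[GROWTH_COLUMNS].sort_values(key).reset_index(drop=True)
        return a.equals(b)

    def write_csv(self, path: str | Path) -> None:
        self.records[GROWTH_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_growth_table(path: str | Path, *, baseline_day: int = 1) -> GrowthTable:
    df = pd.read_csv(path, float_precision="round_trip")
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    df["volume_mm3"] = pd.to_numeric(df["volume_mm3"], errors="raise")
    return GrowthTable(df[GROWTH_COLUMNS], baseline_day=baseline_day)
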