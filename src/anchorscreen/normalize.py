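"""Plate normalization: log transform, B-score median polish, robust Z-scores.

The scoring chain for an anchor screen is::

    raw signal --ln--> log_signal --median polish--> bscore --robust Z--> rz_score

* The **B-score** of a well is the residual of a two-way (row x column)
  median polish of its plate's log-signals, divided by ``1.4826 x MAD`` of
  the plate residuals.  Median polish is exact on additive row+column
  models, so positional artifacts (edge effects, dispenser gradients)
  vanish from the scores.
* The **robust Z-score** (RZ) of a well is ``(value - median) /
  (1.4826 x MAD)`` over a reference population — by default all
  compound-treated wells of the same arm, plate and replicate, scored per
  replicate separately.  The reference ``median_ref``/``mad_ref`` are
  recorded next to every score so the percent-proliferation back-transform
  is self-contained.

The 1.4826 factor makes the MAD a consistent estimate of the standard
deviation under Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plates import PlateSet, ROLE_COMPOUND

__all__ = [
    "MAD_CONSISTENCY",
    "SCORE_COLUMNS",
    "mad",
    "log_transform",
    "median_polish",
    "MedianPolishResult",
    "bscore",
    "robust_zscore",
    "score_plates",
]

#: MAD-to-sigma consistency factor for Gaussian data (1/Phi^-1(3/4))
MAD_CONSISTENCY = 1.4826

#: columns a fully scored table carries on top of the plate columns
SCORE_COLUMNS = ["log_signal", "bscore", "rz_score", "median_ref", "mad_ref"]


def mad(x, *, nan_policy: str = "omit") -> float:
    """Raw median absolute deviation from the median (no consistency scaling)."""
    x = np.asarray(x, dtype=float)
    if nan_policy == "omit":
        x = x[~np.isnan(x)]
    if x.size == 0:
        return math.nan
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def log_transform(plates: PlateSet, *, zero_policy: str = "error") -> pd.DataFrame:
    """Return a score table with ``log_signal = ln(signal)`` filled.

    ``zero_policy`` governs nonpositive signals: ``"error"`` (default)
    raises; ``"floor"`` replaces them with half the smallest positive signal
    on the same plate/replicate before taking logs.
    """
    df = plates.wells.copy()
    nonpos = df["signal"] <= 0
    if nonpos.any():
        if zero_policy == "error":
            raise ValueError(
                f"{int(nonpos.sum())} nonpositive signal(s); set zero_policy='floor' "
                "to floor them at half the smallest positive plate value"
            )
        if zero_policy != "floor":
            raise ValueError(f"unknown zero_policy: {zero_policy!r}")
        floor = (
            df[~nonpos]
            .groupby(["plate_id", "replicate"])["signal"]
            .min()
            .rename("floor_")
        )
        df = df.join(floor, on=["plate_id", "replicate"])
        df.loc[nonpos, "signal"] = df.loc[nonpos, "floor_"] * 0.5
        df = df.drop(columns="floor_")
    df["log_signal"] = np.log(df["signal"])
    return df


@dataclass
class MedianPolishResult:
    """Decomposition ``matrix = grand + row_effects + col_effects + residuals``."""

    grand: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool


def median_polish(
    matrix: np.ndarray, *, max_iter: int = 100, tol: float = 1e-9
) -> MedianPolishResult:
    """Tukey two-way median polish of a 2-D matrix (NaN = missing well).

    Alternately sweeps row medians and column medians out of the residuals,
    accumulating them into row/column effects and the grand effect, until
    the change in the sum of absolute residuals falls below ``tol`` or
    ``max_iter`` sweeps have run.  Medians of even-length vectors are
    midpoints; missing cells are ignored.
    """
    z = np.array(matrix, dtype=float)
    if z.ndim != 2:
        raise ValueError("median_polish expects a 2-D matrix")
    nr, nc = z.shape
    grand = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    # effects are only estimable for rows/columns carrying data; fully
    # missing ones keep effect 0 and are flagged NaN by the caller
    has_row = ~np.all(np.isnan(z), axis=1)
    has_col = ~np.all(np.isnan(z), axis=0)
    prev_abs = np.nansum(np.abs(z))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rmed = np.zeros(nr)
        rmed[has_row] = np.nanmedian(z[has_row, :], axis=1)
        z -= rmed[:, None]
        row_eff += rmed
        cmed_of_row = np.median(row_eff[has_row]) if has_row.any() else 0.0
        row_eff[has_row] -= cmed_of_row
        grand += cmed_of_row

        cmed = np.zeros(nc)
        cmed[has_col] = np.nanmedian(z[:, has_col], axis=0)
        z -= cmed[None, :]
        col_eff += cmed
        rmed_of_col = np.median(col_eff[has_col]) if has_col.any() else 0.0
        col_eff[has_col] -= rmed_of_col
        grand += rmed_of_col

        cur_abs = np.nansum(np.abs(z))
        if abs(prev_abs - cur_abs) < tol:
            converged = True
            break
        prev_abs = cur_abs
    return MedianPolishResult(grand, row_eff, col_eff, z, it, converged)


def bscore(
    scores: pd.DataFrame,
    *,
    include_controls: bool = False,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Fill the ``bscore`` column: per (plate, replicate) median polish.

    The polish is run on compound wells only by default (controls are
    excluded, mirroring a screen whose control layout is not positionally
    balanced).  Wells sitting on rows/columns that carried no polish data
    (e.g. control-only columns) have no estimable positional effect and get
    a NaN B-score — excluded rather than imputed.
    """
    df = scores.copy()
    if "log_signal" not in df.columns:
        raise ValueError("run log_transform first: no log_signal column")
    df["bscore"] = np.nan
    n_rows = int(df["row"].max())
    n_cols = int(df["col"].max())
    for (pid, rep), grp in df.groupby(["plate_id", "replicate"], sort=True):
        fit_grp = grp if include_controls else grp[grp["role"] == ROLE_COMPOUND]
        if fit_grp["row"].nunique() < 2 or fit_grp["col"].nunique() < 2:
            raise ValueError(
                f"plate {pid!r} replicate {rep}: median polish undefined with fewer "
                "than 2 distinct rows and columns of compound wells"
            )
        mat = np.full((n_rows, n_cols), np.nan)
        mat[fit_grp["row"] - 1, fit_grp["col"] - 1] = fit_grp["log_signal"].to_numpy()
        res = median_polish(mat, max_iter=max_iter, tol=tol)
        scale = MAD_CONSISTENCY * mad(res.residuals.ravel())
        if not np.isfinite(scale) or scale <= 0:
            raise ValueError(
                f"plate {pid!r} replicate {rep}: degenerate residual MAD "
                "(constant plate?); B-score undefined — returning raw residuals "
                "requires nonzero spread"
            )
        fitted = res.grand + res.row_effects[grp["row"] - 1] + res.col_effects[grp["col"] - 1]
        est = (~np.all(np.isnan(mat), axis=1))[grp["row"] - 1] & (
            ~np.all(np.isnan(mat), axis=0))[grp["col"] - 1]
        b = (grp["log_signal"].to_numpy() - fitted) / scale
        df.loc[grp.index, "bscore"] = np.where(est, b, np.nan)
    return df


def robust_zscore(values, reference=None):
    """Robust Z-scores ``(v - median) / (1.4826 x MAD)``.

    ``reference`` supplies the population whose median/MAD are used (default:
    ``values`` itself).  Returns ``(rz, median_ref, mad_ref)`` where
    ``mad_ref`` is the raw MAD before consistency scaling.

    Raises if the reference MAD is zero (degenerate population).
    """
    values = np.asarray(values, dtype=float)
    ref = values if reference is None else np.asarray(reference, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("robust_zscore: empty reference population")
    med = float(np.median(ref))
    m = mad(ref)
    if m == 0:
        raise ValueError(
            f"robust_zscore: reference population of size {ref.size} has zero MAD"
        )
    return (values - med) / (MAD_CONSISTENCY * m), med, m


def score_plates(
    plates: PlateSet,
    *,
    scope: str = "plate",
    mad_scope: str = "single",
    zero_policy: str = "error",
    include_controls_in_polish: bool = False,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Run the full scoring chain and return the scored table.

    Chain: natural log, per-(plate, replicate) B-score, then robust Z over
    the compound-treated B-scores of the same arm and replicate.  With
    ``scope="plate"`` (default) the RZ reference is per plate; with
    ``scope="global"`` it pools all plates of an arm/replicate.
    ``mad_scope="pooled"`` replaces each reference MAD by the median of the
    per-plate MADs of the same arm/replicate (an alternative reading of the
    "median MAD" convention for multi-plate screens).

    The returned frame carries :data:`SCORE_COLUMNS`; ``rz_score`` is NaN
    for control wells (they are not part of the reference population).
    """
    df = log_transform(plates, zero_policy=zero_policy)
    df = bscore(df, include_controls=include_controls_in_polish, max_iter=max_iter, tol=tol)
    df["rz_score"] = np.nan
    df["median_ref"] = np.nan
    df["mad_ref"] = np.nan

    treated = df["role"] == ROLE_COMPOUND
    if scope == "plate":
        group_cols = ["arm", "replicate", "plate_id"]
    elif scope == "global":
        group_cols = ["arm", "replicate"]
    else:
        raise ValueError(f"unknown scope: {scope!r}")

    pooled_mads: dict = {}
    if mad_scope == "pooled":
        per_plate = (
            df[treated]
            .groupby(["arm", "replicate", "plate_id"])["bscore"]
            .apply(lambda v: mad(v))
        )
        pooled_mads = per_plate.groupby(level=["arm", "replicate"]).median().to_dict()
    elif mad_scope != "single":
        raise ValueError(f"unknown mad_scope: {mad_scope!r}")

    for key, grp in df[treated].groupby(group_cols, sort=True):
        vals = grp["bscore"].to_numpy()
        rz, med, m = robust_zscore(vals)
        if mad_scope == "pooled":
            m = pooled_mads[(key[0], key[1])]
            if m == 0:
                raise ValueError(f"pooled MAD is zero for arm/replicate {key[:2]}")
            rz = (vals - med) / (MAD_CONSISTENCY * m)
        df.loc[grp.index, "rz_score"] = rz
        df.loc[grp.index, "median_ref"] = med
        df.loc[grp.index, "mad_ref"] = m
    return df
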