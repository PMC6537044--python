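"""Synthetic-data generators with planted ground truth for every pipeline input.

Three generators emulate the study designs the pipeline consumes:

* :func:`simulate_screen` — a 384-well anchor screen: a compound library
  plated with vehicle- and anchor-control columns, run in duplicate in two
  arms (compound alone / compound + anchor), with additive row/column/plate
  positional artifacts and log-normal measurement noise.  A fraction of
  compounds are planted actives (log-scale viability drop); a fraction are
  potentiated by the anchor (additional drop in the combo arm only).  The
  returned truth table carries every planted effect.
* :func:`simulate_matrix` — two-drug checkerboards from true Hill curves
  under Loewe-additive, Bliss-independent, synergistic or antagonistic
  regimes.  The Loewe-additive surface is built by an independent fine-grid
  numeric inversion (no code shared with the analysis solver, so it can
  serve as its oracle).
* :func:`simulate_growth` — exponential xenograft growth with the treated
  rate chosen so the expected endpoint TGI equals a target inhibition.

All generators are pure functions of their spec (same spec, same seed ->
bit-identical output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .plates import (
    ARM_COMBO,
    ARM_SINGLE,
    GROUP_CONTROL,
    GROUP_TREATED,
    GROWTH_COLUMNS,
    PLATE_COLUMNS,
    ROLE_ANCHOR,
    ROLE_COMPOUND,
    ROLE_VEHICLE,
    DoseMatrix,
    GrowthTable,
    PlateSet,
)

__all__ = [
    "ScreenSimSpec",
    "MatrixSimSpec",
    "GrowthSimSpec",
    "simulate_screen",
    "simulate_matrix",
    "simulate_growth",
]


@dataclass(frozen=True)
class ScreenSimSpec:
    """Conditions for a simulated anchor screen.

    Effects are additive shifts on the natural-log signal scale.  Because a
    B-scored well's robust Z is (to first order) its log-scale shift divided
    by ``noise_sd``, planting an effect of ``rz * noise_sd`` plants an
    expected RZ-score of ``rz``.  Default effect distributions are stated in
    those RZ units: actives at Normal(-6, 1) clipped above at -4, anchor
    potentiation at Normal(-8, 3) clipped above at -4.
    """

    n_compounds: int = 1200
    n_rows: int = 16
    n_cols: int = 24
    n_replicates: int = 2
    vehicle_col: int = 23
    anchor_col: int = 24
    active_fraction: float = 0.05
    active_rz: tuple[float, float, float] = (-6.0, 1.0, -4.0)  # (loc, scale, upper clip)
    potentiation_fraction: float = 0.03
    potentiation_rz: tuple[float, float, float] = (-8.0, 3.0, -4.0)
    anchor_log_effect: float = -0.1
    base_log_signal: float = math.log(1.0e6)
    plate_offset_sd: float = 0.1
    row_gradient: float = 0.01   # log units per row step
    col_gradient: float = 0.005  # log units per column step
    noise_sd: float = 0.05       # log-scale Gaussian sd (~5% CV)
    contamination_fraction: float = 0.0  # wells drawn at 5x noise sd
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("active_fraction", "potentiation_fraction", "contamination_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.vehicle_col == self.anchor_col:
            raise ValueError("control layout collision: vehicle and anchor share a column")
        for c in (self.vehicle_col, self.anchor_col):
            if not 1 <= c <= self.n_cols:
                raise ValueError(f"control column {c} outside plate geometry")

    @property
    def compound_cols(self) -> list[int]:
        return [c for c in range(1, self.n_cols + 1)
                if c not in (self.vehicle_col, self.anchor_col)]


def _clipped_normal(rng, loc, scale, upper, size):
    return np.minimum(rng.normal(loc, scale, size), upper)


def simulate_screen(spec: ScreenSimSpec) -> tuple[PlateSet, pd.DataFrame]:
    """Generate an anchor screen and its planted-truth table.

    Returns ``(plates, truth)``; ``truth`` has one row per compound with
    ``is_active``, ``is_potentiated`` and the planted log-scale and RZ-unit
    effect sizes (zero for nulls).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    compounds = np.array([f"C{i:04d}" for i in range(1, n + 1)])

    is_active = rng.random(n) < spec.active_fraction
    loc, scale, upper = spec.active_rz
    active_rz = np.where(is_active, _clipped_normal(rng, loc, scale, upper, n), 0.0)
    is_pot = rng.random(n) < spec.potentiation_fraction
    loc, scale, upper = spec.potentiation_rz
    pot_rz = np.where(is_pot, _clipped_normal(rng, loc, scale, upper, n), 0.0)
    active_eff = active_rz * spec.noise_sd
    pot_eff = pot_rz * spec.noise_sd

    cols = np.array(spec.compound_cols)
    capacity = spec.n_rows * len(cols)
    n_plates = math.ceil(n / capacity)
    # row-major layout: compound i -> plate, row, col (fixed across arms/reps)
    idx = np.arange(n)
    plate_no = idx // capacity
    within = idx % capacity
    c_row = within // len(cols) + 1
    c_col = cols[within % len(cols)]

    r_center = (spec.n_rows + 1) / 2.0
    c_center = (spec.n_cols + 1) / 2.0

    frames = []
    for arm in (ARM_SINGLE, ARM_COMBO):
        for rep in range(1, spec.n_replicates + 1):
            for p in range(n_plates):
                pid = f"{'S' if arm == ARM_SINGLE else 'A'}{p + 1:02d}"
                offset = rng.normal(0.0, spec.plate_offset_sd)
                sel = plate_no == p
                rows_c = c_row[sel]
                cols_c = c_col[sel]
                # control wells: full vehicle and anchor columns
                ctrl_rows = np.arange(1, spec.n_rows + 1)
                all_rows = np.concatenate([rows_c, ctrl_rows, ctrl_rows])
                all_cols = np.concatenate([
                    cols_c,
                    np.full(spec.n_rows, spec.vehicle_col),
                    np.full(spec.n_rows, spec.anchor_col),
                ])
                eff = np.concatenate([
                    active_eff[sel]
                    + (spec.anchor_log_effect + pot_eff[sel] if arm == ARM_COMBO else 0.0),
                    np.zeros(spec.n_rows),
                    np.full(spec.n_rows, spec.anchor_log_effect),
                ])
                noise_scale = np.full(all_rows.size, spec.noise_sd)
                if spec.contamination_fraction > 0:
                    # heavy-tailed contamination stress-tests the robust chain
                    bad = rng.random(all_rows.size) < spec.contamination_fraction
                    noise_scale[bad] *= 5.0
                log_sig = (
                    spec.base_log_signal
                    + offset
                    + spec.row_gradient * (all_rows - r_center)
                    + spec.col_gradient * (all_cols - c_center)
                    + eff
                    + rng.normal(0.0, 1.0, all_rows.size) * noise_scale
                )
                frames.append(pd.DataFrame({
                    "plate_id": pid,
                    "replicate": rep,
                    "row": all_rows,
                    "col": all_cols,
                    "compound_id": np.concatenate([
                        compounds[sel], np.full(2 * spec.n_rows, np.nan, dtype=object)]),
                    "role": np.concatenate([
                        np.full(rows_c.size, ROLE_COMPOUND),
                        np.full(spec.n_rows, ROLE_VEHICLE),
                        np.full(spec.n_rows, ROLE_ANCHOR)]),
                    "arm": arm,
                    "concentration_um": np.concatenate([
                        np.full(rows_c.size, 10.0), np.full(2 * spec.n_rows, np.nan)]),
                    "signal": np.exp(log_sig),
                }))
    wells = pd.concat(frames, ignore_index=True)[PLATE_COLUMNS]
    truth = pd.DataFrame({
        "compound_id": compounds,
        "is_active": is_active,
        "active_rz": active_rz,
        "active_log_effect": active_eff,
        "is_potentiated": is_pot,
        "potentiation_rz": pot_rz,
        "potentiation_log_effect": pot_eff,
    })
    return PlateSet(wells, n_rows=spec.n_rows, n_cols=spec.n_cols), truth


@dataclass(frozen=True)
class MatrixSimSpec:
    """Conditions for a simulated two-drug checkerboard.

    ``hill_a``/``hill_b`` are true single-agent curves as
    ``(top, bottom, ic50, hill)`` on the viability scale.  Dose ladders
    default to the validation design: a two-fold serial dilution from
    10 umol/L plus the zero dose.  ``interaction_strength`` is the planted
    inhibition perturbation (fraction) applied at interior cells in the
    synergy/antagonism regimes.
    """

    hill_a: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 1.0)
    hill_b: tuple[float, float, float, float] = (1.0, 0.0, 2.0, 1.0)
    regime: str = "loewe_additive"
    interaction_strength: float = 0.2
    doses_a: tuple = (0.0, 0.625, 1.25, 2.5, 5.0, 10.0)
    doses_b: tuple = (0.0, 0.625, 1.25, 2.5, 5.0, 10.0)
    noise_cv: float = 0.0
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"
    replicate_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in {"loewe_additive", "bliss_independent", "synergy", "antagonism"}:
            raise ValueError(f"unknown regime: {self.regime!r}")


def _hill_viability(d, curve):
    top, bottom, ic50, hill = curve
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def _loewe_additive_inhibition_oracle(curve_a, curve_b, da: float, db: float) -> float:
    """Loewe-additive inhibition by fine-grid numeric inversion.

    Deliberately shares no code with the analysis module's bisection solver:
    single-agent dose-effect relations are tabulated on dense log-spaced
    dose grids and inverted by linear interpolation; the additivity equation
    is scanned on a dense effect grid for its sign change.
    """
    if da == 0 and db == 0:
        return 1.0 - max(curve_a[0], curve_b[0])
    if db == 0:
        return float(1.0 - _hill_viability(da, curve_a))
    if da == 0:
        return float(1.0 - _hill_viability(db, curve_b))

    def tabulate(curve):
        ic50 = curve[2]
        d_grid = np.geomspace(ic50 * 1e-6, ic50 * 1e6, 4001)
        e_grid = 1.0 - _hill_viability(d_grid, curve)
        return e_grid, d_grid

    ea, dga = tabulate(curve_a)
    eb, dgb = tabulate(curve_b)
    lo = max(ea[0], eb[0])
    hi = min(ea[-1], eb[-1])
    effects = np.linspace(lo, hi, 20001)[1:-1]
    d_need_a = np.interp(effects, ea, dga)
    d_need_b = np.interp(effects, eb, dgb)
    g = da / d_need_a + db / d_need_b - 1.0
    sign_change = np.nonzero(np.diff(np.sign(g)))[0]
    if sign_change.size == 0:
        return float(hi) if g[-1] > 0 else float(lo)
    k = sign_change[0]
    # linear interpolation between the bracketing effect-grid points
    e0, e1, g0, g1 = effects[k], effects[k + 1], g[k], g[k + 1]
    return float(e0 - g0 * (e1 - e0) / (g1 - g0))


def simulate_matrix(spec: MatrixSimSpec) -> DoseMatrix:
    """Generate a checkerboard viability grid under the requested regime."""
    rng = np.random.default_rng(spec.seed)
    da = np.asarray(spec.doses_a, dtype=float)
    db = np.asarray(spec.doses_b, dtype=float)
    na, nb = len(da), len(db)
    grid = np.empty((na, nb))

    if spec.regime == "bliss_independent":
        sa = _hill_viability(da, spec.hill_a)[:, None]
        sb = _hill_viability(db, spec.hill_b)[None, :]
        grid = sa * sb
    else:
        for i in range(na):
            for j in range(nb):
                grid[i, j] = 1.0 - _loewe_additive_inhibition_oracle(
                    spec.hill_a, spec.hill_b, da[i], db[j])
        if spec.regime in ("synergy", "antagonism"):
            sign = 1.0 if spec.regime == "synergy" else -1.0
            inh = 1.0 - grid
            inh[1:, 1:] = np.clip(inh[1:, 1:] + sign * spec.interaction_strength, 0.0, 1.0)
            grid = 1.0 - inh
    if spec.noise_cv > 0:
        grid = grid * np.exp(rng.normal(0.0, spec.noise_cv, grid.shape))
        grid = grid / grid[0, 0]  # re-anchor to the double-vehicle cell
    grid[0, 0] = 1.0
    return DoseMatrix(spec.drug_a, spec.drug_b, da, db, grid,
                      replicate_id=spec.replicate_id)


@dataclass(frozen=True)
class GrowthSimSpec:
    """Conditions for a simulated xenograft efficacy study.

    Exponential growth from a randomized baseline in the 60-100 mm^3
    enrollment window; the treated group's rate is set so the *expected*
    endpoint TGI equals ``inhibition`` (exactly so at zero noise).  The
    measurement schedule is twice weekly for four weeks, n = 7 per group.
    """

    n_per_group: int = 7
    baseline_range: tuple[float, float] = (60.0, 100.0)
    growth_rate: float = 0.08     # per day, control arm (~2.4-fold/11 days)
    inhibition: float = 0.39      # target endpoint TGI fraction
    measurement_cv: float = 0.10  # lognormal caliper noise
    days: tuple = (1, 4, 8, 11, 15, 18, 22, 25, 29)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inhibition < 1:
            raise ValueError("inhibition must lie in (0, 1)")
        if self.days[0] != 1:
            raise ValueError("schedule must start at day 1 (randomization)")

    @property
    def treated_rate(self) -> float:
        span = self.days[-1] - 1
        return self.growth_rate + math.log(1.0 - self.inhibition) / span


def simulate_growth(spec: GrowthSimSpec) -> GrowthTable:
    """Generate a two-arm tumor-growth table from the spec."""
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=int)
    records = []
    for group, rate, prefix in (
        (GROUP_CONTROL, spec.growth_rate, "ctl"),
        (GROUP_TREATED, spec.treated_rate, "trt"),
    ):
        v0 = rng.uniform(*spec.baseline_range, spec.n_per_group)
        for a in range(spec.n_per_group):
            true_v = v0[a] * np.exp(rate * (days - 1))
            noise = (np.exp(rng.normal(0.0, spec.measurement_cv, days.size))
                     if spec.measurement_cv > 0 else 1.0)
            records.append(pd.DataFrame({
                "animal_id": f"{prefix}{a + 1:02d}",
                "group": group,
                "day": days,
                "volume_mm3": true_v * noise,
            }))
    return GrowthTable(pd.concat(records, ignore_index=True)[GROWTH_COLUMNS])
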