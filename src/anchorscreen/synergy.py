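"""Two-drug combination analysis: Loewe-excess surface and Chou-Talalay CI.

Two complementary null models of "no interaction" are scored on a
checkerboard dose matrix:

**Loewe additivity** — a combination ``(d_a, d_b)`` produces effect ``E``
(inhibition fraction) when::

    d_a / D_A(E) + d_b / D_B(E) = 1

where ``D_X(E)`` is the dose of drug X *alone* producing ``E`` (inverted
from its fitted single-agent curve).  The equation is solved per cell by
bisection on ``E`` over the overlap of the two curves' attainable effect
ranges.  The **Loewe excess** is observed minus predicted inhibition, in
percentage points; positive excess = more inhibition than additivity
predicts.

**Chou-Talalay combination index** — from the median-effect model
``fa/fu = (d/Dm)^m`` of each single agent, the dose of drug X alone
reaching the observed combined effect ``fa`` is
``Dx = Dm * (fa/(1-fa))^(1/m)``, and (mutually exclusive form)::

    CI = d_a / Dx_a + d_b / Dx_b

CI < 1 leans synergy, CI = 1 is additive, CI > 1 antagonism.  CI is left
undefined (never fabricated) where ``fa`` is at its bounds or where the
combination's effect exceeds both single agents' observed maxima (the
grey-quadrant convention of checkerboard heatmaps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dose_response import DoseResponseFit, fit_4pl
from .plates import DoseMatrix

__all__ = [
    "MedianEffectFit",
    "SynergyResult",
    "fit_median_effect",
    "median_effect_as_hill",
    "loewe_surface",
    "loewe_excess",
    "chou_talalay_ci",
    "ci_grid",
    "classify_combination",
    "analyze_matrix",
    "LOEWE_EXCESS_THRESHOLD_PP",
    "CI_THRESHOLD",
]

LOEWE_EXCESS_THRESHOLD_PP = 10.0
CI_THRESHOLD = 1.0


@dataclass
class MedianEffectFit:
    """Log-linear median-effect fit: Dm (dose at fa = 0.5) and slope m."""

    drug_id: str
    dm: float
    m: float
    r: float
    n_points: int

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("median-effect dose Dm must be positive")
        if self.n_points < 2:
            raise ValueError("median-effect fit needs >= 2 points")

    def dx(self, fa: float) -> float:
        """Dose of this drug alone producing fraction affected ``fa``."""
        if not 0 < fa < 1:
            raise ValueError("fa must lie strictly in (0, 1)")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def fa(self, dose: float) -> float:
        """Fraction affected at ``dose`` under the median-effect model."""
        if dose <= 0:
            return 0.0
        ratio = (dose / self.dm) ** self.m
        return ratio / (1.0 + ratio)


def fit_median_effect(
    doses,
    fa,
    *,
    drug_id: str = "",
    fa_bounds: tuple[float, float] = (0.01, 0.99),
) -> MedianEffectFit:
    """Fit ``log(fa/fu)`` against ``log(dose)`` by least squares.

    Points with ``fa`` outside ``fa_bounds`` (or at zero dose) are excluded
    — standard median-effect practice, since the logit diverges at the
    bounds.  Slope ``m`` and intercept give ``Dm = exp(-intercept/m)``.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    keep = (d > 0) & (f > fa_bounds[0]) & (f < fa_bounds[1])
    if keep.sum() < 2:
        raise ValueError(
            "median-effect fit infeasible: fewer than 2 doses with fa strictly "
            f"inside {fa_bounds}"
        )
    x = np.log(d[keep])
    y = np.log(f[keep] / (1.0 - f[keep]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m == 0:
        raise ValueError("median-effect fit infeasible: zero slope")
    dm = math.exp(-res.intercept / m)
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 1.0
    return MedianEffectFit(drug_id=drug_id, dm=dm, m=m, r=r, n_points=int(keep.sum()))


def _loewe_cell(fit_a: DoseResponseFit, fit_b: DoseResponseFit,
                da: float, db: float, tol: float) -> tuple[float, bool]:
    """Solve the Loewe equation for one cell; returns (effect, clamped?)."""
    if da == 0 and db == 0:
        return max(fit_a.inhibition_range[0], fit_b.inhibition_range[0]), False
    if db == 0:
        return float(fit_a.inhibition(da)), False
    if da == 0:
        return float(fit_b.inhibition(db)), False
    lo_a, hi_a = fit_a.inhibition_range
    lo_b, hi_b = fit_b.inhibition_range
    lo = max(lo_a, lo_b)
    hi = min(hi_a, hi_b)
    if not hi > lo:
        raise ValueError("single-agent effect ranges do not overlap; Loewe undefined")
    eps = (hi - lo) * 1e-9

    def g(e: float) -> float:
        return da / fit_a.invert_inhibition(e) + db / fit_b.invert_inhibition(e) - 1.0

    e_lo, e_hi = lo + eps, hi - eps
    if g(e_hi) > 0:  # combination exceeds the invertible range: clamp at the bound
        return hi, True
    if g(e_lo) < 0:
        return lo, True
    while e_hi - e_lo > tol:
        mid = 0.5 * (e_lo + e_hi)
        if g(mid) > 0:
            e_lo = mid
        else:
            e_hi = mid
    return 0.5 * (e_lo + e_hi), False


def loewe_surface(
    fit_a: DoseResponseFit,
    fit_b: DoseResponseFit,
    matrix: DoseMatrix,
    *,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Loewe-additive predicted-inhibition grid for a dose matrix.

    Returns ``(predicted, clamped)``: the predicted inhibition fraction per
    cell, and a boolean grid flagging cells where the additive effect fell
    outside the overlap of the two curves' invertible ranges (the nearest
    attainable bound is used there).  Margins reproduce the single-agent
    fits exactly.
    """
    for name, fit in (("A", fit_a), ("B", fit_b)):
        if not fit.converged:
            raise ValueError(f"single-agent fit {name} did not converge")
        lo, hi = fit.inhibition_range
        if hi - lo < 1e-6:
            raise ValueError(f"single-agent curve {name} is flat; Loewe inversion undefined")
    na, nb = len(matrix.doses_a), len(matrix.doses_b)
    pred = np.empty((na, nb))
    clamped = np.zeros((na, nb), dtype=bool)
    for i, da in enumerate(matrix.doses_a):
        for j, db in enumerate(matrix.doses_b):
            pred[i, j], clamped[i, j] = _loewe_cell(fit_a, fit_b, da, db, tol)
    return pred, clamped


def loewe_excess(matrix: DoseMatrix, predicted: np.ndarray) -> np.ndarray:
    """Observed minus Loewe-predicted inhibition, in percentage points."""
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != matrix.viability.shape:
        raise ValueError(
            f"predicted grid {predicted.shape} does not match matrix "
            f"{matrix.viability.shape}"
        )
    return (matrix.inhibition - predicted) * 100.0


def chou_talalay_ci(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    d_a: float,
    d_b: float,
    fa_observed: float,
    *,
    exclusive: bool = True,
) -> float:
    """Chou-Talalay combination index at one observed cell.

    Mutually exclusive (two-term) form by default; ``exclusive=False`` adds
    the third cross-term ``(d_a d_b)/(Dx_a Dx_b)`` of the nonexclusive
    variant.  Returns NaN (undefined) when ``fa_observed`` is at its
    bounds.
    """
    if not 0 < fa_observed < 1:
        return math.nan
    dxa = fit_a.dx(fa_observed)
    dxb = fit_b.dx(fa_observed)
    ci = d_a / dxa + d_b / dxb
    if not exclusive:
        ci += (d_a * d_b) / (dxa * dxb)
    return float(ci)


def ci_grid(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    matrix: DoseMatrix,
    *,
    exclusive: bool = True,
    grey_quadrant: bool = True,
) -> np.ndarray:
    """Per-cell CI over a dose matrix; NaN marks undefined cells.

    Margins (either dose zero) and cells with ``fa`` at {0, 1} are
    undefined.  With ``grey_quadrant=True`` (default), CI is additionally
    left undefined where the combination's observed effect exceeds the
    maximum observed effect of *both* single agents — mirroring the grey
    quadrants of checkerboard CI heatmaps, where extrapolating the
    median-effect lines is not meaningful.
    """
    inh = matrix.inhibition
    fa_max_a = float(np.max(inh[:, 0]))
    fa_max_b = float(np.max(inh[0, :]))
    cap = max(fa_max_a, fa_max_b)
    out = np.full(inh.shape, np.nan)
    for i, da in enumerate(matrix.doses_a):
        for j, db in enumerate(matrix.doses_b):
            if da == 0 or db == 0:
                continue
            fa = inh[i, j]
            if grey_quadrant and fa > cap:
                continue
            out[i, j] = chou_talalay_ci(fit_a, fit_b, da, db, fa, exclusive=exclusive)
    return out


@dataclass
class SynergyResult:
    """Per-cell synergy scores and the matrix-level summary for one checkerboard."""

    matrix: DoseMatrix
    predicted_inhibition: np.ndarray
    clamped: np.ndarray
    excess: np.ndarray
    ci: np.ndarray
    calls: np.ndarray = field(default=None)  # type: ignore[assignment]
    summary: dict = field(default_factory=dict)


def classify_combination(
    result: SynergyResult,
    *,
    loewe_thresh: float = LOEWE_EXCESS_THRESHOLD_PP,
    ci_thresh: float = CI_THRESHOLD,
) -> SynergyResult:
    """Apply the printed thresholds (Loewe excess > 10 pp, CI < 1) per cell.

    Cell calls over interior cells (both doses > 0): ``synergy-leaning``
    when excess exceeds ``loewe_thresh`` or CI falls below ``ci_thresh``;
    ``antagonistic`` when excess falls below ``-loewe_thresh`` and CI does
    not lean synergy; ``additive`` otherwise; margins are ``undefined``.

    The matrix verdict guards against CI noise around 1: *potentiation*
    requires >= 25% of interior cells above the excess threshold, or >= 75%
    of defined-CI cells below the CI threshold.
    """
    na, nb = result.excess.shape
    calls = np.full((na, nb), "undefined", dtype=object)
    interior = np.zeros((na, nb), dtype=bool)
    interior[1:, 1:] = True
    for i in range(na):
        for j in range(nb):
            if not interior[i, j]:
                continue
            ex = result.excess[i, j]
            ci = result.ci[i, j]
            syn = ex > loewe_thresh or (np.isfinite(ci) and ci < ci_thresh)
            if syn:
                calls[i, j] = "synergy-leaning"
            elif ex < -loewe_thresh:
                calls[i, j] = "antagonistic"
            else:
                calls[i, j] = "additive"
    n_int = int(interior.sum())
    ex_int = result.excess[interior]
    ci_def = result.ci[interior & np.isfinite(result.ci)]
    frac_called = float(np.sum(calls[interior] == "synergy-leaning")) / n_int
    frac_excess = float(np.sum(ex_int > loewe_thresh)) / n_int
    frac_ci = float(np.mean(ci_def < ci_thresh)) if ci_def.size else 0.0
    verdict = "potentiation" if (frac_excess >= 0.25 or frac_ci >= 0.75) else "no potentiation"
    result.calls = calls
    result.summary = {
        "drug_a": result.matrix.drug_a,
        "drug_b": result.matrix.drug_b,
        "n_interior_cells": n_int,
        "fraction_cells_called": frac_called,
        "fraction_excess_above_threshold": frac_excess,
        "fraction_ci_below_threshold": frac_ci,
        "max_loewe_excess_pp": float(np.max(ex_int)),
        "min_ci": float(np.min(ci_def)) if ci_def.size else math.nan,
        "median_ci": float(np.median(ci_def)) if ci_def.size else math.nan,
        "verdict": verdict,
        "loewe_threshold_pp": loewe_thresh,
        "ci_threshold": ci_thresh,
    }
    return result


def median_effect_as_hill(fit: MedianEffectFit) -> DoseResponseFit:
    """Re-express a median-effect fit as an equivalent full-range Hill curve.

    The median-effect model fa/fu = (d/Dm)^m is exactly a 4PL with top 1,
    bottom 0, IC50 = Dm and slope m, which lets the Loewe solver invert
    median-effect curves instead of the 4PL fits.
    """
    return DoseResponseFit(compound_id=fit.drug_id, top=1.0, bottom=0.0,
                           ic50=fit.dm, hill=fit.m)


def analyze_matrix(
    matrix: DoseMatrix,
    *,
    fit_a: DoseResponseFit | None = None,
    fit_b: DoseResponseFit | None = None,
    loewe_thresh: float = LOEWE_EXCESS_THRESHOLD_PP,
    ci_thresh: float = CI_THRESHOLD,
    exclusive_ci: bool = True,
    loewe_from_median_effect: bool = False,
    seed: int = 0,
) -> SynergyResult:
    """End-to-end synergy analysis of one checkerboard.

    When single-agent 4PL fits are not supplied, they are fitted from the
    matrix's own zero-dose margins.  Median-effect fits for the CI are
    always taken from the margins (fa = 1 - viability).  With
    ``loewe_from_median_effect=True`` the Loewe surface inverts the
    median-effect curves instead of the 4PL fits.
    """
    if fit_a is None:
        d, v = matrix.margin_a()
        fit_a = fit_4pl(d, np.clip(v, 0, 1.5), compound_id=matrix.drug_a, seed=seed)
    if fit_b is None:
        d, v = matrix.margin_b()
        fit_b = fit_4pl(d, np.clip(v, 0, 1.5), compound_id=matrix.drug_b, seed=seed)
    da, va = matrix.margin_a()
    db, vb = matrix.margin_b()
    me_a = fit_median_effect(da, 1.0 - va, drug_id=matrix.drug_a)
    me_b = fit_median_effect(db, 1.0 - vb, drug_id=matrix.drug_b)

    if loewe_from_median_effect:
        pred, clamped = loewe_surface(median_effect_as_hill(me_a),
                                      median_effect_as_hill(me_b), matrix)
    else:
        pred, clamped = loewe_surface(fit_a, fit_b, matrix)
    excess = loewe_excess(matrix, pred)
    ci = ci_grid(me_a, me_b, matrix, exclusive=exclusive_ci)
    result = SynergyResult(matrix, pred, clamped, excess, ci)
    return classify_combination(result, loewe_thresh=loewe_thresh, ci_thresh=ci_thresh)
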