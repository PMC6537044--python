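"""Four-parameter logistic (4PL) dose-response fitting and IC50 classification.

The model is the standard Hill curve on viability::

    v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

with ``top`` the zero-dose asymptote, ``bottom`` the infinite-dose
asymptote, ``ic50`` the inflection dose (the *relative* IC50) and ``hill``
the slope.  For ``hill > 0`` and ``top > bottom`` the curve decreases with
dose.  Fitting is nonlinear least squares with multi-start initialization
from quantile heuristics; the IC50 is parametrized on the log scale so the
fit is invariant to dose-unit rescaling (IC50 scales linearly, the slope is
unchanged).

Cell lines are then binned by fitted IC50 into ``sensitive``
(< 4 umol/L by default), ``resistant`` (> 30 umol/L) or ``intermediate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "four_pl",
    "fit_4pl",
    "classify_sensitivity",
    "normalize_to_vehicle",
    "SENSITIVE_BELOW_UM",
    "RESISTANT_ABOVE_UM",
]

SENSITIVE_BELOW_UM = 4.0
RESISTANT_ABOVE_UM = 30.0


def normalize_to_vehicle(signal, vehicle_signal):
    """Raw readouts -> viability fractions relative to the vehicle wells' mean.

    Dose-response series are normalized against their own plate's vehicle
    wells before fitting, so fits operate on growth relative to untreated
    cells.
    """
    signal = np.asarray(signal, dtype=float)
    vehicle = np.asarray(vehicle_signal, dtype=float)
    if vehicle.size == 0 or np.any(vehicle <= 0):
        raise ValueError("vehicle wells must be non-empty with positive signal")
    return signal / vehicle.mean()


def four_pl(d, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the 4PL viability curve at dose(s) ``d`` (zero dose allowed)."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, (d / ic50) ** hill, 0.0 if hill > 0 else np.inf)
    out = bottom + (top - bottom) / (1.0 + ratio)
    if hill <= 0:
        # limit at d=0 flips for negative slopes
        out = np.where(d == 0, bottom, out)
    return out


@dataclass
class DoseResponseFit:
    """A fitted (or constructed) 4PL curve plus its sensitivity class."""

    compound_id: str = ""
    cell_line_id: str = ""
    top: float = 1.0
    bottom: float = 0.0
    ic50: float = 1.0
    hill: float = 1.0
    rss: float = 0.0
    converged: bool = True
    sensitivity_class: str | None = None

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom (canonical orientation)")

    def predict(self, d):
        """Viability fraction at dose(s) d."""
        return four_pl(d, self.top, self.bottom, self.ic50, self.hill)

    def inhibition(self, d):
        """Fraction affected (1 - viability) at dose(s) d."""
        return 1.0 - self.predict(d)

    @property
    def inhibition_range(self) -> tuple[float, float]:
        """Attainable inhibition interval (at dose 0 and dose -> infinity)."""
        lo = 1.0 - self.top
        hi = 1.0 - self.bottom
        return (lo, hi) if self.hill > 0 else (hi, lo)

    def invert_inhibition(self, effect: float) -> float:
        """Dose producing inhibition ``effect``; the Loewe D_X(E) term.

        Only defined strictly inside the curve's attainable effect range.
        """
        v = 1.0 - effect
        if not (self.bottom < v < self.top):
            raise ValueError(
                f"effect {effect:.4g} outside invertible range "
                f"{self.inhibition_range} of the fitted curve"
            )
        return self.ic50 * ((self.top - v) / (v - self.bottom)) ** (1.0 / self.hill)


def _residuals(params, d, v, w):
    top, bottom, log_ic50, hill = params
    pred = four_pl(d, top, bottom, math.exp(log_ic50), hill)
    return (pred - v) * w


def fit_4pl(
    doses,
    viability,
    weights=None,
    *,
    compound_id: str = "",
    cell_line_id: str = "",
    n_starts: int = 5,
    seed: int = 0,
    flat_tol: float = 0.05,
) -> DoseResponseFit:
    """Least-squares 4PL fit of viability fractions against a dose ladder.

    Requires >= 4 distinct doses.  Near-constant response (range below
    ``flat_tol``) raises ``ValueError("no dose effect detectable")`` — a
    flat curve has no identifiable IC50.  Multi-start: quantile-based
    heuristics plus seeded jitter; the returned fit carries the best RSS and
    an honest ``converged`` flag (False when no start converged, in which
    case no sensitivity class should be assigned).
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viability, dtype=float)
    if d.shape != v.shape:
        raise ValueError("doses and viability must align")
    if np.unique(d).size < 4:
        raise ValueError("fit_4pl needs at least 4 distinct doses")
    if np.any(v < 0) or np.any(v > 1.5):
        raise ValueError("viability must lie in [0, 1.5]")
    if v.max() - v.min() < flat_tol:
        raise ValueError("no dose effect detectable")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)

    rng = np.random.default_rng(seed)
    pos = d[d > 0]
    top0 = float(np.clip(v[d <= np.quantile(d, 0.25)].mean(), 0.1, 1.5))
    bot0 = float(np.clip(v.min(), 0.0, top0 - 1e-3))
    mid = (top0 + bot0) / 2
    ic0 = float(pos[np.argmin(np.abs(v[d > 0] - mid))]) if pos.size else 1.0
    ic0 = max(ic0, 1e-9)

    # logit linearization of the normalized response gives slope/IC50 estimates
    span = max(top0 - bot0, 1e-3)
    frac = np.clip((top0 - v[d > 0]) / span, 1e-3, 1 - 1e-3)
    x = np.log(pos)
    y = np.log(frac / (1 - frac))
    slope, icpt = np.polyfit(x, y, 1)
    hill0 = float(np.clip(slope, 0.1, 10.0))
    lic0 = float(-icpt / slope) if slope > 0.05 else math.log(ic0)
    lic0 = float(np.clip(lic0, math.log(pos.min()) - 5, math.log(pos.max()) + 5))

    starts = [(top0, bot0, lic0, hill0)]
    starts += [(top0, bot0, math.log(ic0), h) for h in (0.5, 1.0, 2.0)]
    starts.append((1.0, 0.0, math.log(float(np.median(pos))), 1.0))
    while len(starts) < n_starts:
        starts.append(
            (
                top0 * float(np.exp(rng.normal(0, 0.05))),
                bot0 + float(rng.uniform(0, 0.05)),
                math.log(ic0) + float(rng.normal(0, 0.5)),
                float(np.exp(rng.normal(0, 0.3))),
            )
        )

    lo = [0.0, 0.0, math.log(max(pos.min(), 1e-12)) - 7, -20.0]
    hi = [1.6, 1.5, math.log(pos.max()) + 7, 20.0]
    best = None
    for p0 in starts[:n_starts]:
        p0 = np.clip(p0, lo, hi)
        try:
            sol = least_squares(_residuals, p0, bounds=(lo, hi), args=(d, v, w),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return DoseResponseFit(compound_id, cell_line_id, converged=False,
                               rss=math.inf)
    rss, (top, bottom, log_ic50, hill) = best
    if top < bottom:  # canonical orientation: swap asymptotes, flip slope
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(
        compound_id=compound_id,
        cell_line_id=cell_line_id,
        top=float(top),
        bottom=float(bottom),
        ic50=float(math.exp(log_ic50)),
        hill=float(hill),
        rss=rss,
        converged=True,
    )


def classify_sensitivity(
    fit: DoseResponseFit,
    *,
    sensitive_hi: float = SENSITIVE_BELOW_UM,
    resistant_lo: float = RESISTANT_ABOVE_UM,
) -> str:
    """Bin a converged fit by IC50: sensitive / intermediate / resistant.

    ``ic50 < sensitive_hi`` (4 umol/L default) -> sensitive;
    ``ic50 > resistant_lo`` (30 umol/L default) -> resistant; else
    intermediate.  The class is stored on the fit and returned.
    """
    if not fit.converged:
        raise ValueError("cannot classify an unconverged fit")
    if fit.ic50 < sensitive_hi:
        cls = "sensitive"
    elif fit.ic50 > resistant_lo:
        cls = "resistant"
    else:
        cls = "intermediate"
    fit.sensitivity_class = cls
    return cls
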