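"""Xenograft growth analytics (RTV, TGI, Mann-Whitney) and ancillary statistics.

Relative tumor volume (RTV) for an animal is volume at day *t* divided by
its day-1 (randomization) baseline; tumor growth inhibition at a stated
day is::

    TGI = (1 - mean RTV_treated / mean RTV_control) x 100

Group differences on final-day RTVs use a two-tailed Mann-Whitney test
(exact enumeration for small groups, normal approximation with tie
correction otherwise).  Cell-cycle phase shifts between two conditions are
tested per phase (G1 / S / G2M, each vs. the rest) with two-sided Fisher
exact tests, Benjamini-Hochberg adjusted across the three phases.  Caspase
luminescence is normalized to concomitant viability before fold-changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .plates import GROUP_CONTROL, GROUP_TREATED, GrowthTable

__all__ = [
    "GrowthSummary",
    "compute_rtv",
    "tgi",
    "mann_whitney_two_tailed",
    "MannWhitneyResult",
    "fisher_exact_two_sided",
    "fisher_p_by_margins",
    "cellcycle_fisher_bh",
    "normalize_caspase",
]

EXACT_MW_MAX_N = 8  # exact enumeration up to this group size (study used n = 7)


@dataclass
class GrowthSummary:
    """Per-animal RTV series plus per-group daily means and SEMs."""

    rtv: pd.DataFrame            # animal_id, group, day, rtv
    group_stats: pd.DataFrame    # group, day, mean_rtv, sem, n

    def final_day(self) -> int:
        return int(self.rtv["day"].max())

    def rtv_at(self, day: int, group: str) -> np.ndarray:
        sub = self.rtv[(self.rtv["day"] == day) & (self.rtv["group"] == group)]
        return sub["rtv"].to_numpy()


def compute_rtv(growth: GrowthTable) -> GrowthSummary:
    """RTV per animal per day, plus group mean +/- SEM growth curves."""
    df = growth.records.copy()
    base = (
        df[df["day"] == growth.baseline_day]
        .set_index("animal_id")["volume_mm3"]
        .rename("baseline")
    )
    df = df.join(base, on="animal_id")
    df["rtv"] = df["volume_mm3"] / df["baseline"]
    rtv = df[["animal_id", "group", "day", "rtv"]].sort_values(
        ["group", "animal_id", "day"]).reset_index(drop=True)
    gs = (
        rtv.groupby(["group", "day"])["rtv"]
        .agg(mean_rtv="mean", sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)), n="size")
        .reset_index()
    )
    return GrowthSummary(rtv, gs)


def tgi(summary: GrowthSummary, day: int) -> float:
    """Tumor growth inhibition percent at ``day`` (mean-RTV ratio form)."""
    treated = summary.rtv_at(day, GROUP_TREATED)
    control = summary.rtv_at(day, GROUP_CONTROL)
    if treated.size == 0 or control.size == 0:
        raise ValueError(f"day {day} absent from treated and/or control group")
    return float((1.0 - treated.mean() / control.mean()) * 100.0)


@dataclass
class MannWhitneyResult:
    p: float
    statistic: float
    method: str  # "exact" or "asymptotic"

    def __float__(self) -> float:
        return self.p


def mann_whitney_two_tailed(x, y) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test.

    Exact null enumeration when both groups have <= 8 observations and no
    cross-group ties; otherwise the normal approximation with tie
    correction.  Degenerate all-tied samples return p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("mann_whitney_two_tailed needs >= 3 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; Mann-Whitney p set to 1", stacklevel=2)
        return MannWhitneyResult(1.0, x.size * y.size / 2.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(float(min(res.pvalue, 1.0)), float(res.statistic), method)


def fisher_p_by_margins(n1: int, n2: int, k: int) -> np.ndarray:
    """Two-sided Fisher exact p for *every* 2x2 table with fixed margins.

    Margins: row totals ``n1``, ``n2`` and first-column total ``k``.  Entry
    ``i`` of the returned array is the p-value of the table
    ``[[a, n1-a], [k-a, n2-k+a]]`` for ``a = a_min + i`` over the
    hypergeometric support.  Two-sided p sums the probabilities of all
    tables no more likely than the observed one (the minimum-likelihood
    convention, with a small relative tolerance for float ties).
    """
    a_min = max(0, k - n2)
    a_max = min(k, n1)
    a = np.arange(a_min, a_max + 1)
    logpmf = (
        gammaln(n1 + 1) - gammaln(a + 1) - gammaln(n1 - a + 1)
        + gammaln(n2 + 1) - gammaln(k - a + 1) - gammaln(n2 - k + a + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(k + 1) - gammaln(n1 + n2 - k + 1))
    )
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    p = np.array([pmf[pmf <= pi * (1 + 1e-7)].sum() for pi in pmf])
    return np.minimum(p, 1.0)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact test of a 2x2 count table.

    Hypergeometric enumeration over the table's support; equivalent to the
    classic two-sided Fisher test (minimum-likelihood tail definition).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact_two_sided expects a nonnegative 2x2 table")
    n1, n2 = int(t[0].sum()), int(t[1].sum())
    k = int(t[0, 0] + t[1, 0])
    if n1 + n2 == 0:
        raise ValueError("empty table")
    if k == 0 or k == n1 + n2 or n1 == 0 or n2 == 0:
        return 1.0
    p = fisher_p_by_margins(n1, n2, k)
    a_min = max(0, k - n2)
    return float(p[int(t[0, 0]) - a_min])


PHASES = ("G1", "S", "G2M")


def cellcycle_fisher_bh(
    counts_a: dict, counts_b: dict, *, phases: tuple = PHASES, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-phase Fisher exact tests between two conditions, BH-adjusted.

    ``counts_a``/``counts_b`` map phase names to cell counts and must carry
    a ``"total"`` entry (total cells acquired per condition).  Each phase is
    tested phase-vs-rest in a 2x2 table across the two conditions; the
    Benjamini-Hochberg adjustment runs across the listed phases (the test
    family of one experiment).
    """
    for name, c in (("first", counts_a), ("second", counts_b)):
        if c.get("total", 0) <= 0:
            raise ValueError(f"{name} condition has zero total cell count")
        for ph in phases:
            if c.get(ph, 0) > c["total"]:
                raise ValueError(f"{name} condition: {ph} count exceeds total")
    rows = []
    for ph in phases:
        table = [
            [counts_a[ph], counts_a["total"] - counts_a[ph]],
            [counts_b[ph], counts_b["total"] - counts_b[ph]],
        ]
        rows.append({"phase": ph, "p": fisher_exact_two_sided(table)})
    out = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(out["p"], method="fdr_bh")
    out["p_adjusted"] = adj
    out["significant"] = out["p_adjusted"] < alpha
    return out


def normalize_caspase(caspase_lum, viability_lum, *, vehicle_ratio: float | None = None):
    """Caspase activity per unit viability, as fold-change vs vehicle.

    Returns the raw ``caspase/viability`` ratio when ``vehicle_ratio`` is
    None, else the fold-change relative to it.  Invariant to any common
    luminescence gain applied to both channels.
    """
    caspase = np.asarray(caspase_lum, dtype=float)
    viability = np.asarray(viability_lum, dtype=float)
    if np.any(viability <= 0):
        raise ValueError("viability luminescence must be positive")
    ratio = caspase / viability
    if vehicle_ratio is None:
        return ratio
    if vehicle_ratio <= 0:
        raise ValueError("vehicle ratio must be positive")
    return ratio / vehicle_ratio
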