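"""Hit calling, anchor-potentiation ranking (delta-RZ), and the RZ back-transform.

A compound is a *hit* when its robust Z-score falls below a threshold
(default -2) in **every** replicate of the selected arm — the
replicate-concordance rule guards against single-well artifacts.  For each
hit, the anchor potentiation is quantified as::

    delta_RZ = mean_reps RZ(compound + anchor) - mean_reps RZ(compound alone)

More negative delta-RZ means the anchor potentiates the compound's effect
beyond either agent alone.  Ranking hits by ascending delta-RZ surfaces the
strongest combination partners.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .normalize import MAD_CONSISTENCY
from .plates import ARM_COMBO, ARM_SINGLE, ROLE_COMPOUND

__all__ = ["call_hits", "delta_rz", "rz_to_proliferation", "hit_table", "rank_hits"]

logger = logging.getLogger(__name__)


def _rz_by_compound(scores: pd.DataFrame, arm: str) -> pd.DataFrame:
    """Pivot RZ per compound x replicate for one arm (compound wells only)."""
    sub = scores[(scores["role"] == ROLE_COMPOUND) & (scores["arm"] == arm)]
    if sub.empty:
        raise ValueError(f"no scored compound wells for arm {arm!r}")
    piv = sub.pivot_table(index="compound_id", columns="replicate", values="rz_score",
                          aggfunc="mean")
    piv.columns = [f"rz_rep{r}" for r in piv.columns]
    return piv


def call_hits(
    scores: pd.DataFrame,
    *,
    threshold: float = -2.0,
    arm: str = ARM_COMBO,
    min_replicates: int = 2,
    strict: bool = True,
) -> pd.DataFrame:
    """Replicate-concordant hit calls for one arm.

    Returns a frame indexed by compound with per-replicate RZ columns and an
    ``is_hit`` flag: true iff RZ < ``threshold`` (strictly, unless
    ``strict=False`` which uses <=) in *every* replicate.  Compounds scored
    in fewer than ``min_replicates`` replicates are excluded from the calls
    and logged; their ids are kept in ``result.attrs["excluded"]``.
    """
    piv = _rz_by_compound(scores, arm)
    n_reps = piv.shape[1]
    if n_reps < min_replicates:
        raise ValueError(
            f"hit calling needs >= {min_replicates} replicates; arm {arm!r} has {n_reps}"
        )
    n_scored = piv.notna().sum(axis=1)
    excluded = piv.index[n_scored < min_replicates].tolist()
    if excluded:
        logger.warning(
            "excluding %d compound(s) scored in fewer than %d replicates: %s",
            len(excluded), min_replicates, excluded[:10],
        )
    calls = piv.loc[n_scored >= min_replicates].copy()
    rz = calls.to_numpy()
    with np.errstate(invalid="ignore"):
        below = rz < threshold if strict else rz <= threshold
    calls["is_hit"] = np.all(below | np.isnan(rz), axis=1)
    calls.attrs["excluded"] = excluded
    calls.attrs["arm"] = arm
    calls.attrs["threshold"] = threshold
    return calls


def delta_rz(rz_combo, rz_single) -> float:
    """Anchor-potentiation score: mean combo-arm RZ minus mean single-arm RZ."""
    rz_combo = np.asarray(rz_combo, dtype=float)
    rz_single = np.asarray(rz_single, dtype=float)
    if np.all(np.isnan(rz_combo)) or np.all(np.isnan(rz_single)):
        raise ValueError("delta_rz requires scores in both arms")
    return float(np.nanmean(rz_combo) - np.nanmean(rz_single))


def rz_to_proliferation(rz: float, mad_ref: float, median_ref: float = 0.0) -> float:
    """Back-transform an RZ-score to percent proliferation.

    On the natural-log scale, ``rz = (log v - median_ref) / (1.4826 mad_ref)``,
    so the well's signal relative to the reference median is
    ``exp(rz * 1.4826 * mad_ref)``; expressed as a percentage::

        %proliferation = exp(rz * 1.4826 * mad_ref + median_ref)
                         / exp(median_ref) * 100

    The reference median cancels; it is accepted for interface symmetry with
    the stored ``median_ref``.  Monotone increasing in ``rz``; ``rz = 0``
    maps to exactly 100%.
    """
    if mad_ref < 0:
        raise ValueError("mad_ref must be nonnegative")
    x = rz * MAD_CONSISTENCY * mad_ref
    if x > 700:  # exp overflow guard
        return math.inf
    return math.exp(x) * 100.0


def hit_table(
    scores: pd.DataFrame,
    *,
    threshold: float = -2.0,
    hit_arm: str = ARM_COMBO,
    min_replicates: int = 2,
    strict: bool = True,
) -> pd.DataFrame:
    """Full per-compound hit report across both arms.

    Columns: per-replicate RZ for single and combo arms, ``is_hit`` (on the
    ``hit_arm``), ``delta_rz`` (hits only, per the screen's convention —
    NaN for non-hits), per-replicate delta, and percent proliferation per
    arm from each arm's mean RZ and reference MAD.
    """
    combo = _rz_by_compound(scores, ARM_COMBO).add_suffix("_combo")
    single = _rz_by_compound(scores, ARM_SINGLE).add_suffix("_single")
    calls = call_hits(scores, threshold=threshold, arm=hit_arm,
                      min_replicates=min_replicates, strict=strict)
    out = single.join(combo, how="outer")
    out["is_hit"] = calls["is_hit"].reindex(out.index).fillna(False).astype(bool)

    combo_cols = [c for c in out.columns if c.endswith("_combo")]
    single_cols = [c for c in out.columns if c.endswith("_single")]
    mean_combo = out[combo_cols].mean(axis=1)
    mean_single = out[single_cols].mean(axis=1)
    out["delta_rz"] = np.where(out["is_hit"], mean_combo - mean_single, np.nan)
    for c, s in zip(sorted(combo_cols), sorted(single_cols)):
        rep = c.split("_rep")[1].split("_")[0]
        out[f"delta_rz_rep{rep}"] = np.where(out["is_hit"], out[c] - out[s], np.nan)

    # percent proliferation per arm from each arm's reference MAD
    mad_by_arm = (
        scores[scores["role"] == ROLE_COMPOUND]
        .groupby("arm")["mad_ref"]
        .median()
        .to_dict()
    )
    out["pct_proliferation_single"] = [
        rz_to_proliferation(v, mad_by_arm[ARM_SINGLE]) if np.isfinite(v) else np.nan
        for v in mean_single
    ]
    out["pct_proliferation_combo"] = [
        rz_to_proliferation(v, mad_by_arm[ARM_COMBO]) if np.isfinite(v) else np.nan
        for v in mean_combo
    ]
    out.attrs.update(calls.attrs)
    return out


def rank_hits(hits: pd.DataFrame, *, top: int | None = 25) -> pd.DataFrame:
    """Rank hits by ascending delta-RZ (strongest potentiation first).

    Ties are broken by the combo-arm mean RZ (more negative first).  Only
    hit compounds appear; ``top=None`` returns all hits ranked.
    """
    sub = hits[hits["is_hit"]].copy()
    combo_cols = [c for c in sub.columns if c.startswith("rz_rep") and c.endswith("_combo")]
    sub["_tiebreak"] = sub[combo_cols].mean(axis=1)
    sub = sub.sort_values(["delta_rz", "_tiebreak"]).drop(columns="_tiebreak")
    return sub.head(top) if top is not None else sub
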