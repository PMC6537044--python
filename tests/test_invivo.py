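"""RTV/TGI growth analytics, Mann-Whitney, Fisher+BH, caspase normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from anchorscreen import (
    GrowthSimSpec,
    GrowthTable,
    cellcycle_fisher_bh,
    compute_rtv,
    fisher_exact_two_sided,
    fisher_p_by_margins,
    mann_whitney_two_tailed,
    normalize_caspase,
    simulate_growth,
    tgi,
)
from helpers import fisher_two_sided_enum


def _growth_from_volumes(control, treated, days):
    recs = []
    for group, series in (("control", control), ("treated", treated)):
        for a, vols in enumerate(series):
            for day, v in zip(days, vols):
                recs.append({"animal_id": f"{group[0]}{a}", "group": group,
                             "day": day, "volume_mm3": v})
    return GrowthTable(pd.DataFrame(recs))


def test_rtv_definition_and_scale_invariance():
    days = (1, 5, 9)
    g = _growth_from_volumes([(100, 200, 400)], [(80, 80, 80)], days)
    summ = compute_rtv(g)
    assert list(summ.rtv_at(1, "control")) == [1.0]
    assert list(summ.rtv_at(9, "control")) == [4.0]
    # volume units cancel
    g_ml = _growth_from_volumes([(0.1, 0.2, 0.4)], [(0.08, 0.08, 0.08)], days)
    assert np.allclose(compute_rtv(g_ml).rtv["rtv"], summ.rtv["rtv"])


def test_tgi_definitional_identity():
    days = (1, 29)
    # mean RTVs 6.1 (treated) vs 10.0 (control) -> 39%
    g = _growth_from_volumes(
        [(100, 1000)] * 3, [(100, 610)] * 3, days)
    summ = compute_rtv(g)
    assert tgi(summ, 29) == pytest.approx(39.0, abs=1e-12)
    # identical groups -> 0; faster treated growth -> negative, reported as-is
    g0 = _growth_from_volumes([(100, 300)] * 3, [(100, 300)] * 3, days)
    assert tgi(compute_rtv(g0), 29) == 0.0
    gneg = _growth_from_volumes([(100, 300)] * 3, [(100, 600)] * 3, days)
    assert tgi(compute_rtv(gneg), 29) == pytest.approx(-100.0)
    with pytest.raises(ValueError, match="day 15"):
        tgi(summ, 15)


def test_group_sem_matches_definition():
    g = simulate_growth(GrowthSimSpec(seed=5))
    summ = compute_rtv(g)
    day = summ.final_day()
    vals = summ.rtv_at(day, "control")
    row = summ.group_stats.query("group == 'control' and day == @day").iloc[0]
    assert row["sem"] == pytest.approx(vals.std(ddof=1) / math.sqrt(len(vals)))


class TestMannWhitney:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="tied"):
            res = mann_whitney_two_tailed(np.ones(4), np.ones(4))
        assert res.p == 1.0
        res2 = mann_whitney_two_tailed(x, x)
        assert res2.p == pytest.approx(1.0, abs=0.02)

    def test_fully_separated_seven_vs_seven_exact(self):
        x = np.arange(1.0, 8.0)
        y = np.arange(100.0, 107.0)
        res = mann_whitney_two_tailed(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / math.comb(14, 7), rel=1e-12)

    def test_large_or_tied_samples_use_asymptotic(self):
        rng = np.random.default_rng(0)
        res = mann_whitney_two_tailed(rng.normal(size=20), rng.normal(1, 1, 20))
        assert res.method == "asymptotic"
        x = np.array([1.0, 2.0, 2.0, 3.0])
        res2 = mann_whitney_two_tailed(x, x + 0.5)
        assert res2.method == "asymptotic"

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match=">= 3"):
            mann_whitney_two_tailed([1.0, 2.0], [3.0, 4.0, 5.0])


class TestFisher:
    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            t = rng.integers(0, 40, size=(2, 2))
            ours = fisher_exact_two_sided(t)
            ref = stats.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        for table in [(8, 2, 1, 9), (800, 200, 500, 500), (3, 0, 0, 3), (5, 5, 5, 5)]:
            a, b, c, d = table
            assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
                fisher_two_sided_enum(a, b, c, d), rel=1e-10)

    def test_margin_vector_consistency(self):
        p = fisher_p_by_margins(10, 12, 7)
        for i, a in enumerate(range(max(0, 7 - 12), min(7, 10) + 1)):
            t = [[a, 10 - a], [7 - a, 12 - 7 + a]]
            assert p[i] == pytest.approx(fisher_exact_two_sided(t), rel=1e-12)


class TestCellCycle:
    def test_identical_tables_give_unit_p(self):
        c = {"G1": 500, "S": 200, "G2M": 300, "total": 1000}
        out = cellcycle_fisher_bh(c, dict(c))
        assert (out["p_adjusted"] == 1.0).all()
        assert not out["significant"].any()

    def test_strong_g1_shift_detected(self):
        a = {"G1": 800, "S": 100, "G2M": 100, "total": 1000}
        b = {"G1": 500, "S": 250, "G2M": 250, "total": 1000}
        out = cellcycle_fisher_bh(a, b).set_index("phase")
        enum_p = fisher_two_sided_enum(800, 200, 500, 500)
        assert out.loc["G1", "p"] == pytest.approx(enum_p, rel=1e-9)
        assert out.loc["G1", "significant"]

    def test_bh_adjustment_hand_example(self):
        # BH of sorted p (0.01, 0.02, 0.9) -> (0.03, 0.03, 0.9)
        a = {"G1": 1, "S": 1, "G2M": 1, "total": 3}
        out = cellcycle_fisher_bh(a, dict(a))
        # the adjustment path itself, on a hand-set vector:
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests([0.01, 0.02, 0.9], method="fdr_bh")
        assert np.allclose(adj, [0.03, 0.03, 0.9])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            cellcycle_fisher_bh({"G1": 0, "S": 0, "G2M": 0, "total": 0},
                                {"G1": 1, "S": 1, "G2M": 1, "total": 3})


def test_caspase_normalization():
    assert normalize_caspase(100.0, 50.0, vehicle_ratio=2.0) == 1.0
    # caspase x2 and viability x0.5 -> fold-change 4
    assert normalize_caspase(200.0, 25.0, vehicle_ratio=2.0) == 4.0
    # invariant to common luminescence gain
    base = normalize_caspase(300.0, 60.0, vehicle_ratio=5.0)
    assert normalize_caspase(3000.0, 600.0, vehicle_ratio=5.0) == base
    with pytest.raises(ValueError, match="positive"):
        normalize_caspase(10.0, 0.0)
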