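"""Median-effect fitting, Loewe surface/excess, and Chou-Talalay CI."""

import numpy as np
import pytest

from anchorscreen import (
    DoseResponseFit,
    MatrixSimSpec,
    MedianEffectFit,
    analyze_matrix,
    chou_talalay_ci,
    ci_grid,
    classify_combination,
    fit_median_effect,
    loewe_excess,
    loewe_surface,
    simulate_matrix,
)
from anchorscreen.synergy import SynergyResult
from helpers import hill_inverse_dose, hill_viability


def _me_fa(d, dm, m):
    ratio = (np.asarray(d, float) / dm) ** m
    return ratio / (1 + ratio)


class TestMedianEffect:
    def test_exact_recovery(self):
        d = np.array([0.25, 0.5, 1, 2, 4.0])
        fit = fit_median_effect(d, _me_fa(d, dm=1.0, m=1.0))
        assert fit.dm == pytest.approx(1.0, rel=1e-9)
        assert fit.m == pytest.approx(1.0, rel=1e-9)

    def test_dm_is_half_effect_dose(self):
        d = np.array([2.0, 8.0])
        fit = fit_median_effect(d, _me_fa(d, dm=2.0, m=1.3))
        assert fit.dm == pytest.approx(2.0, rel=1e-9)
        assert fit.fa(2.0) == pytest.approx(0.5)

    def test_noisy_binomial_recovery(self):
        rng = np.random.default_rng(17)
        d = np.geomspace(0.125, 8, 7)
        fa_true = _me_fa(d, dm=1.0, m=1.5)
        fa_obs = rng.binomial(1000, fa_true) / 1000
        fit = fit_median_effect(d, fa_obs)
        assert abs(fit.dm - 1.0) < 0.10

    def test_degenerate_fa_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            fit_median_effect([1, 2, 4], [0.0, 1.0, 1.0])

    def test_out_of_bounds_points_excluded(self):
        d = np.array([0.01, 0.5, 1, 2, 100.0])
        fa = _me_fa(d, 1.0, 2.0)  # endpoints outside [0.01, 0.99]
        fit = fit_median_effect(d, fa)
        assert fit.n_points == 3


class TestLoewe:
    CA = dict(top=1.0, bottom=0.0, ic50=1.0, hill=1.0)
    CB = dict(top=1.0, bottom=0.0, ic50=2.0, hill=1.0)

    def test_margins_reproduce_single_agents(self):
        m = simulate_matrix(MatrixSimSpec(hill_a=(1, 0, 1, 1), hill_b=(1, 0, 2, 1)))
        fa, fb = DoseResponseFit(**self.CA), DoseResponseFit(**self.CB)
        pred, clamped = loewe_surface(fa, fb, m)
        assert np.allclose(pred[:, 0], fa.inhibition(m.doses_a), atol=1e-9)
        assert np.allclose(pred[0, :], fb.inhibition(m.doses_b), atol=1e-9)
        assert not clamped[:, 0].any() and not clamped[0, :].any()

    def test_sham_combination_identity(self):
        """A drug split against itself predicts its own single-agent effect."""
        fit = DoseResponseFit(**self.CA)
        m = simulate_matrix(MatrixSimSpec(hill_a=(1, 0, 1, 1), hill_b=(1, 0, 1, 1)))
        pred, _ = loewe_surface(fit, fit, m)
        for i, da in enumerate(m.doses_a):
            for j, db in enumerate(m.doses_b):
                expected = fit.inhibition(da + db)
                assert pred[i, j] == pytest.approx(expected, abs=2e-6)

    def test_bisection_matches_analytic_inversion(self):
        """Closed-form Hill inversion oracle agrees with the bisection solver."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            ca = (1.0, 0.0, float(rng.uniform(0.3, 3)), float(rng.uniform(0.7, 3)))
            cb = (1.0, 0.0, float(rng.uniform(0.3, 3)), float(rng.uniform(0.7, 3)))
            fa = DoseResponseFit(top=ca[0], bottom=ca[1], ic50=ca[2], hill=ca[3])
            fb = DoseResponseFit(top=cb[0], bottom=cb[1], ic50=cb[2], hill=cb[3])
            da, db = ca[2], cb[2] / 2
            m = simulate_matrix(MatrixSimSpec(
                hill_a=ca, hill_b=cb, doses_a=(0.0, da), doses_b=(0.0, db)))
            pred, _ = loewe_surface(fa, fb, m)
            e = pred[1, 1]
            # the Loewe equation holds at the solution, via the closed form
            lhs = da / hill_inverse_dose(e, *ca) + db / hill_inverse_dose(e, *cb)
            assert lhs == pytest.approx(1.0, abs=1e-4)

    def test_excess_shape_mismatch(self):
        m = simulate_matrix(MatrixSimSpec())
        with pytest.raises(ValueError, match="match"):
            loewe_excess(m, np.zeros((2, 2)))

    def test_flat_curve_rejected(self):
        flat = DoseResponseFit(top=0.5, bottom=0.5 - 1e-9, ic50=1.0, hill=1.0)
        m = simulate_matrix(MatrixSimSpec())
        with pytest.raises(ValueError, match="flat"):
            loewe_surface(flat, DoseResponseFit(**self.CB), m)


class TestCI:
    def test_sham_identity_exact(self):
        """Same drug on both axes at (d/2, d/2) and its true fa: CI = 1."""
        me = MedianEffectFit("x", dm=1.0, m=1.3, r=1.0, n_points=5)
        for d in (0.25, 1.0, 4.0):
            fa = me.fa(d)
            assert chou_talalay_ci(me, me, d / 2, d / 2, fa) == pytest.approx(1.0, abs=1e-12)

    def test_loewe_surface_cells_have_unit_ci(self):
        """Equal-slope drugs: dose pairs on the Loewe surface give CI = 1."""
        me_a = MedianEffectFit("a", dm=1.0, m=1.5, r=1.0, n_points=5)
        me_b = MedianEffectFit("b", dm=3.0, m=1.5, r=1.0, n_points=5)
        for fa in (0.2, 0.5, 0.8):
            for frac in (0.25, 0.5, 0.75):
                da = frac * me_a.dx(fa)
                db = (1 - frac) * me_b.dx(fa)
                assert chou_talalay_ci(me_a, me_b, da, db, fa) == pytest.approx(1.0, abs=1e-6)

    def test_ci_monotone_decreasing_in_fa(self):
        me_a = MedianEffectFit("a", dm=1.0, m=1.0, r=1.0, n_points=5)
        me_b = MedianEffectFit("b", dm=2.0, m=2.0, r=1.0, n_points=5)
        cis = [chou_talalay_ci(me_a, me_b, 1.0, 1.0, fa)
               for fa in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(cis) < 0)

    def test_bounds_and_grey_quadrant_undefined(self):
        me = MedianEffectFit("x", dm=1.0, m=1.0, r=1.0, n_points=5)
        assert np.isnan(chou_talalay_ci(me, me, 1, 1, 0.0))
        assert np.isnan(chou_talalay_ci(me, me, 1, 1, 1.0))
        m = simulate_matrix(MatrixSimSpec(regime="synergy", interaction_strength=0.6))
        ci = ci_grid(me, me, m)
        inh = m.inhibition
        cap = max(inh[:, 0].max(), inh[0, :].max())
        assert np.isnan(ci[inh > cap]).all()
        assert np.isnan(ci[0, :]).all() and np.isnan(ci[:, 0]).all()

    def test_nonexclusive_form_adds_cross_term(self):
        me = MedianEffectFit("x", dm=1.0, m=1.0, r=1.0, n_points=5)
        excl = chou_talalay_ci(me, me, 0.5, 0.5, 0.5)
        nonexcl = chou_talalay_ci(me, me, 0.5, 0.5, 0.5, exclusive=False)
        assert nonexcl == pytest.approx(excl + 0.25)


class TestClassification:
    def test_planted_synergy_lowers_ci_and_raises_excess(self):
        m = simulate_matrix(MatrixSimSpec(regime="synergy", interaction_strength=0.2,
                                          noise_cv=0.02, seed=8))
        res = analyze_matrix(m)
        assert res.summary["verdict"] == "potentiation"
        interior_ci = res.ci[1:, 1:]
        defined = interior_ci[np.isfinite(interior_ci)]
        assert np.median(defined) < 1.0

    def test_additive_matrix_not_called(self):
        m = simulate_matrix(MatrixSimSpec(noise_cv=0.02, seed=8))
        res = analyze_matrix(m)
        assert res.summary["verdict"] == "no potentiation"

    def test_antagonism_called_per_cell(self):
        m = simulate_matrix(MatrixSimSpec(regime="antagonism", interaction_strength=0.3,
                                          seed=8))
        res = analyze_matrix(m)
        assert (res.calls[1:, 1:] == "antagonistic").any()
        assert res.summary["verdict"] == "no potentiation"

    def test_thresholds_applied_as_configured(self):
        m = simulate_matrix(MatrixSimSpec(noise_cv=0.0))
        res = analyze_matrix(m)
        # exact additive surface: excess 12 pp at one interior cell flips it
        res.excess[2, 2] = 12.0
        res = classify_combination(res, loewe_thresh=10.0, ci_thresh=1.0)
        assert res.calls[2, 2] == "synergy-leaning"
        res = classify_combination(res, loewe_thresh=15.0, ci_thresh=1.0)
        assert res.calls[2, 2] != "synergy-leaning"


def test_loewe_from_median_effect_curves_flag():
    """Median-effect-driven Loewe inversion matches the 4PL route for pure Hill drugs."""
    from anchorscreen import analyze_matrix as am

    m = simulate_matrix(MatrixSimSpec(hill_a=(1, 0, 1, 1.2), hill_b=(1, 0, 2, 0.9)))
    a = am(m)
    b = am(m, loewe_from_median_effect=True)
    assert np.abs(a.excess - b.excess).max() < 1.0  # pp; fits differ slightly
    assert b.summary["verdict"] == "no potentiation"


def test_bliss_surface_has_consistent_positive_loewe_excess():
    """For slope-1 Hill pairs, Bliss independence out-inhibits Loewe additivity."""
    m = simulate_matrix(MatrixSimSpec(hill_a=(1, 0, 1, 1), hill_b=(1, 0, 2, 1),
                                      regime="bliss_independent"))
    fa = DoseResponseFit(top=1, bottom=0, ic50=1, hill=1)
    fb = DoseResponseFit(top=1, bottom=0, ic50=2, hill=1)
    pred, _ = loewe_surface(fa, fb, m)
    excess = loewe_excess(m, pred)
    assert (excess[1:, 1:] > 0).all()
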