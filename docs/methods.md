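# Methods

This note records the statistical conventions the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical corner cases.

## Scoring chain (normalize)

Signals are analyzed on the natural-log scale throughout; the percent-
proliferation back-transform therefore uses `exp(·)`.

**B-score.** Per plate and replicate, a two-way Tukey median polish
decomposes the log-signal matrix into grand + row + column effects +
residuals, iterating row and column median sweeps until the change in the
sum of absolute residuals falls below `tol` (default 1e-9; `max_iter` 100;
midpoint medians for even-length vectors). The B-score is the residual
divided by `1.4826 × MAD` of the plate's residuals. The polish runs on
compound wells only by default (the control layout of a production screen
is rarely positionally balanced; a flag includes controls). Wells on
rows/columns that carry no polish data have no estimable positional effect
and receive NaN rather than an imputed score.

Two properties of median polish worth knowing:

- *Fixed points are not unique.* Different sweep histories can end at
  different (equally valid) decompositions of the same plate. Consequently
  B-scores are only **approximately** invariant to adding arbitrary
  row/column offsets: about 0.05 B-score units on a full 384-well plate,
  more on partially filled plates. The test suite asserts this at 0.25
  units. Residuals agree with R's `stats::medpolish` to machine precision
  on a reference 4×4 matrix because both use the same stopping rule.
- *Residuals are not orthogonal to the row/column subspace.* Medians, not
  means, are swept out, so the per-plate correlation between B-scores and
  any fixed row+column pattern has an irreducible noise floor (sd ≈ 0.037
  for a 16×22 compound block, independent of the pattern's amplitude and of
  the noise scale). Positional artifacts are removed in the sense that a
  raw-signal correlation of ~0.97 with an injected gradient drops to a
  median ≈ 0.02 after scoring — but individual plates can show incidental
  correlations up to ~0.1, and no median-based normalization can push every
  plate below 0.05.

**Robust Z.** `RZ = (value − median)/(1.4826 × MAD)` with the reference
population = compound-treated B-scores of the same arm, plate and replicate
(per-plate scoping matches the per-plate polish; `scope="global"` pools an
arm's plates). The 1.4826 factor is the Gaussian MAD-to-sigma consistency
constant applied to a single MAD; for multi-plate pooling,
`mad_scope="pooled"` substitutes the median of per-plate MADs. Because the
B-score already standardizes residuals, the RZ step's reference statistics
are near (0, 1/1.4826) but are recomputed — the stated order of operations
(B-score, then median/MAD, then RZ) is followed literally. A zero reference
MAD raises rather than producing infinities.

Zero/negative signals: error by default; `zero_policy="floor"` substitutes
half the smallest positive signal of the same plate/replicate.

## Hit calling and ΔRZ (hits)

A compound is a hit when RZ < −2 **strictly** in every replicate (≤ by
flag); at least two replicates are required, and compounds scored in fewer
are excluded with a logged warning, never silently dropped. ΔRZ is the
difference of replicate means (per-replicate ΔRZ is also emitted; the
choice of means is a convention — nothing downstream is sensitive to it at
two replicates). Hits are ranked by ascending ΔRZ with the combo-arm mean
RZ as tie-break. `%proliferation = exp(RZ × 1.4826 × MAD_ref) × 100`; the
reference median cancels algebraically and RZ = 0 maps to exactly 100%.

## Dose-response (dose_response)

4PL viability model `v(d) = bottom + (top−bottom)/(1+(d/IC50)^hill)`,
fitted by bounded least squares on (top, bottom, log IC50, hill) — the log
parametrization makes the fit exactly equivariant to dose-unit rescaling.
Multi-start (5 starts): a logit-linearization estimate of (IC50, hill) plus
quantile heuristics and seeded jitter; the best RSS wins and `converged` is
honest (no class is assigned to unconverged fits). Near-flat response
(range < 0.05) raises "no dose effect detectable". The reported IC50 is the
**relative** IC50 (curve inflection). Classification bands: sensitive
< 4 µmol/L, resistant > 30 µmol/L, intermediate between.

Accuracy at the study design (8 doses two-fold around the potency,
triplicate, 5% CV): median relative IC50 error ≈ 3.7%, but the error
distribution is heavy-tailed (p90 ≈ 14%), which matters near a band
boundary: a true 35 µmol/L compound fits below the 30 µmol/L resistant
boundary ~8% of the time under triplicate noise. Definitive band
classification therefore uses a pooled design (3 experiments × 6 wells per
dose), under which misclassification was not observed in 900 seeded fits.

## Synergy (synergy)

`fa = 1 − viability` relative to the double-vehicle anchor cell.

**Loewe surface.** Per cell, the additivity equation
`d_a/D_A(E) + d_b/D_B(E) = 1` is solved by bisection on E (tolerance 1e-6)
over the overlap of the two fitted curves' attainable effect ranges, with
`D_X(E)` the closed-form inverse of the 4PL fit. Cells whose additive
effect falls outside the invertible overlap are clamped to the nearest
bound and flagged. Margins reproduce the single-agent fits exactly. The
4PL fits (not the median-effect fits) drive the inversion, consistent with
excess-inhibition conventions; a flag switches to median-effect curves.
**Loewe excess** = (observed − predicted inhibition) × 100, in percentage
points.

**Chou-Talalay CI.** Median-effect fits regress `log(fa/fu)` on
`log(dose)` using margin points with fa in [0.01, 0.99] (configurable;
out-of-range cells are flagged undefined for CI, never clipped into range).
CI is the mutually exclusive two-term form by default (`exclusive=False`
adds the cross-term). CI is undefined at fa ∈ {0, 1}, on the margins, and —
the grey-quadrant rule — wherever the combination's observed effect exceeds
the maximum observed effect of both single agents.

**Calls and verdict.** Cell call "synergy-leaning" when excess > 10 pp or
CI < 1 (printed thresholds; both configurable); "antagonistic" when excess
< −10 pp without a synergy signal. The matrix verdict is deliberately
stricter than any single cell because CI fluctuates around 1 on a truly
additive matrix (≈half the cells dip below 1 under noise): *potentiation*
requires ≥ 25% of interior cells above the excess threshold **or** ≥ 75% of
defined-CI cells below the CI threshold. On simulated matrices this calls
planted 20 pp synergy and stays silent on additive noise at 3% CV.

## In-vivo statistics (invivo)

`RTV(t) = V(t)/V(day 1)` per animal (day 1 = randomization; a missing
baseline is a validation error). `TGI = (1 − mean RTV_t/mean RTV_c) × 100`
at a stated day, group means matching mean ± SEM growth-curve reporting;
negative TGI (treated growing faster) is reported as-is. The Mann-Whitney
test uses exact enumeration when both groups have ≤ 8 observations and no
cross-group ties — so the n = 7/group xenograft design always takes the
exact branch — and the tie-corrected normal approximation otherwise;
degenerate all-tied input returns p = 1 with a warning.

Fisher exact tests are computed in-package by vectorized hypergeometric
enumeration (minimum-likelihood two-sided tail, the classic convention);
this matches `scipy.stats.fisher_exact` to 1e-9 on random tables and a
pure-python enumeration on all 311,150 tables with grand total ≤ 50, while
being fast enough to run that exhaustive comparison routinely. Cell-cycle
counts are tested per phase (G1, S, G2M vs rest) with Benjamini-Hochberg
adjustment across the three phases — the test family of one experiment.
Caspase luminescence is divided by concomitant viability before
fold-changes, making results invariant to common instrument gain.

## Synthetic data (simulate)

All generators are pure functions of their spec (same seed → bit-identical
output).

**Screen.** 16×24 plates; columns 23/24 are vehicle/anchor controls (the
real screen's layout is unpublished, so it is configurable); 22 columns
carry compounds, 352 per plate, 1,200 compounds in duplicate in two arms by
default. Log-signal = base + plate offset (sd 0.1) + row/column gradients
(defaults 0.01/0.005 log units per well step) + compound effect + Gaussian
noise (sd 0.05 ≈ 5% CV, typical of luminescent viability readouts). Since a
B-scored well's RZ is ≈ its log-shift divided by the noise sd, effects are
specified in RZ units and multiplied by `noise_sd`: actives (5% of the
library) at Normal(−6, 1) clipped above at −4; anchor-potentiated compounds
(3%) get an additional combo-arm shift at Normal(−8, 3) clipped at −4; the
anchor alone shifts all combo wells by −0.1 log units (this common shift
cancels in per-arm RZ referencing). A `contamination_fraction` option draws
that fraction of wells at 5× the noise sd, stress-testing the median/MAD
chain (hit sensitivity stays ≥ 0.9 at 5% contamination). What this does
**not** emulate: spatial
autocorrelation beyond separable row/column trends, evaporation-driven
edge nonlinearity, compound fluorescence interference, or carry-over —
passing recovery tests here shows the scoring chain is correct, not that it
is robust to every plate pathology.

**Checkerboards.** True Hill curves per drug; the Loewe-additive regime
inverts the single-agent curves **numerically on fine grids** (deliberately
sharing no code with the analysis module's bisection solver, so each serves
as the other's oracle; agreement ≤ 1e-4 in effect units). Bliss multiplies
survivals; synergy/antagonism shift interior additive inhibition by
± `interaction_strength` (default 0.2). Multiplicative log-normal noise,
then re-anchoring to the (0,0) cell. Validation-style noise is 3% CV
(triplicate-averaged 5% single-well noise).

**Growth.** Baselines uniform in the 60–100 mm³ enrollment window; control
rate 0.08/day; the treated rate is
`r_c + ln(1 − inhibition)/(T − 1)`, which makes the noise-free endpoint TGI
*exactly* the target (default 0.39); measurement noise log-normal at 10%
CV; schedule twice weekly for four weeks, n = 7 per group.

## Determinism

Every stage's randomness is seeded from the pipeline config; product files
are written with fixed float formats (`%.17g` for data that must round-trip
bit-exactly, `%.10g` for derived reports) and sorted JSON keys, so reruns
under one config are byte-identical. Wall-clock timings go to `run.log`,
which is excluded from that contract.

## Problem sizes

The test suite and `scripts/acceptance.py` run the screen at its full
1,200-compound duplicate scale, 200 simulated curves for IC50 recovery,
100 random Hill pairs for the Loewe solver comparison, the exhaustive
Fisher enumeration to grand total 50, and 20 plates for the positional-
artifact diagnostic; the whole suite completes in well under a minute on a
laptop-class core.

## Known limitations

- Median-polish B-scores: approximate offset equivariance and a nonzero
  per-plate correlation floor against positional patterns (see above).
- The 4PL fit reports the relative IC50; absolute-EC50 users must invert
  the fitted curve themselves.
- CI confidence intervals (bootstrap) and ZIP/HSA/MuSyC models are out of
  scope, as are three-drug combinations and mixed-effects growth models.
- The synergy verdict thresholds (25% / 75% concordance rules) are
  pragmatic defaults for small checkerboards, not calibrated error rates.
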