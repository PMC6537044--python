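# anchorscreen

Analysis toolkit for **anchor-compound drug-combination screens** and their
follow-up experiments, built for the workflow in which a compound library is
screened on a cancer cell line **with and without a fixed "anchor" drug** to
find partners the anchor potentiates — and the winning combinations are then
validated by checkerboard synergy assays, dose-response profiling, and
xenograft efficacy studies.

It is a library first (importable API + `examples/`), with a thin
`anchorscreen` CLI for running the pipeline from a shell.

## What it computes

**Plate normalization and hit calling.** Raw per-well viability readouts are
log-transformed and **B-scored**: a two-way median polish of each plate's
log-signals removes plate, row and column effects, and the residuals are
scaled by `1.4826 × MAD` so one unit is one robust standard deviation. Each
well then gets a **robust Z-score**

    RZ = (value − median) / (1.4826 × MAD)

over the compound-treated wells of its arm, plate and replicate. A compound
is a **hit** when RZ < −2 in *every* replicate, and its anchor potentiation
is

    ΔRZ = RZ(compound + anchor) − RZ(compound alone)

(replicate means; more negative = stronger potentiation). RZ maps back to
percent proliferation via `exp(RZ × 1.4826 × MAD) × 100`.

**Dose-response.** Four-parameter logistic fits
`v(d) = bottom + (top − bottom) / (1 + (d/IC50)^hill)` with multi-start
nonlinear least squares; cell lines classify as *sensitive* (IC50 < 4 µmol/L),
*resistant* (> 30 µmol/L) or *intermediate*.

**Synergy.** Per checkerboard cell, the **Loewe excess** = observed −
Loewe-additive inhibition (the additivity equation
`d_a/D_A(E) + d_b/D_B(E) = 1` solved by bisection on the fitted single-agent
curves), and the **Chou-Talalay combination index**
`CI = d_a/Dx_a + d_b/Dx_b` from median-effect fits, with CI undefined where
the combined effect exceeds both single agents (grey-quadrant rule). Calls
use Loewe excess > 10 percentage points or CI < 1.

**In-vivo analytics.** Relative tumor volume `RTV(t) = V(t)/V(day 1)`, tumor
growth inhibition `TGI = (1 − mean RTV_treated / mean RTV_control) × 100`,
exact two-tailed Mann-Whitney on endpoint RTVs, Fisher-exact +
Benjamini-Hochberg for cell-cycle phase counts, and caspase-per-viability
fold-changes.

**Synthetic data with planted truth.** Seeded generators produce every input
the pipeline consumes: 384-well anchor screens with positional artifacts and
planted actives/potentiated compounds, checkerboards under Loewe-additive /
Bliss / synergy / antagonism regimes, and exponential xenograft growth with
a target TGI — so every stage is testable against known ground truth.

## Worked example

```bash
python examples/screen_hits.py
```

```
simulated 5312 wells on 8 plates (54 planted actives, 32 anchor-potentiated)
81 hits at RZ < -2 in both replicates

top 10 by delta-RZ (most anchor-potentiated first):
  compound  delta_RZ  %prolif combo  planted?
     C0459    -14.07            0.0       yes
     C1013    -13.79            0.0       yes
     ...
```

Every compound in the top 10 is a planted potentiation partner: ΔRZ ≈ −14
means the anchor deepened that compound's robust Z-score by fourteen robust
SDs beyond its single-agent effect. The other examples
(`dose_response_fit.py`, `synergy_checkerboard.py`, `xenograft_tgi.py`) walk
the remaining stages; `synergy_checkerboard.py`, for instance, scores an
exactly-additive matrix ("max Loewe excess 0.6 pp, median CI 1.03, no
potentiation") against one with 20 pp of planted synergy ("max excess
21.0 pp, median CI 0.39, potentiation").

Full pipeline from a shell:

```bash
anchorscreen run --out results/ --seed 1
anchorscreen simulate screen --out data/ --seed 1
anchorscreen synergy --matrix data/matrix.csv --out syn/
```

## Layout

- `src/anchorscreen/plates.py` — containers + CSV I/O (plates, dose matrices, growth tables)
- `src/anchorscreen/normalize.py` — log transform, median polish / B-score, robust Z
- `src/anchorscreen/hits.py` — hit rule, ΔRZ ranking, %proliferation back-transform
- `src/anchorscreen/dose_response.py` — 4PL fits, IC50 sensitivity bands
- `src/anchorscreen/synergy.py` — Loewe excess, median-effect CI, combination calls
- `src/anchorscreen/invivo.py` — RTV/TGI, Mann-Whitney, Fisher+BH, caspase
- `src/anchorscreen/simulate.py` — seeded generators with planted truth
- `src/anchorscreen/pipeline.py`, `cli.py` — orchestration and the thin CLI

See `docs/methods.md` for the statistical conventions, default parameters
and known limitations.
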