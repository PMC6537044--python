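"""Score a two-drug checkerboard with Loewe excess and Chou-Talalay CI.

Builds two matrices from the same pair of Hill curves — one exactly
Loewe-additive, one with 20 percentage points of planted synergy — and runs
the full analysis: 4PL fits from the zero-dose margins, bisection solution
of the Loewe additivity equation per cell, excess = observed - predicted
inhibition, and the median-effect CI at each observed effect.
"""

import numpy as np

from anchorscreen import MatrixSimSpec, analyze_matrix, simulate_matrix

for regime in ("loewe_additive", "synergy"):
    matrix = simulate_matrix(MatrixSimSpec(
        regime=regime, interaction_strength=0.2, noise_cv=0.03, seed=8))
    res = analyze_matrix(matrix)
    s = res.summary
    print(f"\n=== {regime} matrix ===")
    print(f"max Loewe excess: {s['max_loewe_excess_pp']:6.1f} pp "
          f"(threshold {s['loewe_threshold_pp']:.0f} pp)")
    print(f"median CI:        {s['median_ci']:6.2f}   "
          f"(CI < {s['ci_threshold']:.0f} leans synergy)")
    print(f"cells called:     {s['fraction_cells_called']:.0%} of "
          f"{s['n_interior_cells']} interior cells")
    print(f"verdict:          {s['verdict']}")
print("\nPositive excess = more inhibition than dose-additivity predicts; "
      "CI well below 1 at the same cells corroborates potentiation.")
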