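"""Stepwise selection of a minimal predictive index equation.

After scoring a simulated trial, regresses H on the per-index
stress/control ratios with forward-entry / backward-removal stepwise
OLS. The selected equation predicts tolerance for new genotypes from a
couple of bench measurements instead of the full index panel.
"""

import heattol as ht

pheno, _, _ = ht.generate_trial(ht.SimulationConfig(seed=7))
cm = ht.compute_coefficients(ht.aggregate_replicates(pheno))
_, scores = ht.score_matrix(cm)

model = ht.stepwise_select(scores.h, cm)
print("selected indices:", model.selected_indices)
print("equation:", model.equation())
print(f"R^2 = {model.r_squared:.3f}, F = {model.f_statistic:.1f}, "
      f"p = {model.p_value:.2e}")

# apply the saved equation to two hypothetical new genotypes
new = {ix: cm.h[ix].iloc[:2] for ix in model.selected_indices}
import pandas as pd

pred = ht.predict_h(model, pd.DataFrame(new).set_axis(["new-A", "new-B"]))
print("\npredicted H for new genotypes (unclipped, with range flag):")
print(pred.to_string())
print("\nA high R^2 with 1-2 indices means the panel can be replaced by "
      "those measurements for screening.")
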