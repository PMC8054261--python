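"""Hierarchical growth-rate model and IC50 fold-change model.

Plants known effects with the synthetic generators and shows the models
recovering them: a 0.006/h stiffness contrast (2 kPa vs 0.2 kPa substrate)
with experiment-date random effects and per-plate residual variances, and
a 1.7-fold IC50 increase under 0.1% vs 21% oxygen.
"""

from ecmscreen import (
    EffectsTableSpec,
    HierarchicalModelSpec,
    fit_hierarchical_growth_model,
    fit_ic50_difference_model,
    gen_effects_table,
)
from ecmscreen.simulation import gen_ic50_replicates

table, truth = gen_effects_table(EffectsTableSpec(seed=8))
contrast = ("plate", "Softwell 2 kPa", "Softwell 0.2 kPa")
post = fit_hierarchical_growth_model(
    table, HierarchicalModelSpec(contrasts=(contrast,), seed=8)
)
row = post["contrast[plate:Softwell 2 kPa-Softwell 0.2 kPa]"]
true_c = truth["plate_effects"]["Softwell 2 kPa"] - truth["plate_effects"]["Softwell 0.2 kPa"]
print(f"stiffness contrast: posterior mean {row['mean']:.4f} /h "
      f"(95% CI {row['ci_lo']:.4f} to {row['ci_hi']:.4f}), truth {true_c:.4f} /h")
print(f"diagnostics: R-hat {row['rhat']:.3f}, ESS {row['ess']:.0f}, "
      f"all-parameter gate converged = {post.converged}\n")

ic50s = gen_ic50_replicates(fold_change=1.7, seed=8)
post2 = fit_ic50_difference_model(ic50s, seed=8)
fold = post2["fold_change[HCT116:0.1-vs-21]"]
print(f"IC50 fold change (0.1% vs 21% O2): posterior mean {fold['mean']:.2f} "
      f"(95% CI {fold['ci_lo']:.2f} to {fold['ci_hi']:.2f}), truth 1.70")
print("A fold change > 1 with a CI excluding 1 indicates hypoxia raised the IC50,")
print("i.e. cells became more drug-resistant under low oxygen.")
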