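"""Module-level disease associations and cognitive trajectories.

Compares module eigenproteins across control / presymptomatic / symptomatic
groups (ANOVA + Tukey, adjusted for age and sex), correlates them with
clinical severity, and recovers per-subject cognitive slopes with a
random-slope mixed model.
"""

import numpy as np
import pandas as pd

from csfnet.associate import (fit_cognitive_slopes, module_group_comparison,
                              trait_correlations)
from csfnet.containers import GREY, ModuleAssignment
from csfnet.network import module_eigenproteins
from csfnet.simulate import generate_cognition, generate_discovery_cohort

matrix, metadata, truth = generate_discovery_cohort(seed=7)
assignment = ModuleAssignment({
    p: f"M{truth.membership[p]}" if truth.membership[p] else GREY
    for p in matrix.protein_ids}).relabel_by_size()
eig = module_eigenproteins(matrix, assignment)

comp = module_group_comparison(eig, metadata)
sym = comp[(comp["group_a"] == "control") & (comp["group_b"] == "symptomatic")]
print("symptomatic vs control (Tukey-adjusted):")
print(sym[["unit", "diff", "p_tukey"]].round(4).to_string(index=False))
print("Modules carrying planted disease shifts separate from controls; "
      "null modules do not.\n")

md = metadata.set_index("sample_id", drop=False)
traits = trait_correlations(eig.values, md, traits=("cdr_sb",))
print("eigenprotein ~ severity (Spearman, BH-FDR):")
print(traits[["unit", "rho", "p", "q"]].round(4).to_string(index=False))

cog = generate_cognition(metadata, truth, resid_sd=0.3, n_visits=4, seed=1)
est = fit_cognitive_slopes(cog, metadata)
joined = pd.concat([est.slopes, truth.true_slopes], axis=1).dropna()
r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
print(f"\nmixed-model slopes vs planted truth: r = {r:.3f} "
      f"({len(joined)} subjects, method = {est.method})")
print("Slopes are annual change in the global cognitive z-score; the "
      "correlation shows the model recovers individual decline rates.")
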