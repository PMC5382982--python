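"""Group inference on graph metrics: mixed ANOVA on a global measure and
per-node AUC t-tests with FDR correction.
"""

import numpy as np
import pandas as pd

from rsnet import (
    CohortSpec, EffectSpec, GroupDesign, SparsityGrid, default_effect_blocks,
    generate_cohort, mixed_anova_global, nodal_auc_ttests, pearson_matrix,
    preprocess_subject, threshold_series,
)
from rsnet.metrics import clustering_coefficient, node_degree

spec = CohortSpec(n_lesion=8, n_sham=8, n_nodes=60, n_hemisphere=30, n_volumes=450, seed=4)
reduced, increased = default_effect_blocks(spec)
effect = EffectSpec(reduced_block=reduced, increased_block=increased,
                    reduction_factor=0.5, increase_factor=1.3)
subjects = generate_cohort(spec, effect)
mats = [pearson_matrix(preprocess_subject(s.ts, s.nuisance, target=300)) for s in subjects]
design = GroupDesign.from_subjects(subjects)
grid = SparsityGrid.default()

# global layer: mean clustering across the sparsity grid
rows, aucs = [], {}
for cm in mats:
    degs = []
    for g in threshold_series(cm, grid):
        rows.append({"subject": cm.subject_id, "group": cm.group,
                     "sparsity": g.sparsity,
                     "value": float(clustering_coefficient(g).mean())})
        degs.append(node_degree(g))
    aucs[cm.subject_id] = np.trapezoid(np.array(degs), grid.as_array(), axis=0)

res = mixed_anova_global(pd.DataFrame(rows))
print(res.table[["Source", "F", "p_unc"]].to_string(index=False))
# Sparsity dominates every global metric (thresholding mechanically
# changes topology); a unilateral planted effect typically leaves the
# global group term non-significant, as in a hemispherically mixed brain.

# nodal layer: degree AUC per node
tests = nodal_auc_ttests(pd.DataFrame.from_dict(aucs, orient="index"), design)
planted = tests.loc[sorted(reduced)]
print(f"\nplanted nodes with significantly lower degree-AUC: "
      f"{int((planted.sig_uncorrected & (planted.direction == 'D')).sum())}"
      f"/{len(reduced)} (uncorrected p<0.05)")
print(f"FDR-significant nodes across the whole parcellation: {int(tests.sig_fdr.sum())}")
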