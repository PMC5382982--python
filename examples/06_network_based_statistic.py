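"""Connection-wise comparison with the network-based statistic (NBS).

Edge-wise t-tests on unthresholded correlation matrices, a primary
t-threshold, and permutation of group labels to attach family-wise
corrected p-values to connected components of affected edges.
"""

import itertools

from rsnet import (
    CohortSpec, EffectSpec, GroupDesign, default_effect_blocks, generate_cohort,
    nbs, pearson_matrix, preprocess_subject, summarize_node_involvement,
)

spec = CohortSpec(n_lesion=10, n_sham=10, n_nodes=60, n_hemisphere=30, n_volumes=450, seed=5)
reduced, increased = default_effect_blocks(spec)
effect = EffectSpec(reduced_block=reduced, increased_block=increased,
                    reduction_factor=0.5, increase_factor=1.3)
subjects = generate_cohort(spec, effect)
mats = [pearson_matrix(preprocess_subject(s.ts, s.nuisance, target=300)) for s in subjects]
design = GroupDesign.from_subjects(subjects)

res = nbs(mats, design, primary_t=3.1, n_perm=2000, tail="lesion<sham", seed=6)
print(f"suprathreshold components: {len(res.components)}")
for i, (ext, p) in enumerate(zip(res.extents, res.p_fwer)):
    flag = " *" if p < 0.05 else ""
    print(f"  component {i}: {ext} edges, p_fwer={p:.4f}{flag}")

sig = res.significant(0.05)
if sig:
    best = max(sig, key=lambda i: res.extents[i])
    found = {tuple(sorted(map(int, e))) for e in res.components[best]}
    planted = {tuple(e) for e in itertools.combinations(sorted(reduced), 2)}
    print(f"planted edges recovered: {len(found & planted)}/{len(planted)}")
    counts = summarize_node_involvement(res)
    top = counts.argsort()[::-1][:5]
    print("most affected nodes (abnormal connections):",
          {int(n): int(counts[n]) for n in top})
# The significant component should concentrate on the reduced block:
# its nodes carry the most abnormal connections, mirroring how NBS
# pinpoints lesion-affected circuitry without testing each edge alone.
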