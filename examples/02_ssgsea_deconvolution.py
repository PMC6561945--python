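"""Score leukocyte signatures per sample with ssGSEA and compare post vs pre.

The paired contrast shows whether treatment shifted each immune cell
population: a fold change above 1 (ratio of anti-log-e mean enrichment
scores) with p < 0.05 marks a significant infiltration change.
"""

import icrprofiler as icp
from icrprofiler.differential import Comparison

counts, samples, truth = icp.generate_dataset(icp.SyntheticConfig(seed=1))
expr, _ = icp.normalize_pipeline(counts)

es = icp.ssgsea_matrix(expr, truth.signatures)
print(f"enrichment matrix: {es.shape[0]} signatures x {es.shape[1]} samples")

pre, post = zip(*samples.pairs())
comp = Comparison("post_vs_pre", "paired", tuple(post), tuple(pre))
for rec in icp.score_fold_change(es, comp):
    flag = " *" if rec.significant else ""
    print(f"  {rec.signature:<18} FC={rec.fold_change:5.2f} "
          f"[{rec.ci_low:.2f}, {rec.ci_high:.2f}]  p={rec.p_value:.4f}{flag}")
# The generator plants a post-treatment shift in the T_cells signature in all
# patients, so T_cells should carry a starred FC > 1; unperturbed signatures
# hover around FC = 1.
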