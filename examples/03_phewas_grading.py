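"""Mini MR-PheWAS: simulate a trait batch, run the pipeline, grade evidence.

Ten traits (two with a real causal effect, one binary) are screened against
a simulated cancer GWAS. Continuous traits are graded robust / probable /
suggestive / non-significant; binary traits are supported / not supported.
The Z matrix and its clustering order mirror the usual results heatmap.
"""

import tempfile

from mrphewas import (
    SimConfig,
    build_zmatrix,
    cluster_matrix,
    run_phewas,
    simulate_phewas,
    summarise_grading,
)

configs = {f"null_{i}": SimConfig(seed=200 + i) for i in range(7)}
configs["adiposity"] = SimConfig(seed=300, beta_causal=0.25)
configs["telomere_length"] = SimConfig(seed=301, beta_causal=-0.2)
configs["reflux_disease"] = SimConfig(seed=302, beta_causal=0.3, exposure_type="binary")

with tempfile.TemporaryDirectory() as tree:
    simulate_phewas(configs, tree)
    run = run_phewas(tree, lifetime_risk=0.04, n_boot=200, seed=5)

summary = summarise_grading(run.graded)
print(f"graded {summary.total} trait-cancer pairs "
      f"(robust threshold {run.robust_threshold:.3g})")
for label, count in sorted(summary.counts.items()):
    print(f"  {label:>16}: {count}  ({summary.percentages[label]}%)")

matrix = build_zmatrix(run.results, run.graded)
print(f"Z matrix rows (traits with evidence): {list(matrix.z.index)}")
if len(matrix.z) >= 2:
    order = cluster_matrix(matrix).row_order
    print(f"clustered row order: {order}")
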