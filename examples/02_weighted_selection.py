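"""Connectivity weighting rescues a subtle, highly connected gene.

Generates the built-in two-causal-gene benchmark: GNAS carries a strong
phenotype effect with few network partners, HDAC1 a subtle effect with many
partners. The unweighted method ranks genes by |d| and usually misses HDAC1;
multiplying each statistic by w_i = 1 + degree pushes the hub up the
ranking.
"""

from samgsr import (SimulationConfig, build_weights, generate_dataset,
                    run_selection, sam_statistics)

cfg = SimulationConfig(seed=12)
train, test, gsc, edges, (weak, strong) = generate_dataset(cfg)
weights = build_weights(edges, train.gene_ids)

print(f"connectivity weights: {weak} w={weights.for_genes([weak])[0]:.0f}, "
      f"{strong} w={weights.for_genes([strong])[0]:.0f}, "
      f"background mean={weights.weights.mean():.2f}")

stats_u = sam_statistics(train, "case", "control")
stats_w = sam_statistics(train, "case", "control", weights=weights)
for gene in (weak, strong):
    i = stats_u.indices([gene])[0]
    print(f"{gene}: d={stats_u.d[i]:+.2f}  weighted d={stats_w.d_effective[i]:+.2f}")

for name, w in (("unweighted", None), ("weighted", weights)):
    sel = run_selection(train, gsc, weights=w, c_k=0.1, alpha=0.05, B=200,
                        seed=5, case_label="case", control_label="control")
    flags = {g: g in sel.genes for g in (weak, strong)}
    print(f"{name:>10}: selected {len(sel.genes)} genes, "
          f"{weak} in core: {flags[weak]}, {strong} in core: {flags[strong]}")

# The weighted run should include the hub gene far more often across seeds;
# the strong-effect gene tops the unweighted ranking whenever its set clears
# the stage-1 screen.
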