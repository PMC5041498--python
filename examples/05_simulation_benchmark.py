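"""Small replicate benchmark of unweighted vs weighted selection.

Runs 10 paired replicates of the built-in two-causal-gene design for each
method (full study: 50 replicates, see scripts/acceptance.py) and prints the
summary table: mean model size, selection frequency of each causal gene, and
test-set error/GBS/BCM/AUPR.
"""

import pandas as pd

from samgsr import SimulationConfig, run_replicates, summarize_replicates

cfg = SimulationConfig(seed=1)
tables = [run_replicates(cfg, 10, method=m, B=100, folds=10)
          for m in ("samgsr", "weighted")]
summary = summarize_replicates(pd.concat(tables, ignore_index=True), cfg)
print(summary.to_string(index=False))

# Expected pattern: both methods find the strong-effect gene (GNAS) in most
# replicates; the weighted method finds the subtle hub gene (HDAC1) far more
# often than the unweighted one, at comparable or better test error.
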