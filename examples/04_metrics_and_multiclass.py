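"""Score probabilistic predictions and compose multi-class probabilities.

Shows the four predictive metrics (error rate at the 0.5 cutoff, GBS, BCM,
macro-AUPR) on a toy prediction table, and how two independent binary tasks
(tumor subtype and clinical stage) multiply into four-class probabilities.
"""

import pandas as pd

from samgsr import PredictionTable, compose_multiclass, evaluate

probs = pd.DataFrame({"case": [0.9, 0.8, 0.3, 0.2, 0.6],
                      "control": [0.1, 0.2, 0.7, 0.8, 0.4]},
                     index=[f"s{i}" for i in range(1, 6)])
truth = ["case", "case", "control", "control", "control"]
pt = PredictionTable(probs, truth, positive_class="case")
report = evaluate(pt)
print("binary prediction metrics:")
print(report.to_frame().to_string(index=False))
# error counts s5 (0.6 > 0.5 but truly control); GBS/BCM reward confident
# correct probabilities; AUPR rewards ranking the true class high.

subtype = pd.DataFrame({"AC": [0.6, 0.9], "SCC": [0.4, 0.1]},
                       index=["p1", "p2"])
stage = pd.DataFrame({"I": [0.7, 0.2], "II": [0.3, 0.8]},
                     index=["p1", "p2"])
four_class = compose_multiclass({"subtype": subtype, "stage": stage},
                                {"AC-I": ("AC", "I"), "AC-II": ("AC", "II"),
                                 "SCC-I": ("SCC", "I"), "SCC-II": ("SCC", "II")})
print("\ncomposed four-class probabilities (rows sum to 1):")
print(four_class.to_string())
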