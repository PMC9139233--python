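"""The statistics used to validate automated gating against expert analysis.

Demonstrates, on small hand-made inputs: per-class diagnostic metrics from
one-vs-rest confusion counts, exact (Clopper–Pearson) binomial confidence
intervals for case-level proportions, Passing–Bablok method-comparison
regression, and the dilution error rules (absolute event delta below 1000
expert events, proportionate percent error at or above).
"""

import numpy as np
import pandas as pd

from mrdflow import (
    class_metrics,
    dilution_errors,
    exact_binomial_ci,
    passing_bablok,
    pearson_r,
    status_table,
)

# Per-class metrics from one-vs-rest counts.
row = class_metrics({"TP": 980, "TN": 98_800, "FP": 120, "FN": 100})
print("Per-class metrics from TP/TN/FP/FN counts:")
print(row[["accuracy", "sensitivity", "specificity", "PPV", "NPV", "F1"]]
      .round(4).to_string(index=False))

# Exact binomial CI: 25 of 25 positive cases detected.
lo, hi = exact_binomial_ci(25, 25)
print(f"\nSensitivity 25/25 -> 100% with exact 95% CI "
      f"({100 * lo:.1f}–{100 * hi:.1f})%: even a perfect score on 25 cases "
      "cannot rule out a true sensitivity below ~86%.")

# Case-level status comparison, DNN vs expert.
dnn = [True] * 25 + [True] + [False] * 8
expert = [True] * 25 + [False] + [False] * 8
st = status_table(dnn, expert)
acc = st["accuracy"]
print(f"\n2x2 status table accuracy: {acc['value']:.1f}% "
      f"(95% CI {acc['ci'][0]:.1f}–{acc['ci'][1]:.1f}%)")

# Passing–Bablok: robust regression of one method on another.
rng = np.random.default_rng(0)
expert_counts = np.sort(rng.uniform(20, 5000, 20))
dnn_counts = 0.98 * expert_counts + rng.normal(0, 20, 20)
fit = passing_bablok(expert_counts, dnn_counts)
print(
    f"\nPassing–Bablok: slope {fit.slope:.3f} "
    f"(95% CI {fit.slope_ci[0]:.3f}–{fit.slope_ci[1]:.3f}), "
    f"intercept {fit.intercept:.1f} "
    f"(95% CI {fit.intercept_ci[0]:.1f}–{fit.intercept_ci[1]:.1f}); "
    f"Pearson r = {pearson_r(expert_counts, dnn_counts):.4f}"
)
print("A slope CI containing 1 and intercept CI containing 0 indicate the "
      "two methods are interchangeable over the tested range.")

# Dilution error rules.
rows = pd.DataFrame({
    "expert_count": [1_132_442, 492, 61],
    "dnn_count": [1_096_836, 480, 60],
})
out = dilution_errors(rows)
print("\nDilution errors (proportionate % above 1000 expert events, "
      "absolute delta below):")
print(out[["expert_count", "dnn_count", "error_type", "error"]]
      .to_string(index=False))
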