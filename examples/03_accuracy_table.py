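"""Re-derive a published screening accuracy table from printed summaries.

Given only the printed sensitivity/specificity of each positivity rule and
the endpoint group sizes, the underlying 2x2 tables are reconstructed
(round-half-up on TP and TN) and the predictive values and accuracy are
recomputed with exact Clopper-Pearson 95% intervals. Every percentage below
is a derived quantity, not a transcribed one.
"""

from sepscreen.pipeline import reproduce_table

table = reproduce_table()
view = table[table["metric"].isin(["ppv", "npv", "accuracy"])]
print(view.to_string(index=False,
                     columns=["endpoint", "rule", "metric", "tp", "fp", "fn", "tn",
                              "percent", "ci_low_percent", "ci_high_percent"]))
print("\nEach row: reconstructed counts, the derived metric as a whole percent,")
print("and its exact binomial 95% confidence interval.")
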