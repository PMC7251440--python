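"""Group statistics of decision features: means, differences, Welch t tests.

A feature can drive the classifier without being marginally significant —
the network uses edges jointly.  Comparing per-feature p values against the
decision-feature status makes that distinction visible.
"""

import plnnfc as pf
from plnnfc.pipeline import interpret_heldout

spec = pf.CohortSpec(seed=5)
ds = pf.simulate_dataset(spec)
cfg = pf.ModelConfig(layer_widths=[ds.d, 16, 8, 1], dropout_rate=0.2, epochs=150, seed=5)
cv = pf.cross_validate(ds.X, ds.y, cfg, k=5, seed=5)
dfs = pf.decision_feature_set(interpret_heldout(cv, ds.X), K=10, epsilon=0.70)

tbl = pf.group_stats(ds, dfs.features, scale="r")  # correlation-scale means
print("per-feature group means (correlation units) and Welch t test:")
print(tbl.round(4).to_string(index=False))

summary = pf.significance_summary(tbl)
print(f"\n{summary['n_significant']}/{len(tbl)} decision features significant at "
      f"p<{summary['alpha']} (uncorrected)")
summary_bh = pf.significance_summary(tbl, correct=True)
print(f"{summary_bh['n_significant']}/{len(tbl)} after Benjamini-Hochberg correction")
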