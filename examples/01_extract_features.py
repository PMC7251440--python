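"""Simulate a small cohort and extract connectivity features.

Each subject is a (T x p) ROI time-series matrix; the pipeline computes the
p x p Pearson matrix, Fisher z-transforms it, and flattens the strict upper
triangle into p(p-1)/2 edge features.
"""

import plnnfc as pf

spec = pf.CohortSpec(p=10, n_per_group=20, T=150, delta=0.4, seed=0)
series, labels = pf.sample_cohort(spec)
ds = pf.build_dataset(series, labels)

imap = pf.EdgeIndexMap(ds.p)
print(f"subjects: {ds.n}  (patients={int(ds.y.sum())}, controls={int((1 - ds.y).sum())})")
print(f"ROIs: {ds.p} -> edge features: {ds.d}  (p(p-1)/2)")
print(f"feature 0 corresponds to ROI pair {imap.pair(0)}")
print(f"first subject, first 4 Fisher-z features: {ds.X[0, :4].round(3)}")
# At the whole-brain AAL parcellation (116 ROIs) the same pipeline yields
print(f"features at p=116: {pf.EdgeIndexMap(116).n_features}")
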