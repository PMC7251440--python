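"""Exact linear interpretation of one prediction.

For a fixed instance, folding eval-time batch norm and the LeakyReLU branch
choices turns the network into sigmoid(w_hat . x + b_hat) *exactly* — the
printed residual is float rounding, not approximation error.
"""

import numpy as np
from scipy.special import expit

import plnnfc as pf

spec = pf.CohortSpec(p=12, n_per_group=40, T=150, delta=0.4, seed=2)
ds = pf.simulate_dataset(spec)
cfg = pf.ModelConfig(layer_widths=[ds.d, 12, 6, 1], dropout_rate=0.1,
                     epochs=80, learning_rate=2e-3, seed=2)
model = pf.train(ds.X, ds.y, cfg)

x = ds.X[0]
llm = pf.local_linear(model, x, subject_id=ds.subject_ids[0])
p_net = pf.forward(model, x)[0]
p_lin = expit(llm.w_hat @ x + llm.b_hat)

print(f"subject {llm.subject_id}: network p={p_net:.6f}, linear surrogate p={p_lin:.6f}")
print(f"max |logit residual| over the whole cohort: {pf.verify_faithfulness(model, ds.X):.2e}")

top = pf.export_instance_weights(llm, pf.EdgeIndexMap(ds.p), top_n=5)
print("\ntop 5 features by |weight| (positive pushes toward the patient class):")
print(top.to_string(index=False))
print(f"\nintercept b_hat = {llm.b_hat:.4f}")
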