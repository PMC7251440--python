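"""Exact local linear interpretation of the piecewise-linear network.

At evaluation time batch normalization is a fixed per-neuron affine map and
LeakyReLU is linear on each side of zero, so for a fixed input the whole
network collapses to ``logit(x) = w_hat . x + b_hat`` exactly — not an
approximation.  The fold proceeds layer by layer: BN becomes slope
``gamma / sqrt(var + eps)`` and intercept ``beta - gamma*mean/sqrt(var+eps)``,
the activation contributes a per-neuron slope (1 or alpha) chosen by the
instance's activation pattern, and the dense maps compose.

Two instances in the same activation region share the same (w_hat, b_hat);
away from region boundaries w_hat equals the gradient of the logit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import EdgeIndexMap
from .model import TrainedModel, forward_logits

__all__ = [
    "ActivationPattern",
    "BnLinearForm",
    "LocalLinearModel",
    "activation_pattern",
    "bn_linear_form",
    "local_linear",
    "verify_faithfulness",
    "export_instance_weights",
]


@dataclass
class ActivationPattern:
    """Per hidden layer: 1 where the pre-activation was >= 0 (slope-1 branch),
    0 where it was negative (slope-alpha branch).  Exactly 0 takes slope 1."""

    states: list[np.ndarray]

    def __eq__(self, other) -> bool:
        return len(self.states) == len(other.states) and all(
            np.array_equal(a, b) for a, b in zip(self.states, other.states)
        )


@dataclass
class BnLinearForm:
    """Eval-time BN as per-neuron affine maps: slope gamma_t, intercept beta_t.

    For a layer without BN both default to the identity (slope 1, intercept 0).
    """

    slopes: list[np.ndarray]
    intercepts: list[np.ndarray]


@dataclass
class LocalLinearModel:
    """The exact linear surrogate for one instance: sigmoid(w_hat.x + b_hat)
    equals the network's eval-mode output on that instance."""

    w_hat: np.ndarray
    b_hat: float
    pattern: ActivationPattern
    subject_id: str | None = None


def bn_linear_form(model: TrainedModel) -> BnLinearForm:
    """Rearrange each hidden block's BN into slope/intercept per neuron."""
    eps = model.config.bn_epsilon
    slopes, intercepts = [], []
    for l in range(model.n_layers - 1):
        p = model.bn[l]
        width = model.config.layer_widths[l + 1]
        if p is None:
            slopes.append(np.ones(width))
            intercepts.append(np.zeros(width))
        else:
            if np.any(p.running_var < 0):
                raise ValueError("negative BN running variance")
            g = p.gamma / np.sqrt(p.running_var + eps)
            slopes.append(g)
            intercepts.append(p.beta - g * p.running_mean)
    return BnLinearForm(slopes, intercepts)


def _hidden_preactivations(model: TrainedModel, x: np.ndarray) -> list[np.ndarray]:
    """Post-BN pre-activation of every hidden block for a single instance."""
    bn = bn_linear_form(model)
    a = model.standardize_input(np.asarray(x, dtype=float).ravel())
    pre = []
    alpha = model.config.leaky_slope
    for l in range(model.n_layers - 1):
        z = model.weights[l] @ a + model.biases[l]
        u = bn.slopes[l] * z + bn.intercepts[l]
        pre.append(u)
        a = np.where(u >= 0, u, alpha * u)
    return pre


def activation_pattern(model: TrainedModel, x: np.ndarray) -> ActivationPattern:
    """Branch choice per hidden neuron for instance ``x`` (eval mode)."""
    return ActivationPattern([(u >= 0).astype(np.int8) for u in _hidden_preactivations(model, x)])


def local_linear(
    model: TrainedModel, x: np.ndarray, subject_id: str | None = None
) -> LocalLinearModel:
    """Fold BN and the instance's activation pattern into (w_hat, b_hat).

    Recursion: with the running affine ``z = A x + c`` entering hidden block
    l, the block a = r * (g * z + t) followed by the next dense layer gives
    ``A' = W diag(r*g) A`` and ``c' = W (r*g*c + r*t) + b``.  The output
    layer has neither BN nor activation.  Any input standardization is
    folded into the first dense layer so (w_hat, b_hat) act on raw features.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.config.d:
        raise ValueError(f"expected {model.config.d} features, got {x.size}")
    bn = bn_linear_form(model)
    pattern = activation_pattern(model, x)
    alpha = model.config.leaky_slope

    A = model.weights[0]
    c = model.biases[0].copy()
    if model.feature_mean is not None:
        A = A / model.feature_scale
        c = c - model.weights[0] @ (model.feature_mean / model.feature_scale)

    for l in range(model.n_layers - 1):
        g, t = bn.slopes[l], bn.intercepts[l]
        r = np.where(pattern.states[l] == 1, 1.0, alpha)
        rg = r * g
        A = rg[:, None] * A
        c = rg * c + r * t
        W, b = model.weights[l + 1], model.biases[l + 1]
        A = W @ A
        c = W @ c + b
    w_hat = A[0]
    b_hat = float(c[0])
    return LocalLinearModel(w_hat=w_hat, b_hat=b_hat, pattern=pattern, subject_id=subject_id)


def verify_faithfulness(model: TrainedModel, X: np.ndarray) -> float:
    """Max absolute difference between the network logit and the folded
    linear form over all rows of ``X``.  Should be at float precision."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    logits = forward_logits(model, X)
    resid = 0.0
    for i in range(X.shape[0]):
        llm = local_linear(model, X[i])
        resid = max(resid, abs(float(llm.w_hat @ X[i] + llm.b_hat) - float(logits[i])))
    return resid


def export_instance_weights(
    llm: LocalLinearModel, index_map: EdgeIndexMap, top_n: int | None = None
) -> pd.DataFrame:
    """Table of (feature index, ROI pair, weight) sorted by |weight| descending,
    ties broken by feature index ascending."""
    w = llm.w_hat
    if index_map.n_features != w.size:
        raise ValueError("edge-index map does not match weight vector length")
    order = np.lexsort((np.arange(w.size), -np.abs(w)))
    if top_n is not None:
        order = order[: max(0, min(top_n, w.size))]
    rows = [index_map.pair(int(k)) for k in order]
    return pd.DataFrame(
        {
            "k": order,
            "roi_i": [r[0] for r in rows],
            "roi_j": [r[1] for r in rows],
            "weight": w[order],
        }
    ).reset_index(drop=True)
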