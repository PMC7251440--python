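"""Piecewise-linear fully connected classifier (fc-BN-LeakyReLU blocks).

The network is a stack of hidden blocks, each a dense layer followed by
batch normalization and a LeakyReLU activation (dropout after each block
during training only), closed by a single dense output unit with a sigmoid.
Every activation is piecewise linear, so at evaluation time the network is
an exact linear classifier within each activation region — the property the
:mod:`plnnfc.linearize` module exploits.

Implemented directly on NumPy: the models are small (tens of hidden units),
training is Adam on binary cross-entropy, and keeping everything in float64
makes the linearization residuals tight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ModelConfig", "TrainedModel", "init_model", "forward", "forward_logits", "train"]


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    ``layer_widths`` runs input -> hidden blocks -> single output unit, e.g.
    ``[6670, 64, 32, 1]``.  ``dropout_rate`` is the probability of *dropping*
    a unit.  ``leaky_slope`` is the LeakyReLU slope for negative inputs; it
    enters the folded linear weights, so it is explicit here.
    """

    layer_widths: list[int]
    leaky_slope: float = 0.01
    dropout_rate: float = 0.8
    use_bn: bool = True
    bn_epsilon: float = 1e-5
    bn_momentum: float = 0.1
    learning_rate: float = 5e-4
    epochs: int = 200
    batch_size: int = 32
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        widths = [int(w) for w in self.layer_widths]
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        if any(w <= 0 for w in widths):
            raise ValueError("layer widths must be positive")
        if widths[-1] != 1:
            raise ValueError("output layer must have exactly 1 unit")
        self.layer_widths = widths
        if not 0.0 <= self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must be in [0, 1)")
        if self.leaky_slope == 0.0:
            warnings.warn(
                "leaky_slope=0 reduces LeakyReLU to ReLU; the linear "
                "interpretation remains valid but dead units carry zero weight",
                stacklevel=2,
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def n_hidden(self) -> int:
        return len(self.layer_widths) - 2

    @property
    def d(self) -> int:
        return self.layer_widths[0]


@dataclass
class BatchNormParams:
    """Per-neuron BN parameters and running statistics (eval-time affine map)."""

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray


@dataclass
class TrainedModel:
    """Dense weights/biases per layer plus BN state per hidden block.

    ``weights[l]`` has shape (m, n) mapping layer l (n units) to layer l+1
    (m units); ``bn[l]`` is ``None`` for the output layer and, when
    ``config.use_bn`` is off, for every layer.  Optional feature
    standardization (mean/scale) is stored so interpretation can fold it
    back into original feature units.
    """

    config: ModelConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    bn: list[BatchNormParams | None]
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        widths = self.config.layer_widths
        for l, W in enumerate(self.weights):
            if W.shape != (widths[l + 1], widths[l]):
                raise ValueError(
                    f"layer {l}: weight shape {W.shape} != {(widths[l + 1], widths[l])}"
                )
        for p in self.bn:
            if p is not None and np.any(p.running_var < 0):
                raise ValueError("negative BN running variance")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def standardize_input(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_scale


def init_model(config: ModelConfig, seed: int | None = None) -> TrainedModel:
    """He-style initialization, deterministic under ``seed``.

    BN starts as the identity map (gamma=1, beta=0, running mean 0, var 1).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    widths = config.layer_widths
    weights, biases, bn = [], [], []
    for l in range(len(widths) - 1):
        n_in, n_out = widths[l], widths[l + 1]
        weights.append(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
        is_hidden = l < len(widths) - 2
        if is_hidden and config.use_bn:
            bn.append(
                BatchNormParams(
                    gamma=np.ones(n_out),
                    beta=np.zeros(n_out),
                    running_mean=np.zeros(n_out),
                    running_var=np.ones(n_out),
                )
            )
        else:
            bn.append(None)
    return TrainedModel(config=config, weights=weights, biases=biases, bn=bn)


def _leaky(u: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(u >= 0, u, alpha * u)


def forward_logits(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Eval-mode pre-sigmoid output, one logit per row of ``X``.

    Dropout is inactive; BN uses running statistics, i.e. a fixed per-neuron
    affine map.  Deterministic function of (model, X).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    if X.shape[1] != model.config.d:
        raise ValueError(f"expected {model.config.d} features, got {X.shape[1]}")
    a = model.standardize_input(X)
    cfg = model.config
    for l in range(model.n_layers):
        z = a @ model.weights[l].T + model.biases[l]
        if l < model.n_layers - 1:  # hidden block
            p = model.bn[l]
            if p is not None:
                z = p.gamma * (z - p.running_mean) / np.sqrt(
                    p.running_var + cfg.bn_epsilon
                ) + p.beta
            a = _leaky(z, cfg.leaky_slope)
        else:
            a = z
    return a[:, 0]


def forward(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Eval-mode predicted probability of the positive class."""
    from scipy.special import expit

    return expit(forward_logits(model, X))


def _bce_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; returns (mean loss, dL/dlogit)."""
    from scipy.special import expit

    p = expit(logits)
    # log-sum-exp form avoids log(0)
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    return loss, (p - y) / y.size


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the network with Adam on binary cross-entropy.

    Training-mode forward uses batch BN statistics and inverted dropout;
    running BN statistics are updated with exponential momentum and used at
    evaluation time.  Reproducible for a fixed config seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    cfg = config
    model = init_model(cfg)
    if cfg.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        model.feature_mean, model.feature_scale = mu, sd
    Xs = model.standardize_input(X)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    nL = model.n_layers
    params = []
    for l in range(nL):
        params += [model.weights[l], model.biases[l]]
        if model.bn[l] is not None:
            params += [model.bn[l].gamma, model.bn[l].beta]
    opt = _Adam([p.shape for p in params], cfg.learning_rate)

    n = Xs.shape[0]
    keep = 1.0 - cfg.dropout_rate
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if idx.size < 2:
                continue  # batch BN needs >1 sample
            a = Xs[idx]
            yb = y[idx]
            cache = []
            # ---- forward (train mode) ----
            for l in range(nL):
                z = a @ model.weights[l].T + model.biases[l]
                st = {"a_in": a, "z": z}
                if l < nL - 1:
                    p = model.bn[l]
                    if p is not None:
                        mu = z.mean(axis=0)
                        var = z.var(axis=0)
                        inv = 1.0 / np.sqrt(var + cfg.bn_epsilon)
                        xhat = (z - mu) * inv
                        zbn = p.gamma * xhat + p.beta
                        st.update(xhat=xhat, inv=inv)
                        B = z.shape[0]
                        m = cfg.bn_momentum
                        p.running_mean = (1 - m) * p.running_mean + m * mu
                        p.running_var = (1 - m) * p.running_var + m * var * B / max(B - 1, 1)
                    else:
                        zbn = z
                    act = _leaky(zbn, cfg.leaky_slope)
                    st["slope"] = np.where(zbn >= 0, 1.0, cfg.leaky_slope)
                    if cfg.dropout_rate > 0:
                        mask = (rng.random(act.shape) < keep) / keep
                        act = act * mask
                        st["mask"] = mask
                    a = act
                else:
                    a = z
                cache.append(st)
            logits = a[:, 0]
            loss, dlogit = _bce_grad(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}; reduce learning rate"
                )
            epoch_loss += loss * idx.size
            # ---- backward ----
            grads = {id(p): np.zeros_like(p) for p in params}
            da = dlogit[:, None]  # grad wrt output of last layer
            for l in range(nL - 1, -1, -1):
                st = cache[l]
                if l < nL - 1:
                    if "mask" in st:
                        da = da * st["mask"]
                    dzbn = da * st["slope"]
                    p = model.bn[l]
                    if p is not None:
                        xhat, inv = st["xhat"], st["inv"]
                        B = xhat.shape[0]
                        grads[id(p.gamma)] += (dzbn * xhat).sum(axis=0)
                        grads[id(p.beta)] += dzbn.sum(axis=0)
                        dxhat = dzbn * p.gamma
                        dz = (
                            inv
                            / B
                            * (
                                B * dxhat
                                - dxhat.sum(axis=0)
                                - xhat * (dxhat * xhat).sum(axis=0)
                            )
                        )
                    else:
                        dz = dzbn
                else:
                    dz = da
                grads[id(model.weights[l])] += dz.T @ st["a_in"]
                grads[id(model.biases[l])] += dz.sum(axis=0)
                da = dz @ model.weights[l]
            opt.step(params, [grads[id(p)] for p in params])
        history.append(epoch_loss / n)
        if verbose and (epoch % 20 == 0 or epoch == cfg.epochs - 1):
            print(f"epoch {epoch:4d}  loss {history[-1]:.4f}")
    model.loss_history = history  # type: ignore[attr-defined]
    return model
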