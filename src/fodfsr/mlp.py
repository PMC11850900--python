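"""The DSR network: a dense net mapping LR SH patches to HR SH blocks.

Architecture: ``input -> [dense -> batch-norm -> ReLU] x len(hidden) ->
dense`` with no output activation.  The default (1188 -> 3 x 1000 -> 352)
has 3,549,352 trainable parameters counting weights, biases, and the two
trainable batch-norm parameters per hidden unit — 3.5 million at coarse
precision.  Training minimizes mean squared error with Adam.

Implemented directly in numpy: forward, backpropagation (including the
batch-norm gradient), and the Adam update are a few dozen lines each,
which keeps the model dependency-free and bit-reproducible under a seed.
Batch statistics are used during training and exponential running averages
during inference, the standard batch-norm convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DSRModelSpec", "TrainConfig", "DSRModel", "count_parameters",
           "train_dsr", "apply_dsr"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1  # running = (1 - m) * running + m * batch


@dataclass(frozen=True)
class DSRModelSpec:
    """Layer widths of the dense super-resolution network."""

    input_dim: int = 27 * 44
    hidden: tuple[int, ...] = (1000, 1000, 1000)
    output_dim: int = 8 * 44

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("all layer widths must be >= 1")
        object.__setattr__(self, "hidden", tuple(int(h) for h in self.hidden))


@dataclass(frozen=True)
class TrainConfig:
    """MSE / Adam training schedule (defaults: batch 512, 100 epochs)."""

    batch_size: int = 512
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def count_parameters(spec: DSRModelSpec) -> int:
    """Closed-form trainable parameter count (weights + biases + 2/BN unit)."""
    total = 0
    prev = spec.input_dim
    for h in spec.hidden:
        total += prev * h + h  # dense
        total += 2 * h  # batch-norm gamma, beta
        prev = h
    total += prev * spec.output_dim + spec.output_dim
    return total


class DSRModel:
    """Dense -> BN -> ReLU blocks with a linear output layer."""

    def __init__(self, spec: DSRModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = [spec.input_dim, *spec.hidden, spec.output_dim]
        self.W, self.b = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init, suited to ReLU
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.gamma = [np.ones(h) for h in spec.hidden]
        self.beta = [np.zeros(h) for h in spec.hidden]
        self.run_mean = [np.zeros(h) for h in spec.hidden]
        self.run_var = [np.ones(h) for h in spec.hidden]

    # ---- parameter bookkeeping -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b, *self.gamma, *self.beta]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # ---- forward / backward ----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        """Returns predictions and, in training mode, the backprop cache."""
        if x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input dim {x.shape[1]} does not match model {self.spec.input_dim}"
            )
        cache = []
        h = x
        for i in range(len(self.spec.hidden)):
            z = h @ self.W[i] + self.b[i]
            if train:
                mu = z.mean(0)
                var = z.var(0)
                self.run_mean[i] = (1 - _BN_MOMENTUM) * self.run_mean[i] + _BN_MOMENTUM * mu
                self.run_var[i] = (1 - _BN_MOMENTUM) * self.run_var[i] + _BN_MOMENTUM * var
            else:
                mu, var = self.run_mean[i], self.run_var[i]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_std
            pre = self.gamma[i] * zhat + self.beta[i]
            out = np.maximum(pre, 0.0)
            cache.append((h, zhat, inv_std, pre))
            h = out
        y = h @ self.W[-1] + self.b[-1]
        return (y, (cache, h)) if train else y

    def _backward(self, x, y_pred, y_true, cache):
        """Gradient of the MSE loss; returns grads aligned with parameters()."""
        caches, h_last = cache
        n = len(x)
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        gg = [None] * len(self.gamma)
        gB = [None] * len(self.beta)

        d = 2.0 * (y_pred - y_true) / (n * y_true.shape[1])  # dL/dy
        gW[-1] = h_last.T @ d
        gb[-1] = d.sum(0)
        d = d @ self.W[-1].T
        for i in reversed(range(len(self.spec.hidden))):
            h_in, zhat, inv_std, pre = caches[i]
            d = d * (pre > 0)  # ReLU
            gg[i] = (d * zhat).sum(0)
            gB[i] = d.sum(0)
            # batch-norm backprop (batch statistics)
            dzhat = d * self.gamma[i]
            m = d.shape[0]
            dz = (inv_std / m) * (
                m * dzhat - dzhat.sum(0) - zhat * (dzhat * zhat).sum(0)
            )
            gW[i] = h_in.T @ dz
            gb[i] = dz.sum(0)
            d = dz @ self.W[i].T
        return [*gW, *gb, *gg, *gB]

    # ---- persistence -----------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
            for i, arr in enumerate(getattr(self, name)):
                arrays[f"{name}{i}"] = arr
        np.savez(directory / "weights.npz", **arrays)
        (directory / "model.json").write_text(
            json.dumps(
                {
                    "input_dim": self.spec.input_dim,
                    "hidden": list(self.spec.hidden),
                    "output_dim": self.spec.output_dim,
                }
            )
        )

    @classmethod
    def load(cls, directory) -> "DSRModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        spec = DSRModelSpec(meta["input_dim"], tuple(meta["hidden"]), meta["output_dim"])
        model = cls(spec)
        with np.load(directory / "weights.npz") as data:
            for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
                setattr(
                    model,
                    name,
                    [data[f"{name}{i}"] for i in range(len(getattr(model, name)))],
                )
        return model


def train_dsr(
    inputs: np.ndarray,
    targets: np.ndarray,
    spec: DSRModelSpec | None = None,
    cfg: TrainConfig | None = None,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[DSRModel, dict]:
    """Train the network; returns the model and a loss-history log.

    Fully deterministic for a fixed ``cfg.seed`` (initialization and
    mini-batch shuffling both derive from it).  Batches of size 1 are
    skipped during training because batch statistics degenerate.
    """
    if len(inputs) == 0:
        raise ValueError("empty training set")
    spec = spec or DSRModelSpec(inputs.shape[1], (1000, 1000, 1000), targets.shape[1])
    cfg = cfg or TrainConfig()
    model = DSRModel(spec, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)

    params = model.parameters()
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    step = 0
    history: dict[str, list[float]] = {"train_mse": [], "val_mse": []}

    for _ in range(cfg.epochs):
        order = rng.permutation(len(inputs))
        losses, weights = [], []
        for start in range(0, len(inputs), cfg.batch_size):
            batch = order[start: start + cfg.batch_size]
            if len(batch) < 2:
                continue
            x, y = inputs[batch], targets[batch]
            y_pred, cache = model.forward(x, train=True)
            losses.append(float(np.mean((y_pred - y) ** 2)))
            weights.append(len(batch))
            grads = model._backward(x, y_pred, y, cache)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**step) / (1 - cfg.beta1**step)
            for p, g, m, v in zip(model.parameters(), grads, m_t, v_t):
                m *= cfg.beta1
                m += (1 - cfg.beta1) * g
                v *= cfg.beta2
                v += (1 - cfg.beta2) * g * g
                p -= lr_t * m / (np.sqrt(v) + cfg.adam_eps)
        history["train_mse"].append(float(np.average(losses, weights=weights)))
        if val is not None:
            pred = model.forward(val[0])
            history["val_mse"].append(float(np.mean((pred - val[1]) ** 2)))
    return model, history


def apply_dsr(
    model: DSRModel,
    lr_sh: np.ndarray,
    mask: np.ndarray | None = None,
    batch_size: int = 4096,
) -> np.ndarray:
    """Upsample a normalized SH volume to doubled resolution.

    Each masked LR voxel's 3x3x3 neighborhood is pushed through the network
    and the 352-vector prediction is scattered to the voxel's HR 2x2x2
    block; HR voxels of unmasked LR voxels stay zero.
    """
    from .patches import blocks_to_volume, extract_inputs

    if mask is None:
        mask = np.ones(lr_sh.shape[:3], dtype=bool)
    n_coef = lr_sh.shape[3]
    if model.spec.input_dim != 27 * n_coef:
        raise ValueError("model input dim does not match 27 x coefficient count")
    rows, idx = extract_inputs(lr_sh, mask)
    preds = np.concatenate(
        [model.forward(rows[i: i + batch_size]) for i in range(0, len(rows), batch_size)]
    ) if len(rows) else np.zeros((0, model.spec.output_dim))
    return blocks_to_volume(preds, idx, lr_sh.shape[:3], n_coef)
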