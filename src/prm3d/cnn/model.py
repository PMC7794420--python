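"""The 9-layer 3D CNN for COPD vs non-COPD classification.

Three conv → batch-norm → ReLU → max-pool blocks (3×3×3 kernels, filters
32/64/128, 2×2×2 pooling: 32³ → 16³ → 8³ → 4³) followed by fully connected
layers 128 → 128 → 2 (ReLU on the first two) and a softmax.  All conv and
dense weights are initialised from a normal with mean 0 and standard
deviation 0.1, biases at zero.

With one input channel the model carries 1,343,490 trainable parameters:
conv 896 + 55,360 + 221,312, batch-norm 448, dense 1,048,704 + 16,512 + 258.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from ..preprocess import NetworkInput
from .layers import (
    Adam,
    BatchNorm3d,
    Conv3d,
    Dense,
    Flatten,
    Layer,
    MaxPool3d,
    ReLU,
    softmax,
)

FILTERS = (32, 64, 128)
DENSE_UNITS = (128, 128, 2)
INIT_SD = 0.1


class CNN3D:
    """9-layer volumetric classifier (see module docstring)."""

    def __init__(self, input_channels: int = 1, seed: int = 0):
        if input_channels not in (1, 2):
            raise ValueError(f"input_channels must be 1 or 2, got {input_channels}")
        self.input_channels = input_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[Layer] = []
        c = input_channels
        for i, f in enumerate(FILTERS):
            # the first conv sits on the raw input and never needs dx
            layers += [Conv3d(c, f, rng, INIT_SD, need_input_grad=i > 0),
                       BatchNorm3d(f), ReLU(), MaxPool3d()]
            c = f
        layers.append(Flatten())
        n_in = 4 * 4 * 4 * FILTERS[-1]
        layers += [Dense(n_in, DENSE_UNITS[0], rng, INIT_SD), ReLU(),
                   Dense(DENSE_UNITS[0], DENSE_UNITS[1], rng, INIT_SD), ReLU(),
                   Dense(DENSE_UNITS[1], DENSE_UNITS[2], rng, INIT_SD)]
        self.layers = layers
        #: index of the third conv block's ReLU output (Grad-CAM tap, 8³×128)
        self.cam_layer_index = 10

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True,
                retain_activations: bool = False) -> np.ndarray:
        """Logits for a channels-last batch (N, 32, 32, 32, C).

        ``retain_activations`` keeps every intermediate activation on the
        model (needed by Grad-CAM); off by default, since the stack is large.
        """
        if x.ndim != 5 or x.shape[-1] != self.input_channels:
            raise ValueError(
                f"expected (N, 32, 32, 32, {self.input_channels}), got {x.shape}"
            )
        out = x.astype(np.float32)
        self._activations = [out] if retain_activations else None
        for layer in self.layers:
            out = layer.forward(out, train=train)
            if retain_activations:
                self._activations.append(out)
        return out

    def backward(self, dlogits: np.ndarray, until_layer: int = 0) -> np.ndarray:
        """Backpropagate; stops early (returning d(activation)) if requested."""
        d = dlogits.astype(np.float32)
        for i in range(len(self.layers) - 1, until_layer - 1, -1):
            d = self.layers[i].backward(d)
        return d

    def recalibrate_batchnorm(self, x: np.ndarray, batch_size: int = 25) -> None:
        """Re-estimate BN population statistics with one pass at fixed weights.

        The momentum running averages trail the weights when training is
        short; this replaces them with the exact batch-statistic averages
        (law of total variance across batches) so that eval-mode inference
        sees the activation distribution the final weights actually produce.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm3d)]
        for bn in bns:
            bn._collect = []
        for start in range(0, len(x), batch_size):
            self.forward(x[start:start + batch_size], train=True)
        for bn in bns:
            means = np.stack([m for m, _ in bn._collect])
            varis = np.stack([v for _, v in bn._collect])
            bn.running_mean[...] = means.mean(axis=0)
            bn.running_var[...] = varis.mean(axis=0) + means.var(axis=0)
            bn._collect = None

    def predict_proba(self, x: np.ndarray, batch_size: int = 25) -> np.ndarray:
        """Class probabilities (N, 2) in eval mode; columns (non-COPD, COPD).

        Processed in chunks to bound the activation memory.
        """
        out = [
            softmax(self.forward(x[i:i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        self.clear_caches()
        return np.concatenate(out)

    def clear_caches(self) -> None:
        """Drop per-layer forward caches (they hold full-size activations)."""
        for layer in self.layers:
            for attr in ("_cols", "_cache", "_arg", "_x", "_mask"):
                if hasattr(layer, attr):
                    setattr(layer, attr, None)
        self._activations = None

    # -- persistence --------------------------------------------------------
    def state(self) -> dict:
        return {
            "input_channels": self.input_channels,
            "seed": self.seed,
            "params": [p.copy() for p in self.params()],
            "running": [
                (l.running_mean.copy(), l.running_var.copy())
                for l in self.layers
                if isinstance(l, BatchNorm3d)
            ],
        }

    def load_state(self, state: dict) -> None:
        for p, saved in zip(self.params(), state["params"]):
            p[...] = saved
        bns = [l for l in self.layers if isinstance(l, BatchNorm3d)]
        for bn, (rm, rv) in zip(bns, state["running"]):
            bn.running_mean[...] = rm
            bn.running_var[...] = rv

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self.state(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "CNN3D":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(state["input_channels"], state["seed"])
        model.load_state(state)
        return model


def build_model(input_channels: int = 1, seed: int = 0) -> CNN3D:
    """Construct the classifier with seeded N(0, 0.1) weight initialisation."""
    return CNN3D(input_channels=input_channels, seed=seed)


def stack_inputs(inputs: list[NetworkInput]) -> tuple[np.ndarray, np.ndarray]:
    """Stack NetworkInputs into a channels-last batch plus a label vector."""
    x = np.stack([inp.values for inp in inputs]).transpose(0, 2, 3, 4, 1)
    labels = np.array(
        [-1 if inp.label is None else inp.label for inp in inputs], dtype=np.int64
    )
    return np.ascontiguousarray(x, dtype=np.float32), labels


def predict(model: CNN3D, x: NetworkInput | list[NetworkInput]) -> np.ndarray:
    """Softmax class probabilities; (2,) for one input, (N, 2) for a batch."""
    single = isinstance(x, NetworkInput)
    batch, _ = stack_inputs([x] if single else x)
    probs = model.predict_proba(batch)
    return probs[0] if single else probs
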