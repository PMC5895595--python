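"""Sequential container, softmax, and the softmax cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .layers import Layer


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted for stability."""
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def softmax_ce(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, dlogits)``; the gradient is already divided by the
    batch size so it feeds straight into ``Sequential.backward``.
    """
    n = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1))
    loss = float(np.mean(logz - shifted[np.arange(n), labels]))
    dlogits = softmax(logits)
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Sequential:
    """An ordered stack of layers with shared forward/backward plumbing.

    The final dense layer emits logits; ``predict_proba`` applies the
    terminal softmax.  Weight snapshots (``get_weights``/``set_weights``)
    are used by the trainer to retain the best-validation epoch.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple):
        self.layers = layers
        self.input_shape = tuple(input_shape)  # (H, W, C) or (D,)
        for layer in layers:
            if hasattr(layer, "skip_input_grad"):
                layer.skip_input_grad = False
        if layers and hasattr(layers[0], "skip_input_grad"):
            layers[0].skip_input_grad = True

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [softmax(self.forward(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    # -- parameter plumbing -------------------------------------------------
    def trainable_params(self):
        ps, gs = [], []
        for layer in self.layers:
            if layer.trainable:
                ps.extend(layer.params)
                gs.extend(layer.grads)
        return ps, gs

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                np.copyto(p, weights[i])
                i += 1
        if i != len(weights):
            raise ValueError("weight list does not match architecture")

    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    # -- introspection ------------------------------------------------------
    def summary(self) -> list[dict]:
        """Layer-by-layer description (name, type, output shape)."""
        shape = (1, *self.input_shape)
        rows = []
        for layer in self.layers:
            shape = layer.output_shape(shape)
            rows.append({"name": layer.name,
                         "type": type(layer).__name__,
                         "output_shape": list(shape[1:])})
        return rows

    def output_shape(self) -> tuple:
        shape = (1, *self.input_shape)
        for layer in self.layers:
            shape = layer.output_shape(shape)
        return tuple(shape[1:])
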