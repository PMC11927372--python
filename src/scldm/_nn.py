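"""Minimal feed-forward network toolkit on numpy.

Dense ReLU networks with hand-written reverse-mode gradients and an Adam
optimizer. Parameters live in flat ``dict[str, ndarray]`` maps so that
checkpointing (``np.savez``) and EMA shadow tracking are trivial.

The networks here are deliberately small (latent-space MLPs); no
convolutions, no autodiff graph.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


def init_mlp(sizes: list[int], rng: np.random.Generator, name: str = "mlp") -> Params:
    """He-initialised dense stack ``sizes[0] -> ... -> sizes[-1]``.

    Hidden layers use ReLU; the final layer is linear.
    """
    if len(sizes) < 2:
        raise ValueError("need at least input and output sizes")
    params: Params = {}
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        std = np.sqrt(2.0 / fan_in)
        params[f"{name}.W{i}"] = rng.normal(0.0, std, size=(fan_in, fan_out))
        params[f"{name}.b{i}"] = np.zeros(fan_out)
    return params


def n_layers(params: Params, name: str) -> int:
    return sum(1 for k in params if k.startswith(f"{name}.W"))


def mlp_forward(params: Params, x: np.ndarray, name: str = "mlp"):
    """Forward pass. Returns ``(output, cache)``; cache feeds mlp_backward."""
    L = n_layers(params, name)
    inputs = []
    h = x
    for i in range(L):
        inputs.append(h)
        h = h @ params[f"{name}.W{i}"] + params[f"{name}.b{i}"]
        if i < L - 1:
            h = np.maximum(h, 0.0)
    return h, inputs


def mlp_backward(params: Params, inputs: list[np.ndarray], grad_out: np.ndarray,
                 name: str = "mlp"):
    """Gradients of a scalar loss w.r.t. params and the input.

    ``grad_out`` is dLoss/dOutput. Returns ``(grads, grad_input)``.
    """
    L = n_layers(params, name)
    grads: Params = {}
    g = grad_out
    for i in reversed(range(L)):
        x_in = inputs[i]
        grads[f"{name}.W{i}"] = x_in.T @ g
        grads[f"{name}.b{i}"] = g.sum(axis=0)
        g = g @ params[f"{name}.W{i}"].T
        if i > 0:
            # ReLU mask: inputs[i] is the post-activation output of layer i-1
            g = g * (inputs[i] > 0)
    return grads, g


class Adam:
    """Adam optimizer over a flat parameter dict (in-place updates)."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def clone_params(params: Params) -> Params:
    return {k: v.copy() for k, v in params.items()}
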