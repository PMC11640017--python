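"""Minimal fully connected network with manual backprop and Adam.

The survival objectives in this package only need gradients of a loss with
respect to the network *outputs*; each estimator supplies that gradient
analytically and this module handles the chain rule through the hidden
layers.  ReLU activations, inverted dropout, He initialisation.  Everything
is plain numpy so training is deterministic given the generator passed in.
"""

from __future__ import annotations

import numpy as np


class MLP:
    def __init__(self, n_in: int, n_out: int, n_layers: int, n_nodes: int,
                 dropout: float, rng: np.random.Generator):
        self.dropout = float(dropout)
        sizes = [n_in] + [n_nodes] * n_layers + [n_out]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Returns (outputs, cache); cache feeds backward()."""
        a = X
        acts, masks = [X], []
        n_hidden = len(self.W) - 1
        for i in range(n_hidden):
            z = a @ self.W[i] + self.b[i]
            a = np.maximum(z, 0.0)
            if training and self.dropout > 0.0:
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(a)
        out = a @ self.W[-1] + self.b[-1]
        return out, (acts, masks)

    def backward(self, cache, dout: np.ndarray):
        """Gradients of the loss w.r.t. all weights, given dL/doutput."""
        acts, masks = cache
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        gW[-1] = acts[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        for i in range(len(self.W) - 2, -1, -1):
            delta = delta @ self.W[i + 1].T
            if masks[i] is not None:
                delta = delta * masks[i]
            delta = delta * (acts[i + 1] > 0.0)
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
        return gW, gb

    def params(self):
        return self.W + self.b

    def set_flat(self, flats):
        k = len(self.W)
        self.W = [np.asarray(f) for f in flats[:k]]
        self.b = [np.asarray(f) for f in flats[k:]]


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
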