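"""Minimal dense neural network with manual backpropagation and AdamW.

Backbone for the conditional diffusion denoiser: a dense encoder–decoder
over flattened trial segments with an additive skip connection from the
first encoder layer to the last decoder layer, SiLU activations, and a
two-layer conditioning MLP whose output is injected additively into every
hidden layer. Written directly in NumPy so that training is exactly
reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["DenoiserNet", "AdamW", "sinusoidal_embedding"]


def _silu(x: np.ndarray) -> np.ndarray:
    return x * expit(x)


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = expit(x)
    return s * (1.0 + x * (1.0 - s))


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Transformer-style sinusoidal embedding of (integer) timesteps."""
    t = np.asarray(t, dtype=float).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class DenoiserNet:
    """Dense encoder–decoder denoiser with additive conditioning.

    Layers (x flattened to ``data_dim``):

        c  = [silu(Wc2·silu(Wc1·u + bc1) + bc2), u]   u = [t-emb, class, β]
        h1 = silu(W1·x + b1 + C1·c)                   (encoder)
        h2 = silu(W2·h1 + b2 + C2·c)                  (bottleneck)
        h3 = silu(W3·h2 + b3 + C3·c)                  (decoder)
        out = W4·(h3 + h1) + b4                       (skip connection)

    The raw condition vector u is concatenated to the learned embedding
    before injection so the class/β inputs reach every layer unmediated
    regardless of how the conditioning MLP initializes.
    """

    def __init__(
        self,
        data_dim: int,
        cond_in_dim: int,
        hidden: tuple[int, int] = (256, 128),
        cond_dim: int = 64,
        seed: int = 0,
    ) -> None:
        self.data_dim = data_dim
        self.cond_in_dim = cond_in_dim
        self.hidden = hidden
        self.cond_dim = cond_dim
        rng = np.random.default_rng(seed)
        d1, d2 = hidden

        def init(n_in: int, n_out: int) -> np.ndarray:
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

        ca = cond_dim + cond_in_dim  # learned embedding ⊕ raw condition
        self.params = {
            "Wc1": init(cond_in_dim, cond_dim), "bc1": np.zeros(cond_dim),
            "Wc2": init(cond_dim, cond_dim), "bc2": np.zeros(cond_dim),
            "W1": init(data_dim, d1), "b1": np.zeros(d1), "C1": init(ca, d1),
            "W2": init(d1, d2), "b2": np.zeros(d2), "C2": init(ca, d2),
            "W3": init(d2, d1), "b3": np.zeros(d1), "C3": init(ca, d1),
            "W4": init(d1, data_dim), "b4": np.zeros(data_dim),
        }

    def forward(self, x: np.ndarray, u: np.ndarray, cache: dict | None = None) -> np.ndarray:
        p = self.params
        zc1 = u @ p["Wc1"] + p["bc1"]
        hc1 = _silu(zc1)
        zc2 = hc1 @ p["Wc2"] + p["bc2"]
        c = np.concatenate([_silu(zc2), u], axis=1)
        z1 = x @ p["W1"] + p["b1"] + c @ p["C1"]
        h1 = _silu(z1)
        z2 = h1 @ p["W2"] + p["b2"] + c @ p["C2"]
        h2 = _silu(z2)
        z3 = h2 @ p["W3"] + p["b3"] + c @ p["C3"]
        h3 = _silu(z3)
        hs = h3 + h1
        out = hs @ p["W4"] + p["b4"]
        if cache is not None:
            cache.update(x=x, u=u, zc1=zc1, hc1=hc1, zc2=zc2, c=c,
                         z1=z1, h1=h1, z2=z2, h2=h2, z3=z3, h3=h3, hs=hs)
        return out

    def loss_and_grads(self, x: np.ndarray, u: np.ndarray, target: np.ndarray,
                       sample_weight: np.ndarray | None = None) -> tuple[float, dict]:
        """(Optionally row-weighted) MSE against ``target`` with full gradients.

        With ``sample_weight`` w the loss is mean(w_i²·(out − target)²),
        which lets a caller train in one parameterization while reporting
        the loss of another (the weights absorb the change of variables).
        """
        p = self.params
        cache: dict = {}
        out = self.forward(x, u, cache)
        diff = out - target
        if sample_weight is not None:
            w2 = np.asarray(sample_weight, dtype=float).reshape(-1, 1) ** 2
            loss = float(np.mean(w2 * diff**2))
            g_out = 2.0 * w2 * diff / diff.size
        else:
            loss = float(np.mean(diff**2))
            g_out = 2.0 * diff / diff.size

        grads: dict[str, np.ndarray] = {}
        grads["W4"] = cache["hs"].T @ g_out
        grads["b4"] = g_out.sum(axis=0)
        g_hs = g_out @ p["W4"].T
        g_h3 = g_hs
        g_z3 = g_h3 * _silu_grad(cache["z3"])
        grads["W3"] = cache["h2"].T @ g_z3
        grads["b3"] = g_z3.sum(axis=0)
        grads["C3"] = cache["c"].T @ g_z3
        g_c = g_z3 @ p["C3"].T
        g_h2 = g_z3 @ p["W3"].T
        g_z2 = g_h2 * _silu_grad(cache["z2"])
        grads["W2"] = cache["h1"].T @ g_z2
        grads["b2"] = g_z2.sum(axis=0)
        grads["C2"] = cache["c"].T @ g_z2
        g_c = g_c + g_z2 @ p["C2"].T
        g_h1 = g_z2 @ p["W2"].T + g_hs  # skip connection
        g_z1 = g_h1 * _silu_grad(cache["z1"])
        grads["W1"] = cache["x"].T @ g_z1
        grads["b1"] = g_z1.sum(axis=0)
        grads["C1"] = cache["c"].T @ g_z1
        g_c = g_c + g_z1 @ p["C1"].T
        # only the learned-embedding half of c backpropagates (u is input)
        g_zc2 = g_c[:, : self.cond_dim] * _silu_grad(cache["zc2"])
        grads["Wc2"] = cache["hc1"].T @ g_zc2
        grads["bc2"] = g_zc2.sum(axis=0)
        g_hc1 = g_zc2 @ p["Wc2"].T
        g_zc1 = g_hc1 * _silu_grad(cache["zc1"])
        grads["Wc1"] = cache["u"].T @ g_zc1
        grads["bc1"] = g_zc1.sum(axis=0)
        return loss, grads


@dataclass
class AdamW:
    """AdamW with decoupled weight decay (applied to weight matrices only)."""

    lr: float = 1e-3
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k.startswith(("W", "C")):
                params[k] -= self.lr * self.weight_decay * params[k]
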