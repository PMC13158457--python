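"""Small fully connected network with exact gradients, in plain numpy.

The neural correction term of the hybrid model is a 2-hidden-layer, 32-unit
SiLU MLP mapping normalized time to a scalar force correction (pN).  Training
the physics-regularized loss needs three derivative quantities, all computed
analytically here (no finite differences):

* the forward value ``y(t)``;
* the tangent ``dy/dt`` via forward-mode propagation of dual numbers through
  every layer (the physics penalty involves the correction's time derivative);
* gradients of any loss ``L(y, dy/dt)`` with respect to every weight and
  bias, via reverse-mode propagation through the *extended* graph that
  carries both the value and the tangent.  Backprop through the tangent path
  requires the second derivative of the activation, so SiLU', SiLU'' are
  implemented explicitly.

A standard Adam optimizer operating on flat parameter vectors completes the
module.  Everything is deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLPSpec", "MLP", "Adam", "silu", "silu_d1", "silu_d2"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def silu(x: np.ndarray) -> np.ndarray:
    """SiLU(x) = x * sigmoid(x)."""
    return x * _sigmoid(x)


def silu_d1(x: np.ndarray) -> np.ndarray:
    """First derivative: sigma(x) * (1 + x * (1 - sigma(x)))."""
    s = _sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


def silu_d2(x: np.ndarray) -> np.ndarray:
    """Second derivative: sigma(1-sigma) * (2 + x * (1 - 2 sigma))."""
    s = _sigmoid(x)
    return s * (1.0 - s) * (2.0 + x * (1.0 - 2.0 * s))


@dataclass(frozen=True)
class MLPSpec:
    """Architecture of the correction network (defaults match the model)."""

    input_dim: int = 1
    hidden_layers: int = 2
    hidden_width: int = 32
    output_dim: int = 1

    def __post_init__(self) -> None:
        for name in ("input_dim", "hidden_layers", "hidden_width", "output_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim] + [self.hidden_width] * self.hidden_layers + [self.output_dim]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class MLP:
    """SiLU MLP with value+tangent forward pass and exact backprop.

    Weights are stored as lists ``Ws[l] (out, in)`` and ``bs[l] (out,)``.
    The final linear layer is zero-initialized so that a fresh network outputs
    exactly zero everywhere: the hybrid prediction then starts at the SLS
    backbone.
    """

    spec: MLPSpec
    Ws: list = field(default_factory=list)
    bs: list = field(default_factory=list)

    @classmethod
    def init(cls, spec: MLPSpec, rng: np.random.Generator) -> "MLP":
        Ws, bs = [], []
        n_layers = len(spec.layer_dims)
        for li, (fan_in, fan_out) in enumerate(spec.layer_dims):
            if li == n_layers - 1:
                W = np.zeros((fan_out, fan_in))
                b = np.zeros(fan_out)
            else:
                bound = 1.0 / np.sqrt(fan_in)
                W = rng.uniform(-bound, bound, size=(fan_out, fan_in))
                b = rng.uniform(-bound, bound, size=fan_out)
            Ws.append(W)
            bs.append(b)
        return cls(spec=spec, Ws=Ws, bs=bs)

    # -- flat parameter vector interface (for Adam and serialization) --------

    def get_flat(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.Ws] + [b for b in self.bs])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for li, W in enumerate(self.Ws):
            self.Ws[li] = flat[i : i + W.size].reshape(W.shape).copy()
            i += W.size
        for li, b in enumerate(self.bs):
            self.bs[li] = flat[i : i + b.size].copy()
            i += b.size

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.Ws) + sum(b.size for b in self.bs)

    # -- forward --------------------------------------------------------------

    def forward(self, x: np.ndarray, x_tan: np.ndarray | None = None):
        """Forward pass on a batch.

        Parameters
        ----------
        x
            Inputs, shape ``(n, input_dim)``.
        x_tan
            Optional input tangents ``dx/dt`` of the same shape.  When given,
            the tangent ``dy/dt`` is propagated alongside the value.

        Returns
        -------
        (y, y_tan, cache)
            Output values ``(n, output_dim)``, output tangents (or ``None``)
            and the cache needed by :meth:`backward`.
        """
        h_v = np.asarray(x, dtype=float)
        h_t = None if x_tan is None else np.asarray(x_tan, dtype=float)
        cache = []
        n_layers = len(self.Ws)
        for li in range(n_layers):
            W, b = self.Ws[li], self.bs[li]
            a_v = h_v @ W.T + b
            a_t = None if h_t is None else h_t @ W.T
            last = li == n_layers - 1
            if last:
                o_v, o_t = a_v, a_t
                cache.append((h_v, h_t, a_v, a_t))
            else:
                o_v = silu(a_v)
                o_t = None if a_t is None else silu_d1(a_v) * a_t
                cache.append((h_v, h_t, a_v, a_t))
            h_v, h_t = o_v, o_t
        return h_v, h_t, cache

    def backward(self, cache, gy: np.ndarray, gy_tan: np.ndarray | None = None):
        """Reverse pass: gradients of a scalar loss w.r.t. all parameters.

        ``gy = dL/dy`` and, if the tangent path was used in the loss,
        ``gy_tan = dL/d(dy/dt)``; both shaped like the network output.
        Returns ``(gWs, gbs)`` matching ``Ws``/``bs``.
        """
        n_layers = len(self.Ws)
        gWs = [None] * n_layers
        gbs = [None] * n_layers
        g_v = np.asarray(gy, dtype=float)
        g_t = None if gy_tan is None else np.asarray(gy_tan, dtype=float)
        for li in range(n_layers - 1, -1, -1):
            h_v, h_t, a_v, a_t = cache[li]
            W = self.Ws[li]
            last = li == n_layers - 1
            if last:
                ga_v, ga_t = g_v, g_t
            else:
                d1 = silu_d1(a_v)
                if g_t is None:
                    ga_v = g_v * d1
                    ga_t = None
                else:
                    # value adjoint picks up the tangent path through phi''
                    ga_v = g_v * d1 + g_t * silu_d2(a_v) * a_t
                    ga_t = g_t * d1
            gW = ga_v.T @ h_v
            if ga_t is not None and h_t is not None:
                gW = gW + ga_t.T @ h_t
            gWs[li] = gW
            gbs[li] = ga_v.sum(axis=0)
            g_v = ga_v @ W
            g_t = None if ga_t is None else ga_t @ W
        return gWs, gbs

    def flat_grad(self, gWs, gbs) -> np.ndarray:
        return np.concatenate([g.ravel() for g in gWs] + [g for g in gbs])


class Adam:
    """Adaptive-moment first-order optimizer on a flat parameter vector."""

    def __init__(self, n: int, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        return params - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
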