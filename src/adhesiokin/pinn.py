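"""Hybrid SLS + neural-residual force model and its physics-regularized training.

The hybrid prediction is

    F_hat(t) = F_SLS(t; backbone) + F_NN(t; weights),

an analytical Standard-Linear-Solid backbone plus an MLP correction on
normalized time.  Training minimizes

    L = L_data + L_phys                          (fixed, equal weights)
    L = e^{-s_d} L_data + e^{-s_p} L_phys + s_d + s_p   (adaptive)

where ``L_data`` is the Smooth-L1 (Huber) mismatch on the replicate-level
observations, and ``L_phys`` regularizes the correction itself,

    L_phys = 1/Var(F_data) * 1/M * sum_j [ F_NN(t_j)^2 + (dF_NN/dt)(t_j)^2 ],

evaluated at M collocation times; the variance normalization is computed once
from the training data and held fixed, so data and physics terms live on a
commensurate numerical scale from the first epoch.  The adaptive variant
learns the log-variances ``s_d = log sigma_d^2``, ``s_p = log sigma_p^2``,
down-weighting whichever term carries more uncertainty while the ``+ s``
penalty prevents weight collapse.

The time derivative inside the physics term is obtained by automatic
differentiation (forward-tangent propagation through the network, chained
through the time normalization), never by finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import AdhesionDataset
from .mlp import MLP, Adam, MLPSpec
from .sls import SLSParams, sls_mean

__all__ = [
    "TrainConfig",
    "PINNState",
    "TrainHistory",
    "normalize_time",
    "nn_correction",
    "nn_correction_and_derivative",
    "hybrid_predict",
    "data_loss",
    "physics_loss",
    "total_loss",
    "train_pinn",
    "correction_curve",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the PINN training loop."""

    epochs: int = 8000
    learning_rate: float = 1e-3
    n_collocation: int = 200
    seed: int = 0
    adaptive: bool = True
    huber_threshold: float = 1.0
    train_backbone: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_collocation < 2:
            raise ValueError("n_collocation must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.huber_threshold <= 0:
            raise ValueError("huber_threshold must be > 0")


@dataclass
class PINNState:
    """Trained (or initialized) hybrid-model state.

    ``backbone`` stays frozen during training unless the co-training flag is
    set; ``var_data`` is the empirical variance of the observed forces, fixed
    before epoch 1.
    """

    net: MLP
    s_data: float
    s_phys: float
    backbone: SLSParams
    var_data: float
    t_max: float

    def __post_init__(self) -> None:
        if self.var_data <= 0:
            raise ValueError("var_data must be > 0")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")

    # -- serialization (single plain-JSON artifact, schema-versioned) --------

    def to_json(self) -> str:
        payload = {
            "format_version": 1,
            "spec": {
                "input_dim": self.net.spec.input_dim,
                "hidden_layers": self.net.spec.hidden_layers,
                "hidden_width": self.net.spec.hidden_width,
                "output_dim": self.net.spec.output_dim,
            },
            "weights": [w.tolist() for w in self.net.Ws],
            "biases": [b.tolist() for b in self.net.bs],
            "s_data": self.s_data,
            "s_phys": self.s_phys,
            "backbone": {"F0": self.backbone.F0, "Fmax": self.backbone.Fmax,
                         "tau": self.backbone.tau},
            "var_data": self.var_data,
            "t_max": self.t_max,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PINNState":
        p = json.loads(text)
        if p.get("format_version") != 1:
            raise ValueError("unsupported PINN state format version")
        spec = MLPSpec(**p["spec"])
        net = MLP(spec=spec, Ws=[np.array(w) for w in p["weights"]],
                  bs=[np.array(b) for b in p["biases"]])
        return cls(net=net, s_data=p["s_data"], s_phys=p["s_phys"],
                   backbone=SLSParams(**p["backbone"]),
                   var_data=p["var_data"], t_max=p["t_max"])


@dataclass
class TrainHistory:
    """Per-epoch loss components and uncertainty weights."""

    total: np.ndarray
    data: np.ndarray
    physics: np.ndarray
    weight_data: np.ndarray
    weight_phys: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.total.size + 1),
                "total": self.total,
                "data": self.data,
                "physics": self.physics,
                "weight_data": self.weight_data,
                "weight_phys": self.weight_phys,
            }
        )


def normalize_time(t, t_max: float):
    """Map physical time (min) to the dimensionless network input t / t_max."""
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > t_max):
        raise ValueError("t must lie in [0, t_max]")
    out = t_arr / t_max
    return float(out) if np.isscalar(t) else out


def _net_inputs(state: PINNState, t) -> np.ndarray:
    tn = np.atleast_1d(np.asarray(normalize_time(t, state.t_max), dtype=float))
    return tn[:, None]


def nn_correction(state: PINNState, t):
    """Neural correction F_NN(t) in pN; scalar in, scalar out."""
    y, _, _ = state.net.forward(_net_inputs(state, t))
    out = y[:, 0]
    return float(out[0]) if np.isscalar(t) else out


def nn_correction_and_derivative(state: PINNState, t):
    """Correction and its derivative dF_NN/dt w.r.t. physical time (pN/min).

    The tangent seed 1/t_max chains the derivative through the time
    normalization, so the returned derivative is per minute of physical time.
    """
    x = _net_inputs(state, t)
    x_tan = np.full_like(x, 1.0 / state.t_max)
    y, y_tan, _ = state.net.forward(x, x_tan)
    out, out_d = y[:, 0], y_tan[:, 0]
    if np.isscalar(t):
        return float(out[0]), float(out_d[0])
    return out, out_d


def hybrid_predict(state: PINNState, t):
    """Hybrid force prediction: SLS backbone plus neural correction (pN)."""
    return sls_mean(state.backbone, t) + nn_correction(state, t)


def correction_curve(state: PINNState, times) -> np.ndarray:
    """Neural correction evaluated on a time grid (difference between the
    hybrid prediction and the SLS backbone)."""
    return np.atleast_1d(nn_correction(state, np.atleast_1d(times)))


# -- loss terms ----------------------------------------------------------------


def _smooth_l1(r: np.ndarray, beta: float) -> np.ndarray:
    a = np.abs(r)
    return np.where(a < beta, 0.5 * r**2 / beta, a - 0.5 * beta)


def _smooth_l1_grad(r: np.ndarray, beta: float) -> np.ndarray:
    return np.where(np.abs(r) < beta, r / beta, np.sign(r))


def data_loss(predicted, observed, threshold: float = 1.0) -> float:
    """Smooth-L1 (Huber) data mismatch, averaged over observations.

    Quadratic ``0.5 r^2 / threshold`` for residuals below the transition
    threshold (pN), linear ``|r| - 0.5 threshold`` beyond it.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size == 0:
        raise ValueError("data_loss needs at least one observation")
    return float(np.mean(_smooth_l1(p - o, threshold)))


def physics_loss(state: PINNState, collocation_times) -> float:
    """Variance-normalized regularizer on the neural correction.

    Mean over collocation points of ``F_NN^2 + (dF_NN/dt)^2``, divided by the
    fixed empirical variance of the observed forces.  Zero iff the correction
    and its time derivative vanish at every collocation point.
    """
    tc = np.atleast_1d(np.asarray(collocation_times, dtype=float))
    if tc.size == 0:
        raise ValueError("physics_loss needs at least one collocation point")
    y, y_d = nn_correction_and_derivative(state, tc)
    return float(np.mean(y**2 + y_d**2) / state.var_data)


def total_loss(data_loss_value: float, physics_loss_value: float,
               s_data: float = 0.0, s_phys: float = 0.0,
               adaptive: bool = True) -> float:
    """Combine the two loss terms.

    Fixed weighting is the plain sum; adaptive weighting uses the learnable
    log-variances, ``e^{-s_d} L_d + e^{-s_p} L_p + s_d + s_p``.
    """
    if not adaptive:
        return float(data_loss_value + physics_loss_value)
    return float(
        np.exp(-s_data) * data_loss_value
        + np.exp(-s_phys) * physics_loss_value
        + s_data + s_phys
    )


# -- training ------------------------------------------------------------------


def _backbone_jacobian(params: SLSParams, t: np.ndarray) -> np.ndarray:
    """d mu / d (F0, Fmax, tau) at each time, shape (n, 3)."""
    e = np.exp(-t / params.tau)
    dF0 = e
    dFmax = 1.0 - e
    dtau = -(params.Fmax - params.F0) * e * t / params.tau**2
    return np.stack([dF0, dFmax, dtau], axis=1)


def train_pinn(data: AdhesionDataset, backbone: SLSParams,
               config: TrainConfig) -> tuple[PINNState, TrainHistory]:
    """Train the hybrid model with Adam.

    The backbone stays frozen at its deterministic SLS fit (the correction is
    then interpretable as deviation from that fit); ``config.train_backbone``
    co-trains it through the data term instead.  ``var_data`` is frozen from
    the observed forces before the first epoch.  Identical seeds give
    bitwise-identical histories.

    Raises
    ------
    FloatingPointError
        If any loss becomes non-finite, naming the epoch.
    """
    if len(data) == 0:
        raise ValueError("training data must be nonempty")

    rng = np.random.default_rng(config.seed)
    t_max = data.t_max if data.t_max > 0 else 1.0
    var_data = float(np.var(data.forces))
    if var_data <= 0:
        var_data = 1.0  # constant data: unit scale keeps the regularizer defined

    net = MLP.init(MLPSpec(), rng)
    state = PINNState(net=net, s_data=0.0, s_phys=0.0, backbone=backbone,
                      var_data=var_data, t_max=t_max)

    t_obs = data.times
    f_obs = data.forces
    x_obs = (t_obs / t_max)[:, None]
    t_col = np.linspace(0.0, t_max, config.n_collocation)
    x_col = (t_col / t_max)[:, None]
    x_col_tan = np.full_like(x_col, 1.0 / t_max)
    M = config.n_collocation
    beta = config.huber_threshold

    n_net = net.n_params
    # flat optimization vector: [net params, s_data, s_phys, (backbone?)]
    theta = np.concatenate([net.get_flat(), [0.0, 0.0],
                            backbone.as_array() if config.train_backbone else []])
    opt = Adam(theta.size, lr=config.learning_rate)

    hist_total = np.empty(config.epochs)
    hist_data = np.empty(config.epochs)
    hist_phys = np.empty(config.epochs)
    hist_wd = np.empty(config.epochs)
    hist_wp = np.empty(config.epochs)

    for epoch in range(config.epochs):
        net.set_flat(theta[:n_net])
        s_d, s_p = theta[n_net], theta[n_net + 1]
        if config.train_backbone:
            F0, Fmax, tau = theta[n_net + 2 : n_net + 5]
            bb = SLSParams(F0=max(F0, 0.0), Fmax=Fmax, tau=max(tau, 0.05))
        else:
            bb = backbone

        # data term
        y_obs, _, cache_obs = net.forward(x_obs)
        mu = sls_mean(bb, t_obs)
        r = mu + y_obs[:, 0] - f_obs
        L_d = float(np.mean(_smooth_l1(r, beta)))
        g_r = _smooth_l1_grad(r, beta) / r.size  # dL_d/d pred

        # physics term
        y_col, yt_col, cache_col = net.forward(x_col, x_col_tan)
        yv, yt = y_col[:, 0], yt_col[:, 0]
        L_p = float(np.mean(yv**2 + yt**2) / var_data)

        if config.adaptive:
            w_d, w_p = float(np.exp(-s_d)), float(np.exp(-s_p))
            L = w_d * L_d + w_p * L_p + s_d + s_p
        else:
            w_d = w_p = 1.0
            L = L_d + L_p

        if not np.isfinite(L):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch + 1} "
                f"(data={L_d!r}, physics={L_p!r})"
            )

        hist_total[epoch] = L
        hist_data[epoch] = L_d
        hist_phys[epoch] = L_p
        hist_wd[epoch] = w_d
        hist_wp[epoch] = w_p

        # gradients
        gW_d, gb_d = net.backward(cache_obs, (w_d * g_r)[:, None])
        scale = 2.0 / (var_data * M) * w_p
        gW_p, gb_p = net.backward(cache_col, (scale * yv)[:, None],
                                  (scale * yt)[:, None])
        g_net = net.flat_grad(gW_d, gb_d) + net.flat_grad(gW_p, gb_p)

        if config.adaptive:
            g_sd = -w_d * L_d + 1.0
            g_sp = -w_p * L_p + 1.0
        else:
            g_sd = g_sp = 0.0

        pieces = [g_net, [g_sd, g_sp]]
        if config.train_backbone:
            J = _backbone_jacobian(bb, t_obs)
            pieces.append(J.T @ (w_d * g_r))
        grad = np.concatenate([np.asarray(p, dtype=float).ravel() for p in pieces])
        theta = opt.step(theta, grad)

    net.set_flat(theta[:n_net])
    if config.train_backbone:
        F0, Fmax, tau = theta[n_net + 2 : n_net + 5]
        backbone = SLSParams(F0=max(float(F0), 0.0), Fmax=float(Fmax),
                             tau=max(float(tau), 0.05))
    final_state = PINNState(net=net, s_data=float(theta[n_net]),
                            s_phys=float(theta[n_net + 1]),
                            backbone=backbone, var_data=var_data, t_max=t_max)
    history = TrainHistory(total=hist_total, data=hist_data, physics=hist_phys,
                           weight_data=hist_wd, weight_phys=hist_wp)
    return final_state, history


def init_state(data: AdhesionDataset, backbone: SLSParams, seed: int = 0) -> PINNState:
    """Untrained state (zero output layer): hybrid prediction == backbone."""
    rng = np.random.default_rng(seed)
    var_data = float(np.var(data.forces)) or 1.0
    return PINNState(net=MLP.init(MLPSpec(), rng), s_data=0.0, s_phys=0.0,
                     backbone=backbone, var_data=var_data,
                     t_max=data.t_max if data.t_max > 0 else 1.0)
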