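"""No-U-Turn Sampler with dual-averaging step size and windowed mass adaptation.

A self-contained numpy implementation of dynamic Hamiltonian Monte Carlo with
multinomial sampling over the doubling trajectory (the modern NUTS variant),
plus the two standard warmup adaptations:

* primal-dual averaging of the leapfrog step size toward a target acceptance
  statistic (default 0.9);
* expanding-window estimation of the posterior covariance used as a dense
  pre-conditioner (the "mass matrix"), Stan-style, shrunk toward the
  diagonal; a diagonal metric is available for high-dimensional targets.

The target density is supplied as a callable ``logp_and_grad(z) ->
(logp, grad)`` on an unconstrained parameter vector ``z``; constraint
transforms and their Jacobians are the caller's business.  Everything is
deterministic given a ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_MAX_TREEDEPTH = 10
_DELTA_MAX = 1000.0  # divergence threshold on the joint log-density error


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_draws, dim)
    n_divergent: int
    step_size: float
    accept_mean: float
    inv_mass: np.ndarray


class _Metric:
    """Euclidean metric; dense or diagonal inverse mass."""

    def __init__(self, dim: int, dense: bool):
        self.dim = dim
        self.dense = dense
        if dense:
            self.inv_mass = np.eye(dim)
            self._chol_mass = np.eye(dim)  # Cholesky of mass = inv(inv_mass)
        else:
            self.inv_mass = np.ones(dim)
            self._sqrt_mass = np.ones(dim)

    def update(self, cov: np.ndarray) -> None:
        if self.dense:
            self.inv_mass = cov
            self._chol_mass = np.linalg.cholesky(np.linalg.inv(cov))
        else:
            self.inv_mass = cov
            self._sqrt_mass = 1.0 / np.sqrt(cov)

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        eta = rng.standard_normal(self.dim)
        if self.dense:
            return self._chol_mass @ eta
        return self._sqrt_mass * eta

    def velocity(self, r: np.ndarray) -> np.ndarray:
        if self.dense:
            return self.inv_mass @ r
        return self.inv_mass * r

    def kinetic(self, r: np.ndarray) -> float:
        return 0.5 * float(np.dot(r, self.velocity(r)))


def _leapfrog(f, z, r, grad, eps, metric):
    r1 = r + 0.5 * eps * grad
    z1 = z + eps * metric.velocity(r1)
    logp1, grad1 = f(z1)
    r1 = r1 + 0.5 * eps * grad1
    return z1, r1, logp1, grad1


def _find_initial_step(f, z, logp, grad, metric, rng):
    eps = 1.0
    r = metric.sample_momentum(rng)
    H0 = logp - metric.kinetic(r)
    _, r1, logp1, _ = _leapfrog(f, z, r, grad, eps, metric)
    H1 = logp1 - metric.kinetic(r1)
    if not np.isfinite(H1):
        H1 = -np.inf
    a = 1.0 if (H1 - H0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**a
        _, r1, logp1, _ = _leapfrog(f, z, r, grad, eps, metric)
        H1 = logp1 - metric.kinetic(r1)
        if not np.isfinite(H1):
            H1 = -np.inf
        if a * (H1 - H0) <= a * np.log(0.5):
            break
    return eps


def _logaddexp(a: float, b: float) -> float:
    return float(np.logaddexp(a, b))


class _Tree:
    __slots__ = ("z_minus", "r_minus", "g_minus", "z_plus", "r_plus", "g_plus",
                 "z_prop", "g_prop", "logp_prop", "log_w", "ok", "alpha",
                 "n_alpha", "divergent", "rho")


def _uturn(metric, r_begin, r_end, rho) -> bool:
    """Generalized U-turn test on the accumulated momentum ``rho``."""
    return (np.dot(metric.velocity(r_begin), rho) <= 0
            or np.dot(metric.velocity(r_end), rho) <= 0)


def _merged_turning(metric, left: "_Tree", right: "_Tree",
                    rho: np.ndarray) -> bool:
    """Stan-style termination: test the full span plus the two cross-subtree
    spans ending/starting at the merge boundary (catches U-turns the plain
    end-to-end test misses)."""
    if _uturn(metric, left.r_minus, right.r_plus, rho):
        return True
    if _uturn(metric, left.r_minus, right.r_minus, left.rho + right.r_minus):
        return True
    if _uturn(metric, left.r_plus, right.r_plus, left.r_plus + right.rho):
        return True
    return False


def _build_tree(f, z, r, grad, v, j, eps, H0, metric, rng):
    """Multinomial NUTS subtree of depth ``j`` in direction ``v``."""
    if j == 0:
        z1, r1, logp1, grad1 = _leapfrog(f, z, r, grad, v * eps, metric)
        joint = logp1 - metric.kinetic(r1)
        if not np.isfinite(joint):
            joint = -np.inf
        t = _Tree()
        t.z_minus = t.z_plus = t.z_prop = z1
        t.r_minus = t.r_plus = r1
        t.g_minus = t.g_plus = t.g_prop = grad1
        t.logp_prop = logp1
        t.log_w = joint - H0
        t.rho = r1.copy()
        t.divergent = (H0 - joint) > _DELTA_MAX
        t.ok = not t.divergent
        t.alpha = min(1.0, float(np.exp(joint - H0))) if np.isfinite(joint) else 0.0
        t.n_alpha = 1
        return t

    t = _build_tree(f, z, r, grad, v, j - 1, eps, H0, metric, rng)
    if not t.ok:
        return t
    if v == -1:
        t2 = _build_tree(f, t.z_minus, t.r_minus, t.g_minus, v, j - 1, eps,
                         H0, metric, rng)
        left, right = t2, t
        turning = _merged_turning(metric, left, right, left.rho + right.rho)
        t.z_minus, t.r_minus, t.g_minus = t2.z_minus, t2.r_minus, t2.g_minus
    else:
        t2 = _build_tree(f, t.z_plus, t.r_plus, t.g_plus, v, j - 1, eps,
                         H0, metric, rng)
        left, right = t, t2
        turning = _merged_turning(metric, left, right, left.rho + right.rho)
        t.z_plus, t.r_plus, t.g_plus = t2.z_plus, t2.r_plus, t2.g_plus
    log_w = _logaddexp(t.log_w, t2.log_w)
    # unbiased multinomial choice between the two halves
    if np.log(rng.uniform()) < t2.log_w - log_w:
        t.z_prop, t.g_prop, t.logp_prop = t2.z_prop, t2.g_prop, t2.logp_prop
    t.log_w = log_w
    t.alpha += t2.alpha
    t.n_alpha += t2.n_alpha
    t.divergent = t.divergent or t2.divergent
    t.rho = t.rho + t2.rho
    t.ok = t2.ok and not turning
    return t


def nuts_sample(logp_and_grad, z0: np.ndarray, n_warmup: int, n_draws: int,
                rng: np.random.Generator, target_accept: float = 0.9,
                max_treedepth: int = _MAX_TREEDEPTH,
                dense_mass: bool | None = None,
                init_inv_mass: np.ndarray | None = None) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws in unconstrained space.

    ``dense_mass`` defaults to a full covariance metric for dim <= 20 and a
    diagonal one above.  ``init_inv_mass`` (a covariance guess, e.g. from a
    Laplace approximation) seeds the metric instead of the identity; warmup
    windows still refine it.
    """
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    logp, grad = logp_and_grad(z)
    if not np.isfinite(logp):
        raise ValueError("non-finite log-posterior at the initial point")
    if dense_mass is None:
        dense_mass = dim <= 20

    metric = _Metric(dim, dense_mass)
    if init_inv_mass is not None:
        metric.update(np.asarray(init_inv_mass, dtype=float))
    eps = _find_initial_step(logp_and_grad, z, logp, grad, metric, rng)

    mu = np.log(10.0 * eps)
    log_eps_bar, H_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # warmup windows: fast start (step size only), expanding slow windows
    # (metric), fast tail (final step-size run-in)
    init_fast = min(max(int(0.15 * n_warmup), 10), n_warmup)
    term_fast = min(max(int(0.1 * n_warmup), 10), n_warmup - init_fast)
    slow_end = n_warmup - term_fast
    window_ends = []
    w = 25
    pos = init_fast
    while pos < slow_end:
        end = pos + w
        if slow_end - end < 2 * w:  # no room for the next doubled window
            end = slow_end
        window_ends.append(end)
        pos = end
        w *= 2

    samples_window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_div = 0
    accept_sum, accept_n = 0.0, 0

    total = n_warmup + n_draws
    win_idx = 0
    for it in range(total):
        warming = it < n_warmup
        r = metric.sample_momentum(rng)
        H0 = logp - metric.kinetic(r)
        traj = _Tree()
        traj.z_minus = traj.z_plus = z
        traj.r_minus = traj.r_plus = r
        traj.g_minus = traj.g_plus = grad
        traj.rho = r.copy()
        log_w = 0.0
        j, ok = 0, True
        alpha, n_alpha = 0.0, 1
        divergent = False
        while ok and j < max_treedepth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                t = _build_tree(logp_and_grad, traj.z_minus, traj.r_minus,
                                traj.g_minus, v, j, eps, H0, metric, rng)
                left, right = t, traj
            else:
                t = _build_tree(logp_and_grad, traj.z_plus, traj.r_plus,
                                traj.g_plus, v, j, eps, H0, metric, rng)
                left, right = traj, t
            alpha, n_alpha = t.alpha, t.n_alpha
            divergent = divergent or t.divergent
            if t.ok:
                # biased progressive sampling favoring the new subtree
                if np.log(rng.uniform()) < t.log_w - log_w:
                    z, grad, logp = t.z_prop, t.g_prop, t.logp_prop
                log_w = _logaddexp(log_w, t.log_w)
                turning = _merged_turning(metric, left, right,
                                          left.rho + right.rho)
                traj.rho = traj.rho + t.rho
                if v == -1:
                    traj.z_minus, traj.r_minus, traj.g_minus = \
                        t.z_minus, t.r_minus, t.g_minus
                else:
                    traj.z_plus, traj.r_plus, traj.g_plus = \
                        t.z_plus, t.r_plus, t.g_plus
                ok = not turning
            else:
                ok = False
            j += 1

        if divergent and not warming:
            n_div += 1

        accept_stat = alpha / max(n_alpha, 1)
        if warming:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            H_bar = (1 - frac) * H_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(da_count) / gamma * H_bar
            eta = da_count**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))

            if init_fast <= it < slow_end:
                samples_window.append(z.copy())
            if win_idx < len(window_ends) and it + 1 == window_ends[win_idx]:
                if len(samples_window) >= 10:
                    S = np.asarray(samples_window)
                    n_s = S.shape[0]
                    shrink = n_s / (n_s + 5.0)
                    if dense_mass:
                        cov = np.cov(S, rowvar=False)
                        cov = shrink * cov + (1 - shrink) * 1e-3 * np.eye(dim)
                        cov += 1e-10 * np.eye(dim)
                    else:
                        cov = shrink * S.var(axis=0, ddof=1) + (1 - shrink) * 1e-3
                    metric.update(cov)
                    samples_window = []
                    eps = _find_initial_step(logp_and_grad, z, logp, grad,
                                             metric, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, H_bar, da_count = 0.0, 0.0, 0
                win_idx += 1
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            accept_sum += accept_stat
            accept_n += 1
            draws[it - n_warmup] = z

    return NutsResult(draws=draws, n_divergent=n_div, step_size=eps,
                      accept_mean=accept_sum / max(accept_n, 1),
                      inv_mass=np.asarray(metric.inv_mass))
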