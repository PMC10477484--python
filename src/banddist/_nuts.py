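"""A no-U-turn sampler with dual-averaging step size and dense mass matrix.

Implements the efficient NUTS tree-doubling scheme (slice variant) on an
unconstrained parameter vector, given a callable returning the log density
and its gradient.  Warm-up follows the usual schedule: an initial step-size
adaptation phase, a window that re-estimates the (dense) mass matrix from
warm-up draws, and a final step-size re-adaptation with the new metric.
The metric can be seeded from a Laplace approximation so short warm-ups
start near the right scale; a dense metric keeps trajectories short in the
presence of the strong posterior correlations typical of trend + random
effect + detection models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

__all__ = ["NutsResult", "nuts_sample"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_kept, ndim)
    n_divergent: int
    step_size: float
    mean_accept: float


class _Metric:
    """Euclidean metric: momenta ~ N(0, M); positions move along M^{-1} p."""

    def __init__(self, inv_mass: np.ndarray):
        d = inv_mass.shape[0]
        self.inv_mass = inv_mass
        # inv_mass = L L^T; momentum draw p = L^{-T} u has covariance M
        self.chol = np.linalg.cholesky(inv_mass + 1e-10 * np.eye(d))

    def draw_momentum(self, rng: np.random.Generator) -> np.ndarray:
        u = rng.standard_normal(self.chol.shape[0])
        return solve_triangular(self.chol, u, lower=True, trans="T")

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.inv_mass @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.inv_mass @ p)


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0: float, target: float = 0.8):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _leapfrog(value_and_grad, metric, x, p, grad, eps):
    p = p + 0.5 * eps * grad
    x = x + eps * metric.velocity(p)
    lp, grad = value_and_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _find_initial_step(value_and_grad, metric, x, rng) -> float:
    """Heuristic bracketing of a step size with ~50% acceptance."""
    eps = 0.1
    lp, grad = value_and_grad(x)
    p = metric.draw_momentum(rng)
    h0 = lp - metric.kinetic(p)

    def h_after(eps):
        x1, p1, lp1, _ = _leapfrog(value_and_grad, metric, x, p, grad, eps)
        if not np.isfinite(lp1):
            return -np.inf
        return lp1 - metric.kinetic(p1)

    direction = 1.0 if (h_after(eps) - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        if direction * (h_after(eps) - h0) < direction * np.log(0.5):
            break
    return float(eps)


def nuts_sample(
    value_and_grad,
    x0: np.ndarray,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_depth: int = 10,
    init_cov: np.ndarray | None = None,
) -> NutsResult:
    """Run one NUTS chain; returns the post-warm-up draws.

    ``init_cov`` seeds the metric (a posterior covariance guess, e.g. a
    Laplace approximation); the covariance is then re-estimated from
    expanding warm-up windows, each followed by a step-size re-adaptation.
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    inv_mass = np.array(init_cov, dtype=float) if init_cov is not None else np.eye(d)
    metric = _Metric(inv_mass)

    lp, grad = value_and_grad(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")

    eps = _find_initial_step(value_and_grad, metric, x, rng)
    da = _DualAveraging(eps, target_accept)

    # expanding covariance windows within warm-up, Stan-style: step size only
    # in the first and last stretches, metric updates at each window end
    window_ends = [
        int(f * warmup) for f in (0.4, 0.75, 0.9)
    ]
    w_start = max(1, int(0.15 * warmup))
    wn = 0
    wmean = np.zeros(d)
    wm2 = np.zeros((d, d))

    draws = np.empty((max(n_iter - warmup, 0), d))
    n_div = 0
    acc_sum = 0.0
    acc_n = 0

    for it in range(n_iter):
        p0 = metric.draw_momentum(rng)
        h0 = lp - metric.kinetic(p0)
        log_u = np.log(rng.random()) + h0

        x_minus = x_plus = x
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        x_new, lp_new, g_new = x, lp, grad
        n_valid = 1
        keep_going = True
        depth = 0
        sum_accept = 0.0
        n_accept = 0

        while keep_going and depth < max_depth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                (
                    _, _, _, x_plus, p_plus, g_plus,
                    x_prop, lp_prop, g_prop, n_prop, valid, a, na, div,
                ) = _build_tree(
                    value_and_grad, metric, x_plus, p_plus, g_plus, log_u,
                    direction, depth, eps, h0, rng,
                )
            else:
                (
                    x_minus, p_minus, g_minus, _, _, _,
                    x_prop, lp_prop, g_prop, n_prop, valid, a, na, div,
                ) = _build_tree(
                    value_and_grad, metric, x_minus, p_minus, g_minus, log_u,
                    direction, depth, eps, h0, rng,
                )
            sum_accept += a
            n_accept += na
            n_div += int(div)
            if valid and n_prop > 0 and rng.random() < n_prop / max(n_valid, 1):
                x_new, lp_new, g_new = x_prop, lp_prop, g_prop
            n_valid += n_prop
            dx = x_plus - x_minus
            keep_going = (
                valid
                and np.dot(dx, metric.velocity(p_minus)) >= 0
                and np.dot(dx, metric.velocity(p_plus)) >= 0
            )
            depth += 1

        x, lp, grad = x_new, lp_new, g_new
        accept_stat = sum_accept / max(n_accept, 1)

        if it < warmup:
            eps = da.update(accept_stat)
            if it >= w_start:
                wn += 1
                delta = x - wmean
                wmean += delta / wn
                wm2 += np.outer(delta, x - wmean)
            if (it + 1) in window_ends and wn > max(8, d // 4):
                cov = wm2 / (wn - 1)
                shrink = wn / (wn + 5.0)
                cov = shrink * cov + (1 - shrink) * np.diag(np.diag(cov) + 1e-6)
                metric = _Metric(cov + 1e-8 * np.eye(d))
                eps = _find_initial_step(value_and_grad, metric, x, rng)
                da = _DualAveraging(eps, target_accept)
                wn = 0
                wmean[:] = 0.0
                wm2[:] = 0.0
            if it == warmup - 1:
                eps = da.adapted
        else:
            draws[it - warmup] = x
            acc_sum += accept_stat
            acc_n += 1

    return NutsResult(
        draws=draws,
        n_divergent=n_div,
        step_size=float(eps),
        mean_accept=acc_sum / max(acc_n, 1),
    )


def _build_tree(
    value_and_grad, metric, x, p, grad, log_u, direction, depth, eps, h0, rng
):
    """Recursively double the trajectory; slice-sampling NUTS tree.

    Returns (x_minus, p_minus, g_minus, x_plus, p_plus, g_plus,
    x_prop, lp_prop, g_prop, n_prop, valid, sum_accept, n_accept, divergent).
    """
    if depth == 0:
        x1, p1, lp1, g1 = _leapfrog(value_and_grad, metric, x, p, grad, direction * eps)
        h1 = lp1 - metric.kinetic(p1) if np.isfinite(lp1) else -np.inf
        divergent = (h0 - h1) > _MAX_ENERGY_ERROR or not np.isfinite(h1)
        n_prop = int(log_u <= h1)
        accept = float(np.exp(min(0.0, h1 - h0))) if np.isfinite(h1) else 0.0
        return (
            x1, p1, g1, x1, p1, g1,
            x1, lp1, g1, n_prop, not divergent, accept, 1, divergent,
        )

    (
        xm, pm, gm, xp, pp, gp,
        x_prop, lp_prop, g_prop, n1, valid1, a1, na1, div1,
    ) = _build_tree(
        value_and_grad, metric, x, p, grad, log_u, direction, depth - 1, eps, h0, rng
    )
    if not valid1:
        return (xm, pm, gm, xp, pp, gp, x_prop, lp_prop, g_prop, n1, False, a1, na1, div1)

    if direction == 1:
        (
            _, _, _, xp, pp, gp,
            x_prop2, lp_prop2, g_prop2, n2, valid2, a2, na2, div2,
        ) = _build_tree(
            value_and_grad, metric, xp, pp, gp, log_u, direction, depth - 1, eps, h0, rng
        )
    else:
        (
            xm, pm, gm, _, _, _,
            x_prop2, lp_prop2, g_prop2, n2, valid2, a2, na2, div2,
        ) = _build_tree(
            value_and_grad, metric, xm, pm, gm, log_u, direction, depth - 1, eps, h0, rng
        )
    if n2 > 0 and rng.random() < n2 / max(n1 + n2, 1):
        x_prop, lp_prop, g_prop = x_prop2, lp_prop2, g_prop2
    dx = xp - xm
    no_uturn = (
        np.dot(dx, metric.velocity(pm)) >= 0 and np.dot(dx, metric.velocity(pp)) >= 0
    )
    valid = valid2 and no_uturn
    return (
        xm, pm, gm, xp, pp, gp,
        x_prop, lp_prop, g_prop, n1 + n2, valid, a1 + a2, na1 + na2, div1 or div2,
    )
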