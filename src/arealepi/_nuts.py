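"""No-U-Turn sampler with dual-averaging step size and diagonal metric.

A compact, dependency-free implementation of the standard adaptive HMC
recipe: slice-variable NUTS trees (doubling until a U-turn or divergence),
dual averaging of the step size towards a target acceptance statistic, and
windowed estimation of a diagonal inverse metric during warmup.  The target
density is supplied as a callable ``f(theta) -> (logp, grad)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "NUTSResult"]

_MAX_DELTA = 1000.0  # divergence threshold on the energy error


@dataclass
class NUTSResult:
    draws: np.ndarray  # (n_draws, dim)
    logp: np.ndarray  # (n_draws,)
    accept_stat: np.ndarray
    tree_depth: np.ndarray
    divergent: np.ndarray
    step_size: float
    inv_metric: np.ndarray


class _DualAveraging:
    def __init__(self, eps0: float, target: float) -> None:
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept)
        self.log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return math.exp(self.log_eps)

    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


def _leapfrog(f, theta, r, grad, eps, inv_metric):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_metric * r1
    logp1, grad1 = f(theta1)
    if not np.isfinite(logp1):
        return theta1, r1, grad1, logp1
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, grad1, logp1


def _hamiltonian(logp, r, inv_metric):
    return logp - 0.5 * float(np.dot(r * r, inv_metric))


def _find_initial_step(f, theta, logp, grad, inv_metric, rng):
    eps = 1.0
    r = rng.standard_normal(len(theta)) / np.sqrt(inv_metric)
    h0 = _hamiltonian(logp, r, inv_metric)
    _, r1, _, logp1 = _leapfrog(f, theta, r, grad, eps, inv_metric)
    h1 = _hamiltonian(logp1, r1, inv_metric) if np.isfinite(logp1) else -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, r1, _, logp1 = _leapfrog(f, theta, r, grad, eps, inv_metric)
        h1 = _hamiltonian(logp1, r1, inv_metric) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) < direction * math.log(0.5):
            break
    return max(eps, 1e-10)


def _build_tree(f, state, logu, v, depth, eps, inv_metric, h0, rng):
    """Recursive tree doubling; ``state`` is (theta, r, grad, logp).

    Returns (left, right, proposal, n_accept, keep_going, sum_alpha,
    n_alpha, divergent); a base-case stop (keep_going == 0) is a
    divergence, a higher-level stop may also be a U-turn.
    """
    if depth == 0:
        theta1, r1, grad1, logp1 = _leapfrog(f, *state[:3], v * eps, inv_metric)
        h1 = _hamiltonian(logp1, r1, inv_metric) if np.isfinite(logp1) else -np.inf
        n1 = int(logu <= h1)
        s1 = int(np.isfinite(h1) and (logu < _MAX_DELTA + h1))
        alpha = min(1.0, math.exp(min(0.0, h1 - h0))) if np.isfinite(h1) else 0.0
        st = (theta1, r1, grad1, logp1)
        return st, st, st, n1, s1, alpha, 1, int(s1 == 0)
    st_m, st_p, st_prop, n1, s1, a1, na1, div1 = _build_tree(
        f, state, logu, v, depth - 1, eps, inv_metric, h0, rng
    )
    if s1 == 1:
        if v == -1:
            st_m, _, st_prop2, n2, s2, a2, na2, div2 = _build_tree(
                f, st_m, logu, v, depth - 1, eps, inv_metric, h0, rng
            )
        else:
            _, st_p, st_prop2, n2, s2, a2, na2, div2 = _build_tree(
                f, st_p, logu, v, depth - 1, eps, inv_metric, h0, rng
            )
        if n2 > 0 and rng.random() < n2 / max(n1 + n2, 1):
            st_prop = st_prop2
        dtheta = st_p[0] - st_m[0]
        s1 = (
            s2
            * int(np.dot(dtheta, inv_metric * st_m[1]) >= 0)
            * int(np.dot(dtheta, inv_metric * st_p[1]) >= 0)
        )
        n1 += n2
        a1 += a2
        na1 += na2
        div1 |= div2
    return st_m, st_p, st_prop, n1, s1, a1, na1, div1


def _warmup_windows(n_warmup: int) -> tuple[int, int, list[int]]:
    """Stan-style (fast-start, slow windows..., fast-end) schedule.

    Returns (init_buffer, term_buffer, list of slow-window end iterations).
    """
    if n_warmup < 40:
        return n_warmup, 0, []
    init_buf = max(1, int(0.15 * n_warmup))
    term_buf = max(1, int(0.10 * n_warmup))
    slow = n_warmup - init_buf - term_buf
    ends = []
    w = max(25, slow // 8)
    pos = init_buf
    while pos < init_buf + slow:
        w_eff = min(w, init_buf + slow - pos)
        # absorb a too-small trailing window into the last one
        if init_buf + slow - (pos + w_eff) < 10:
            w_eff = init_buf + slow - pos
        pos += w_eff
        ends.append(pos)
        w *= 2
    return init_buf, term_buf, ends


def sample_nuts(
    f: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_depth: int = 10,
) -> NUTSResult:
    dim = len(theta0)
    inv_metric = np.ones(dim)
    theta = np.asarray(theta0, dtype=float).copy()
    logp, grad = f(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(f, theta, logp, grad, inv_metric, rng)
    da = _DualAveraging(eps, target_accept)
    init_buf, term_buf, window_ends = _warmup_windows(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    out_logp = np.empty(n_draws)
    out_accept = np.empty(n_draws)
    out_depth = np.empty(n_draws, dtype=np.int64)
    out_div = np.zeros(n_draws, dtype=bool)

    for it in range(n_warmup + n_draws):
        warm = it < n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_metric)
        h0 = _hamiltonian(logp, r0, inv_metric)
        logu = h0 - rng.exponential(1.0)
        st_m = (theta, r0, grad, logp)
        st_p = (theta, r0, grad, logp)
        n_acc, s, depth = 1, 1, 0
        alpha_sum, n_alpha = 0.0, 0
        diverged = False
        while s == 1 and depth < max_depth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                st_m, _, st_prop, n1, s1, a1, na1, div1 = _build_tree(
                    f, st_m, logu, v, depth, eps, inv_metric, h0, rng
                )
            else:
                _, st_p, st_prop, n1, s1, a1, na1, div1 = _build_tree(
                    f, st_p, logu, v, depth, eps, inv_metric, h0, rng
                )
            if s1 == 1 and rng.random() < min(1.0, n1 / max(n_acc, 1)):
                theta, _, grad, logp = st_prop
            diverged = diverged or bool(div1)
            n_acc += n1
            alpha_sum += a1
            n_alpha += na1
            dtheta = st_p[0] - st_m[0]
            s = (
                s1
                * int(np.dot(dtheta, inv_metric * st_m[1]) >= 0)
                * int(np.dot(dtheta, inv_metric * st_p[1]) >= 0)
            )
            depth += 1
        accept = alpha_sum / max(n_alpha, 1)

        if warm:
            eps = da.update(accept)
            in_slow = init_buf <= it < (n_warmup - term_buf) and window_ends
            if in_slow:
                welford_n += 1
                d = theta - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (theta - welford_mean)
                if (it + 1) in window_ends and welford_n > 5:
                    var = welford_m2 / max(welford_n - 1, 1)
                    w = welford_n
                    inv_metric = (w / (w + 5.0)) * var + (5.0 / (w + 5.0)) * 1e-3
                    inv_metric = np.maximum(inv_metric, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    eps = _find_initial_step(f, theta, logp, grad, inv_metric, rng)
                    da = _DualAveraging(eps, target_accept)
            if it == n_warmup - 1:
                eps = da.adapted()
        else:
            k = it - n_warmup
            draws[k] = theta
            out_logp[k] = logp
            out_accept[k] = accept
            out_depth[k] = depth
            out_div[k] = diverged

    return NUTSResult(
        draws=draws,
        logp=out_logp,
        accept_stat=out_accept,
        tree_depth=out_depth,
        divergent=out_div,
        step_size=eps,
        inv_metric=inv_metric,
    )
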