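"""No-U-Turn Hamiltonian Monte Carlo on an unconstrained parameter vector.

Multinomial NUTS with dual-averaging step-size adaptation and a
diagonal mass matrix estimated during warmup (expanding-window scheme).
The target is supplied as a callable returning ``(logp, grad)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["nuts_chain", "ChainStats"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainStats:
    accept_rate: float
    divergences: int
    step_size: float
    mean_treedepth: float


class _Tree:
    __slots__ = ("q_minus", "p_minus", "grad_minus", "q_plus", "p_plus",
                 "grad_plus", "proposal", "proposal_logp", "log_weight",
                 "sum_accept", "n_leaves", "turning", "diverged")


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p, inv_mass * p))


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * (inv_mass * p)
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _is_turning(q_minus, q_plus, p_minus, p_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _build_tree(logp_grad, q, p, grad, logp, depth, direction, eps, h0,
                inv_mass, rng) -> _Tree:
    t = _Tree()
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p, grad, direction * eps,
                                         inv_mass)
        joint = logp1 - _kinetic(p1, inv_mass)
        t.log_weight = joint - h0
        t.diverged = not np.isfinite(joint) or (h0 - joint) > _DIVERGENCE_THRESHOLD
        t.turning = False
        t.q_minus = t.q_plus = q1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.proposal, t.proposal_logp = q1, logp1
        t.sum_accept = min(1.0, math.exp(min(0.0, t.log_weight)))
        t.n_leaves = 1
        return t

    first = _build_tree(logp_grad, q, p, grad, logp, depth - 1, direction, eps,
                        h0, inv_mass, rng)
    if first.diverged or first.turning:
        return first
    if direction == 1:
        second = _build_tree(logp_grad, first.q_plus, first.p_plus,
                             first.grad_plus, logp, depth - 1, direction, eps,
                             h0, inv_mass, rng)
        first.q_plus, first.p_plus, first.grad_plus = (
            second.q_plus, second.p_plus, second.grad_plus)
    else:
        second = _build_tree(logp_grad, first.q_minus, first.p_minus,
                             first.grad_minus, logp, depth - 1, direction, eps,
                             h0, inv_mass, rng)
        first.q_minus, first.p_minus, first.grad_minus = (
            second.q_minus, second.p_minus, second.grad_minus)

    total = np.logaddexp(first.log_weight, second.log_weight)
    if math.log(rng.uniform()) < second.log_weight - total:
        first.proposal, first.proposal_logp = second.proposal, second.proposal_logp
    first.log_weight = total
    first.sum_accept += second.sum_accept
    first.n_leaves += second.n_leaves
    first.diverged = second.diverged
    first.turning = second.turning or _is_turning(
        first.q_minus, first.q_plus, first.p_minus, first.p_plus, inv_mass)
    return first


def _nuts_step(logp_grad, q, logp, grad, eps, inv_mass, sqrt_mass, rng,
               max_treedepth):
    p0 = sqrt_mass * rng.standard_normal(q.shape)
    h0 = logp - _kinetic(p0, inv_mass)
    q_minus = q_plus = q
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    proposal, proposal_logp = q, logp
    log_weight = 0.0
    sum_accept, n_leaves = 0.0, 0
    divergence = False
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, q_plus, p_plus, grad_plus, logp, depth,
                              1, eps, h0, inv_mass, rng)
            q_plus, p_plus, grad_plus = sub.q_plus, sub.p_plus, sub.grad_plus
        else:
            sub = _build_tree(logp_grad, q_minus, p_minus, grad_minus, logp,
                              depth, -1, eps, h0, inv_mass, rng)
            q_minus, p_minus, grad_minus = sub.q_minus, sub.p_minus, sub.grad_minus
        sum_accept += sub.sum_accept
        n_leaves += sub.n_leaves
        if sub.diverged:
            divergence = True
            break
        if sub.turning:
            break
        # biased progressive sampling towards the new subtree
        if math.log(rng.uniform()) < sub.log_weight - log_weight:
            proposal, proposal_logp = sub.proposal, sub.proposal_logp
        log_weight = np.logaddexp(log_weight, sub.log_weight)
        depth += 1
        if _is_turning(q_minus, q_plus, p_minus, p_plus, inv_mass):
            break
    accept_stat = sum_accept / max(n_leaves, 1)
    new_logp, new_grad = (logp, grad)
    if proposal is not q:
        new_logp, new_grad = logp_grad(proposal)  # cache-free; cheap relative to tree
    return proposal, new_logp, new_grad, accept_stat, divergence, depth


def _find_reasonable_eps(logp_grad, q, logp, grad, inv_mass, sqrt_mass, rng):
    eps = 1.0
    p0 = sqrt_mass * rng.standard_normal(q.shape)
    h0 = logp - _kinetic(p0, inv_mass)
    q1, p1, logp1, _ = _leapfrog(logp_grad, q, p0, grad, eps, inv_mass)
    joint = logp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(joint):
        joint = -math.inf
    direction = 1.0 if (joint - h0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        q1, p1, logp1, _ = _leapfrog(logp_grad, q, p0, grad, eps, inv_mass)
        joint = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(joint):
            joint = -math.inf
        if direction * (joint - h0) <= direction * math.log(0.5):
            break
    return max(eps, 1e-10)


def nuts_chain(logp_grad, theta0: np.ndarray, n_warmup: int, n_draws: int,
               rng: np.random.Generator, target_accept: float = 0.8,
               max_treedepth: int = 10) -> tuple[np.ndarray, ChainStats]:
    """Run one NUTS chain; returns (draws, stats).

    ``draws`` has shape (n_draws, dim) and contains post-warmup states
    only. Mass-matrix adaptation uses an initial step-size-only buffer
    (15% of warmup), expanding variance-estimation windows, and a final
    step-size-only buffer (10%).
    """
    q = np.asarray(theta0, dtype=float).copy()
    dim = q.size
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim)
    sqrt_mass = np.ones(dim)

    init_buffer = max(1, int(0.15 * n_warmup))
    term_buffer = max(1, int(0.10 * n_warmup))
    window_end = min(init_buffer + max(25, int(0.25 * n_warmup)),
                     n_warmup - term_buffer)

    eps = _find_reasonable_eps(logp_grad, q, logp, grad, inv_mass, sqrt_mass, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    accepts, divergences, depths = [], 0, []

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        q, logp, grad, accept_stat, diverged, depth = _nuts_step(
            logp_grad, q, logp, grad, eps, inv_mass, sqrt_mass, rng,
            max_treedepth)
        if warming:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - math.sqrt(da_count) / gamma * h_bar
            eta = da_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)

            if init_buffer <= it < n_warmup - term_buffer:
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
                if it + 1 == window_end:
                    var = welford_m2 / max(welford_n - 1, 1)
                    n = welford_n
                    inv_mass = var * (n / (n + 5.0)) + 1e-3 * (5.0 / (n + 5.0))
                    sqrt_mass = 1.0 / np.sqrt(inv_mass)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    # restart dual averaging around the current step size
                    eps = _find_reasonable_eps(logp_grad, q, logp, grad,
                                               inv_mass, sqrt_mass, rng)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
                    window_end = min(init_buffer + 2 * (window_end - init_buffer),
                                     n_warmup - term_buffer)
            if it + 1 == n_warmup:
                eps = math.exp(log_eps_bar) if da_count else eps
        else:
            draws[it - n_warmup] = q
            accepts.append(accept_stat)
            divergences += int(diverged)
            depths.append(depth)

    stats = ChainStats(
        accept_rate=float(np.mean(accepts)) if accepts else math.nan,
        divergences=divergences,
        step_size=eps,
        mean_treedepth=float(np.mean(depths)) if depths else math.nan)
    return draws, stats
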