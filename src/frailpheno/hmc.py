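"""A compact Hamiltonian Monte Carlo sampler with warm-up adaptation.

Static-trajectory HMC with leapfrog integration, dual-averaging step-size
adaptation toward a target acceptance rate, and a diagonal mass matrix
estimated from the warm-up draws.  Designed for smooth, moderate-dimension
posteriors (tens of parameters) where analytic gradients are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HMCResult:
    draws: np.ndarray        # (n_chains, n_kept, dim)
    accept_rate: np.ndarray  # per chain
    step_size: np.ndarray    # per chain, post-adaptation
    divergences: int


def _leapfrog(theta, r, eps, n_steps, grad, inv_mass):
    g = grad(theta)
    for _ in range(n_steps):
        r = r + 0.5 * eps * g
        theta = theta + eps * (inv_mass * r)
        g = grad(theta)
        r = r + 0.5 * eps * g
    return theta, r, g


def _find_initial_step(logp_grad, theta, inv_mass, rng):
    eps = 0.1
    lp0, g0 = logp_grad(theta)
    r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    def joint(th, r):
        lp, _ = logp_grad(th)
        return lp - 0.5 * np.sum(inv_mass * r * r)
    h0 = lp0 - 0.5 * np.sum(inv_mass * r0 * r0)
    th, r, _ = _leapfrog(theta, r0, eps, 1, lambda t: logp_grad(t)[1], inv_mass)
    h1 = joint(th, r)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        th, r, _ = _leapfrog(theta, r0, eps, 1, lambda t: logp_grad(t)[1], inv_mass)
        h1 = joint(th, r)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-6)


def sample_chain(logp_grad, init, n_iter, warmup, seed, target_accept=0.8,
                 sim_length=1.0, max_leapfrog=64):
    """Run one HMC chain; returns (kept draws, accept rate, step size, divergences).

    ``logp_grad(theta) -> (logp, grad)`` must be finite at ``init``.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(init, dtype=float).copy()
    dim = theta.size
    inv_mass = np.ones(dim)
    grad_only = lambda t: logp_grad(t)[1]

    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    kept = np.empty((n_iter - warmup, dim))
    n_accept = 0.0
    divergences = 0
    # mass-estimation window inside warm-up
    w_lo, w_hi = int(0.25 * warmup), int(0.75 * warmup)
    mass_buf = []

    lp, g = logp_grad(theta)
    da_iter = 0
    for it in range(n_iter):
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * r0 * r0)
        n_steps = max(1, min(max_leapfrog, int(np.ceil(sim_length / eps))))
        n_steps = int(rng.integers(max(1, n_steps // 2), n_steps + 1))
        th_new, r_new, g_new = _leapfrog(theta, r0, eps, n_steps, grad_only, inv_mass)
        lp_new, _ = logp_grad(th_new)
        h1 = lp_new - 0.5 * np.sum(inv_mass * r_new * r_new)
        log_accept = h1 - h0
        if not np.isfinite(log_accept):
            log_accept = -np.inf
            if it >= warmup:
                divergences += 1
        p_accept = min(1.0, np.exp(log_accept))
        if rng.random() < p_accept:
            theta, lp = th_new, lp_new
        if it < warmup:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (target_accept - p_accept) / (da_iter + t0)
            log_eps = mu_da - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if w_lo <= it < w_hi:
                mass_buf.append(theta.copy())
            if it == w_hi - 1 and len(mass_buf) >= 10:
                var = np.var(np.asarray(mass_buf), axis=0)
                inv_mass = np.clip(var, 1e-8, None)
                # restart step-size adaptation under the new metric
                eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            n_accept += p_accept
            kept[it - warmup] = theta
    n_kept = n_iter - warmup
    return kept, n_accept / max(n_kept, 1), eps, divergences


def sample(logp_grad, init, n_chains=4, n_iter=3000, warmup=None, seed=0,
           target_accept=0.8, sim_length=1.0, max_leapfrog=64, jitter=0.5):
    """Run ``n_chains`` HMC chains from jittered initial points.

    ``init`` is a centre point; each chain starts at init + Uniform(-j, j).
    Returns an :class:`HMCResult` with draws shaped (chains, kept, dim).
    """
    if warmup is None:
        warmup = n_iter // 2
    init = np.asarray(init, dtype=float)
    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_chains)]
    draws, acc, steps = [], [], []
    div = 0
    for c in range(n_chains):
        rng0 = np.random.default_rng(chain_seeds[2 * c])
        start = init + jitter * rng0.uniform(-1, 1, size=init.size)
        lp0, _ = logp_grad(start)
        if not np.isfinite(lp0):
            start = init.copy()
        k, a, e, d = sample_chain(
            logp_grad, start, n_iter, warmup, chain_seeds[2 * c + 1],
            target_accept=target_accept, sim_length=sim_length, max_leapfrog=max_leapfrog)
        draws.append(k)
        acc.append(a)
        steps.append(e)
        div += d
    return HMCResult(np.asarray(draws), np.asarray(acc), np.asarray(steps), div)
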