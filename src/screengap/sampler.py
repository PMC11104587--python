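"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

A self-contained gradient-based sampler in the style of Stan's static-HMC
phase: leapfrog integration with a jittered number of steps, dual-averaging
step-size adaptation toward a target acceptance rate, and a diagonal mass
matrix re-estimated in two warmup windows. The target supplies the joint
log-density and its analytic gradient; all parameters must already be
transformed to the real line.

Everything is driven by a single ``numpy.random.Generator``, so a fixed
seed yields bit-identical chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ChainResult:
    samples: np.ndarray  # (draws, dim) post-warmup
    accept_rate: float
    step_size: float
    n_divergent: int


def _safe(logp_and_grad):
    def wrapped(q):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            logp, grad = logp_and_grad(q)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(q)
        return logp, grad

    return wrapped


def _leapfrog(target, q, p, grad, step, inv_mass, n_steps):
    """Standard leapfrog; returns (q, p, logp, grad) at the trajectory end."""
    p = p + 0.5 * step * grad
    logp = -np.inf
    for i in range(n_steps):
        q = q + step * inv_mass * p
        logp, grad = target(q)
        if logp == -np.inf:
            return q, p, -np.inf, grad
        if i < n_steps - 1:
            p = p + step * grad
    p = p + 0.5 * step * grad
    return q, p, logp, grad


def _find_initial_step(target, q0, inv_mass, rng):
    """Double/halve until one leapfrog step has acceptance near 0.5."""
    step = 0.1
    logp0, grad0 = target(q0)
    p0 = rng.standard_normal(q0.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * np.sum(inv_mass * p0 ** 2)
    _, p1, logp1, _ = _leapfrog(target, q0, p0, grad0, step, inv_mass, 1)
    h1 = logp1 - 0.5 * np.sum(inv_mass * p1 ** 2)
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        step *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(target, q0, p0, grad0, step, inv_mass, 1)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1 ** 2)
        if not np.isfinite(h1):
            if direction > 0:
                step /= 2.0
                break
            continue
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return step


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman-Gelman constants)."""

    def __init__(self, step0: float, target: float):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.log_step = np.log(step0)
        self.log_step_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + 10.0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_step = self.mu - np.sqrt(self.count) / 0.05 * self.h_bar
        eta = self.count ** -0.75
        self.log_step_bar = eta * self.log_step + (1.0 - eta) * self.log_step_bar
        return float(np.exp(self.log_step))

    @property
    def final_step(self) -> float:
        return float(np.exp(self.log_step_bar))


def sample_chain(
    logp_and_grad,
    init: np.ndarray,
    rng: np.random.Generator,
    warmup: int = 1000,
    draws: int = 1000,
    max_leapfrog: int = 64,
    target_accept: float = 0.85,
) -> ChainResult:
    """Run one HMC chain; returns the post-warmup draws.

    Warmup schedule (fractions of ``warmup``): 0-15% step-size only on the
    identity metric; [15%, 50%) and [50%, 85%) accumulate draws whose
    variances become the diagonal mass matrix at each window close (step
    size is re-initialized and re-averaged after each switch); the final
    15% polishes the step size on the final metric. The number of leapfrog
    steps per iteration is jittered uniformly in [80%, 100%] of
    ``max_leapfrog``.
    """
    target = _safe(logp_and_grad)
    q = np.array(init, dtype=float)
    dim = q.size
    inv_mass = np.ones(dim)
    logp, grad = target(q)
    if logp == -np.inf:
        raise FloatingPointError("non-finite log-density at the initial point")

    step = _find_initial_step(target, q, inv_mass, rng)
    adapt = _DualAveraging(step, target_accept)

    w1, w2, w3 = int(0.15 * warmup), int(0.5 * warmup), int(0.85 * warmup)
    windows = {w2: [], w3: []}
    current_window = None

    total = warmup + draws
    samples = np.empty((draws, dim))
    n_accept = 0
    n_divergent = 0
    l_lo = max(1, int(0.8 * max_leapfrog))

    for it in range(total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(inv_mass * p0 ** 2)
        n_steps = int(rng.integers(l_lo, max_leapfrog + 1))
        q1, p1, logp1, grad1 = _leapfrog(target, q, p0, grad, step, inv_mass, n_steps)
        with np.errstate(over="ignore", invalid="ignore"):
            h1 = logp1 - 0.5 * np.sum(inv_mass * p1 ** 2)
        delta = h1 - h0
        if not np.isfinite(delta):
            delta = -np.inf
        if delta < -1000.0:
            n_divergent += 1
        alpha = float(np.exp(min(delta, 0.0)))
        if np.log(rng.random()) < delta:
            q, logp, grad = q1, logp1, grad1
            if it >= warmup:
                n_accept += 1

        if it < warmup:
            step = adapt.update(alpha)
            if w1 <= it < w2:
                windows[w2].append(q.copy())
            elif w2 <= it < w3:
                windows[w3].append(q.copy())
            if (it == w2 - 1 or it == w3 - 1) and len(windows[it + 1]) >= 10:
                var = np.var(np.asarray(windows[it + 1]), axis=0)
                inv_mass = np.maximum(var, 1e-8)
                step = _find_initial_step(target, q, inv_mass, rng)
                adapt = _DualAveraging(step, target_accept)
            if it == warmup - 1:
                step = adapt.final_step
        else:
            samples[it - warmup] = q

    return ChainResult(
        samples=samples,
        accept_rate=n_accept / max(draws, 1),
        step_size=float(step),
        n_divergent=n_divergent,
    )
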