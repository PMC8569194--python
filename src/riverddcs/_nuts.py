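"""No-U-Turn sampler (NUTS) on a Euclidean diagonal metric.

A self-contained multinomial NUTS implementation in the style of Stan's
adaptive HMC: leapfrog integration, dynamic trajectory doubling terminated by
the no-U-turn criterion, multinomial sampling of the proposal across the
trajectory, dual-averaging step-size adaptation toward a target acceptance
statistic, and windowed estimation of a diagonal mass matrix during warmup.

The target is supplied as a callable returning the log density and its
gradient at an unconstrained parameter vector.  Sampler pathologies are
reported, never hidden: each draw carries a divergence flag (energy error
exceeding a fixed threshold) and the tree depth reached, so downstream
diagnostics can count divergent transitions and saturated trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "NUTSResult"]

#: energy error (in nats) beyond which a leapfrog step counts as divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NUTSResult:
    """Draws and per-draw sampler statistics from one chain."""

    draws: np.ndarray          # (n_draws, dim) post-warmup positions
    diverging: np.ndarray      # (n_draws,) bool
    treedepth: np.ndarray      # (n_draws,) int, depth reached
    max_treedepth_hit: np.ndarray  # (n_draws,) bool, trajectory saturated
    accept_stat: np.ndarray    # (n_draws,) mean Metropolis statistic
    energy: np.ndarray         # (n_draws,) Hamiltonian at the draw
    step_size: float           # adapted step size used after warmup
    inv_mass: np.ndarray       # (dim,) adapted diagonal inverse mass


class _Leaf:
    """One trajectory state: position, momentum, gradient, log density."""

    __slots__ = ("q", "r", "grad", "logp")

    def __init__(self, q, r, grad, logp):
        self.q = q
        self.r = r
        self.grad = grad
        self.logp = logp


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(r, inv_mass * r))


def _leapfrog(logp_grad, leaf: _Leaf, eps: float, inv_mass: np.ndarray) -> _Leaf:
    r = leaf.r + 0.5 * eps * leaf.grad
    q = leaf.q + eps * inv_mass * r
    logp, grad = logp_grad(q)
    r = r + 0.5 * eps * grad
    return _Leaf(q, r, grad, logp)


def _uturn(rho: np.ndarray, r_minus, r_plus, inv_mass) -> bool:
    return (
        np.dot(rho, inv_mass * r_minus) <= 0.0
        or np.dot(rho, inv_mass * r_plus) <= 0.0
    )


class _Tree:
    """A built subtree: endpoints, proposal, multinomial weight, momenta sum."""

    __slots__ = (
        "minus", "plus", "proposal", "proposal_logp", "logw", "rho",
        "sum_accept", "n_leaf", "diverged", "turning",
    )

    def __init__(self, minus, plus, proposal, proposal_logp, logw, rho,
                 sum_accept, n_leaf, diverged, turning):
        self.minus = minus
        self.plus = plus
        self.proposal = proposal
        self.proposal_logp = proposal_logp
        self.logw = logw
        self.rho = rho
        self.sum_accept = sum_accept
        self.n_leaf = n_leaf
        self.diverged = diverged
        self.turning = turning


def _build_tree(logp_grad, leaf, depth, direction, eps, h0, inv_mass, rng):
    if depth == 0:
        new = _leapfrog(logp_grad, leaf, direction * eps, inv_mass)
        if np.isfinite(new.logp):
            h = -new.logp + _kinetic(new.r, inv_mass)
        else:
            h = math.inf
        delta = h0 - h  # log multinomial weight relative to the start
        diverged = not np.isfinite(h) or (h - h0) > DIVERGENCE_THRESHOLD
        accept = math.exp(min(0.0, delta)) if np.isfinite(delta) else 0.0
        return _Tree(
            minus=new, plus=new, proposal=new, proposal_logp=new.logp,
            logw=delta if np.isfinite(delta) else -math.inf,
            rho=new.r.copy(), sum_accept=accept, n_leaf=1,
            diverged=diverged, turning=False,
        )

    first = _build_tree(logp_grad, leaf, depth - 1, direction, eps, h0, inv_mass, rng)
    if first.diverged or first.turning:
        return first
    start = first.plus if direction > 0 else first.minus
    second = _build_tree(logp_grad, start, depth - 1, direction, eps, h0, inv_mass, rng)

    sum_accept = first.sum_accept + second.sum_accept
    n_leaf = first.n_leaf + second.n_leaf
    if second.diverged:
        first.sum_accept, first.n_leaf = sum_accept, n_leaf
        first.diverged = True
        return first

    logw = np.logaddexp(first.logw, second.logw)
    # multinomial sampling within the subtree
    if math.log(rng.random() + 1e-320) < second.logw - logw:
        proposal, proposal_logp = second.proposal, second.proposal_logp
    else:
        proposal, proposal_logp = first.proposal, first.proposal_logp
    minus = first.minus if direction > 0 else second.minus
    plus = second.plus if direction > 0 else first.plus
    rho = first.rho + second.rho
    turning = second.turning or _uturn(rho, minus.r, plus.r, inv_mass)
    return _Tree(
        minus=minus, plus=plus, proposal=proposal, proposal_logp=proposal_logp,
        logw=logw, rho=rho, sum_accept=sum_accept, n_leaf=n_leaf,
        diverged=False, turning=turning,
    )


def _transition(logp_grad, current: _Leaf, eps, inv_mass, max_treedepth, rng):
    """One NUTS transition; returns (new leaf, stats dict)."""
    dim = current.q.shape[0]
    r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    leaf = _Leaf(current.q, r0, current.grad, current.logp)
    h0 = -leaf.logp + _kinetic(r0, inv_mass)

    minus = plus = leaf
    proposal, proposal_logp = leaf, leaf.logp
    logw_total = 0.0  # weight of the initial point: exp(h0 - h0)
    rho = r0.copy()
    sum_accept = 0.0
    n_leaf = 0
    diverged = False
    depth = 0
    saturated = True
    for depth in range(max_treedepth):
        direction = 1 if rng.random() < 0.5 else -1
        start = plus if direction > 0 else minus
        subtree = _build_tree(
            logp_grad, start, depth, direction, eps, h0, inv_mass, rng
        )
        sum_accept += subtree.sum_accept
        n_leaf += subtree.n_leaf
        if subtree.diverged:
            diverged = True
            saturated = False
            break
        if not subtree.turning:
            # biased progressive sampling favours the new subtree
            if math.log(rng.random() + 1e-320) < subtree.logw - logw_total:
                proposal, proposal_logp = subtree.proposal, subtree.proposal_logp
        logw_total = np.logaddexp(logw_total, subtree.logw)
        if direction > 0:
            plus = subtree.plus
        else:
            minus = subtree.minus
        rho = rho + subtree.rho
        if subtree.turning or _uturn(rho, minus.r, plus.r, inv_mass):
            saturated = False
            break
    stats = {
        "diverging": diverged,
        "treedepth": depth + 1,
        "max_treedepth_hit": saturated,
        "accept_stat": sum_accept / max(n_leaf, 1),
        "energy": -proposal_logp + _kinetic(proposal.r, inv_mass),
    }
    return _Leaf(proposal.q, proposal.r, proposal.grad, proposal_logp), stats


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        w = 1.0 / (m + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        eta = m ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return math.exp(self.log_eps)

    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)

    def restart(self, eps0: float) -> None:
        self.mu = math.log(10.0 * eps0)
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0


def _find_initial_step(logp_grad, leaf: _Leaf, inv_mass, rng, eps=1.0):
    """Crude bracketing of a step size with acceptance near 0.5."""
    dim = leaf.q.shape[0]
    r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    start = _Leaf(leaf.q, r0, leaf.grad, leaf.logp)
    h0 = -start.logp + _kinetic(r0, inv_mass)

    def log_ratio(e):
        new = _leapfrog(logp_grad, start, e, inv_mass)
        if not np.isfinite(new.logp):
            return -math.inf
        return h0 - (-new.logp + _kinetic(new.r, inv_mass))

    direction = 1.0 if log_ratio(eps) > math.log(0.5) else -1.0
    for _ in range(50):
        candidate = eps * 2.0 ** direction
        if direction * log_ratio(candidate) <= direction * math.log(0.5):
            break
        eps = candidate
    return eps


def _metric_windows(n_warmup: int) -> tuple[int, int, list[int]]:
    """Stan-style warmup schedule: init buffer, term buffer, window ends."""
    if n_warmup < 40:
        return n_warmup, 0, []
    init = max(20, int(0.15 * n_warmup))
    term = max(10, int(0.10 * n_warmup))
    base = max(20, int(0.10 * n_warmup))
    ends = []
    start = init
    width = base
    while start + width < n_warmup - term:
        if start + 3 * width >= n_warmup - term:
            width = n_warmup - term - start  # absorb the remainder
        ends.append(start + width)
        start += width
        width *= 2
    return init, term, ends


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # Stan's regularisation toward the unit metric
        return var * self.n / (self.n + 5.0) + 1e-3 * 5.0 / (self.n + 5.0)


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NUTSResult:
    """Run one NUTS chain and return post-warmup draws with statistics.

    ``logp_grad`` maps an unconstrained vector to ``(log density, gradient)``;
    non-finite log densities are treated as zero-probability regions.
    Deterministic given ``rng``'s state.
    """
    theta0 = np.asarray(theta0, dtype=float)
    dim = theta0.shape[0]
    logp, grad = logp_grad(theta0)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    current = _Leaf(theta0, np.zeros(dim), grad, logp)

    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, current, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)
    init_buf, term_buf, window_ends = _metric_windows(n_warmup)
    welford = _Welford(dim)

    for it in range(n_warmup):
        current, stats = _transition(
            logp_grad, current, eps, inv_mass, max_treedepth, rng
        )
        eps = da.update(stats["accept_stat"])
        if init_buf <= it < n_warmup - term_buf and window_ends:
            welford.push(current.q)
            if it + 1 == window_ends[0]:
                inv_mass = welford.variance()
                welford = _Welford(dim)
                window_ends.pop(0)
                eps = _find_initial_step(logp_grad, current, inv_mass, rng, da.adapted())
                da.restart(eps)
    eps = da.adapted() if n_warmup > 0 else eps

    draws = np.empty((n_draws, dim))
    keys = ("diverging", "treedepth", "max_treedepth_hit", "accept_stat", "energy")
    stat_arrays = {k: np.empty(n_draws) for k in keys}
    for it in range(n_draws):
        current, stats = _transition(
            logp_grad, current, eps, inv_mass, max_treedepth, rng
        )
        draws[it] = current.q
        for k in keys:
            stat_arrays[k][it] = stats[k]
    return NUTSResult(
        draws=draws,
        diverging=stat_arrays["diverging"].astype(bool),
        treedepth=stat_arrays["treedepth"].astype(int),
        max_treedepth_hit=stat_arrays["max_treedepth_hit"].astype(bool),
        accept_stat=stat_arrays["accept_stat"],
        energy=stat_arrays["energy"],
        step_size=eps,
        inv_mass=inv_mass,
    )
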