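"""Master equation for homogeneous groups.

For a group of ``N`` identical individuals the pooled state is the pair
``(i, j)`` of shelter occupancies (``i`` in the PS, ``j`` in the CS,
``N - i - j`` outside).  The probability ``P(i, j, t)`` obeys a birth-death
master equation whose transition rates are the per-second joining and
leaving probabilities of :mod:`sheltering.core_model`:

* ``(i-1, j) -> (i, j)`` at rate ``(N-(i-1)-j) * theta * mu_ps``
* ``(i, j-1) -> (i, j)`` at rate ``(N-i-(j-1)) * theta * mu_cs``
* ``(i+1, j) -> (i, j)`` at rate ``(i+1) * rho * exp(-sigma*i)``
* ``(i, j+1) -> (i, j)`` at rate ``(j+1) * rho * exp(-sigma*j)``

The chain satisfies detailed balance, which yields the exact product-form
stationary law

``P(i, j) ∝ N!/(i! j! (N-i-j)!) (theta/rho)^(i+j) mu_ps^i mu_cs^j
exp(sigma * [i(i-1) + j(j-1)] / 2)``.

At ``sigma = 0`` this reduces to a multinomial distribution with cell
probabilities ``(theta*mu_ps/(theta+rho), theta*mu_cs/(theta+rho),
rho/(theta+rho))`` — the nonsocial limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gammaln, logsumexp

from .core_model import ModelParams

__all__ = [
    "StateSpace",
    "StateDistribution",
    "build_generator",
    "integrate_master_equation",
    "steady_state_closed_form",
    "marginal_stats",
]

#: Largest group size for which the dense generator is built.
MAX_STATE_SPACE_N = 200


class StateSpaceSizeError(ValueError):
    pass


class SolverError(RuntimeError):
    """Raised when the ODE integration fails; carries solver diagnostics."""


@dataclass(frozen=True)
class StateSpace:
    """Enumeration of the ``(N+1)(N+2)/2`` occupancy states for group size N.

    States are ordered lexicographically by ``(i, j)``.
    """

    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.n > MAX_STATE_SPACE_N:
            raise StateSpaceSizeError(
                f"N={self.n} exceeds the configured state-space cap {MAX_STATE_SPACE_N}"
            )

    @property
    def size(self) -> int:
        return (self.n + 1) * (self.n + 2) // 2

    def states(self) -> np.ndarray:
        """Array of shape (size, 2) of (i, j) pairs, in index order."""
        out = [(i, j) for i in range(self.n + 1) for j in range(self.n + 1 - i)]
        return np.asarray(out, dtype=np.int64)

    def index(self, i: int, j: int) -> int:
        if not (0 <= i and 0 <= j and i + j <= self.n):
            raise IndexError(f"({i}, {j}) outside the state space for N={self.n}")
        # states with first coordinate < i: sum_{k<i} (N+1-k)
        return i * (self.n + 1) - i * (i - 1) // 2 + j


@dataclass
class StateDistribution:
    """Probability over the (i, j) states at one time point."""

    state_space: StateSpace
    probs: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.state_space.size,):
            raise ValueError("probability vector does not match the state space")
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    @classmethod
    def all_outside(cls, space: StateSpace) -> "StateDistribution":
        """Point mass on (0, 0): every individual outside (the t=0 condition)."""
        p = np.zeros(space.size)
        p[space.index(0, 0)] = 1.0
        return cls(space, p, time=0.0)

    def grid(self) -> np.ndarray:
        """Probabilities as a dense (N+1, N+1) array indexed [i, j] (0 off-simplex)."""
        n = self.state_space.n
        out = np.zeros((n + 1, n + 1))
        ij = self.state_space.states()
        out[ij[:, 0], ij[:, 1]] = self.probs
        return out


def build_generator(params: ModelParams, n: int) -> np.ndarray:
    """Dense rate matrix G over the StateSpace, columns summing to zero.

    ``dP/dt = G @ P`` with P indexed per :meth:`StateSpace.index`.
    """
    space = StateSpace(n)
    size = space.size
    G = np.zeros((size, size))
    jps = params.theta * params.mu_ps
    jcs = params.theta * params.mu_cs
    for i in range(n + 1):
        for j in range(n + 1 - i):
            src = space.index(i, j)
            out = n - i - j
            if out > 0:
                if jps > 0:
                    G[space.index(i + 1, j), src] += out * jps
                if jcs > 0:
                    G[space.index(i, j + 1), src] += out * jcs
            if i > 0 and params.rho > 0:
                G[space.index(i - 1, j), src] += i * params.rho * np.exp(-params.sigma * (i - 1))
            if j > 0 and params.rho > 0:
                G[space.index(i, j - 1), src] += j * params.rho * np.exp(-params.sigma * (j - 1))
    G[np.diag_indices_from(G)] -= G.sum(axis=0)
    return G


def integrate_master_equation(
    generator: np.ndarray,
    p0: StateDistribution,
    t: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> StateDistribution:
    """Propagate ``dP/dt = G P`` from ``p0`` to time ``t`` (seconds).

    Uses a stiff-capable BDF integrator with the generator as the exact
    Jacobian.  The output is clipped at -1e-12 and renormalized, so it is a
    valid distribution even in the presence of roundoff.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return StateDistribution(p0.state_space, p0.probs.copy(), time=p0.time)
    sol = solve_ivp(
        lambda _t, p: generator @ p,
        (0.0, float(t)),
        p0.probs,
        method="BDF",
        jac=lambda _t, _p: generator,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"master-equation integration failed: {sol.message}")
    p = sol.y[:, -1]
    if p.min() < -1e-12:
        raise SolverError(f"negative probability {p.min():.3e} beyond clipping tolerance")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return StateDistribution(p0.state_space, p, time=p0.time + t)


def steady_state_closed_form(params: ModelParams, n: int) -> StateDistribution:
    """Exact stationary distribution (product form), computed in log space.

    ``rho = 0`` is handled as the limit concentrated on fully sheltered
    states (``i + j = N``), which is itself the product form restricted to
    the absorbing simplex edge.
    """
    if params.theta == 0 and params.rho == 0:
        raise ValueError("steady state undefined when theta = rho = 0")
    space = StateSpace(n)
    ij = space.states()
    i = ij[:, 0].astype(float)
    j = ij[:, 1].astype(float)
    with np.errstate(divide="ignore"):
        log_mu_ps = np.log(params.mu_ps) if params.mu_ps > 0 else -np.inf
        log_mu_cs = np.log(params.mu_cs) if params.mu_cs > 0 else -np.inf
    logw = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(j + 1)
        - gammaln(n - i - j + 1)
        + params.sigma * (i * (i - 1) + j * (j - 1)) / 2.0
    )
    # weights with mu = 0 contribute only through i (or j) = 0 terms
    logw += np.where(i > 0, i * log_mu_ps, 0.0)
    logw += np.where(j > 0, j * log_mu_cs, 0.0)
    if params.rho > 0:
        logw += (i + j) * (np.log(params.theta) - np.log(params.rho)) if params.theta > 0 else np.where(
            i + j > 0, -np.inf, 0.0
        )
    else:
        # theta/rho -> inf: all mass on i + j = N
        logw = np.where(i + j == n, logw, -np.inf)
    logw -= logsumexp(logw)
    p = np.exp(logw)
    p /= p.sum()
    return StateDistribution(space, p, time=np.inf)


def marginal_stats(
    dist: StateDistribution,
    *,
    consensus_threshold: float = 0.9,
    consensus_basis: str = "total",
) -> dict:
    """Summaries of an occupancy distribution.

    Returns mean sheltered count, the probabilities of a strict PS majority,
    strict CS majority and tie, the probability of consensus (>= threshold of
    the basis population in a single shelter), and the distribution of the
    occupancy difference ``i - j``.
    """
    if consensus_basis not in {"total", "sheltered"}:
        raise ValueError("consensus_basis must be 'total' or 'sheltered'")
    space = dist.state_space
    ij = space.states()
    i, j = ij[:, 0], ij[:, 1]
    p = dist.probs
    mean_sheltered = float(((i + j) * p).sum())
    p_ps = float(p[i > j].sum())
    p_cs = float(p[j > i].sum())
    p_tie = float(p[i == j].sum())
    big = np.maximum(i, j)
    if consensus_basis == "total":
        consensus = big >= consensus_threshold * space.n
    else:
        sheltered = i + j
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(sheltered > 0, big / np.maximum(sheltered, 1), np.nan)
        consensus = (sheltered > 0) & (frac >= consensus_threshold)
    # a "consensus" also requires no second aggregate: with two shelters the
    # >=90% condition already forces the minority shelter below 10%.
    p_consensus = float(p[consensus].sum())
    diff = i - j
    diff_support = np.arange(-space.n, space.n + 1)
    diff_probs = np.zeros(diff_support.size)
    for d, q in zip(diff, p):
        diff_probs[d + space.n] += q
    return {
        "mean_sheltered": mean_sheltered,
        "p_ps_majority": p_ps,
        "p_cs_majority": p_cs,
        "p_tie": p_tie,
        "p_consensus": p_consensus,
        "consensus_threshold": consensus_threshold,
        "consensus_basis": consensus_basis,
        "diff_support": diff_support,
        "diff_probs": diff_probs,
    }
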