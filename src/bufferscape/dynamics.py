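"""Population projection through stochastic kernel sequences.

The stochastic growth rate is estimated by projecting a population through
the realized kernel sequence and averaging log growth increments after a
burn-in that discards transient dynamics:

    lambda_s = exp( E[ ln(N_{t+1} / N_t) ] )

States are renormalized to total 1 at every step for numerical stability;
the log increments are exactly those of the unnormalized matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ipm_core import KernelSequence, dominant_eigenvalue, mean_kernel

__all__ = [
    "DegenerateTrajectoryError",
    "PopulationTrajectory",
    "StochasticGrowthResult",
    "project",
    "stochastic_growth_rate",
    "stochastic_growth",
    "random_structure",
    "average_size_distribution",
]

DEFAULT_BURN_IN = 200


class DegenerateTrajectoryError(RuntimeError):
    """The projected population total reached zero (absorbing kernel)."""


@dataclass(frozen=True)
class PopulationTrajectory:
    """Normalized states and exact log growth increments of a projection.

    ``states`` has shape (T+1, n); each row sums to 1.  ``log_increments``
    has length T; ``totals`` reconstructs the unnormalized population
    totals N_t at every step.
    """

    states: np.ndarray
    log_increments: np.ndarray
    initial_total: float

    @property
    def totals(self) -> np.ndarray:
        return self.initial_total * np.exp(
            np.concatenate([[0.0], np.cumsum(self.log_increments)])
        )


def _as_A(kernels: KernelSequence | np.ndarray) -> np.ndarray:
    A = kernels.A if isinstance(kernels, KernelSequence) else np.asarray(kernels, dtype=float)
    if A.ndim != 3:
        raise ValueError(f"kernel sequence must be (T, n, n), got shape {A.shape}")
    return A


def project(kernels: KernelSequence | np.ndarray, n0: np.ndarray) -> PopulationTrajectory:
    """Project ``n0`` through the kernel sequence, renormalizing each step."""
    A = _as_A(kernels)
    n0 = np.asarray(n0, dtype=float)
    if n0.min() < 0 or n0.sum() <= 0:
        raise ValueError("n0 must be nonnegative with positive total")
    if n0.shape != (A.shape[1],):
        raise ValueError(f"n0 length {n0.shape} does not match mesh size {A.shape[1]}")
    T = A.shape[0]
    states = np.empty((T + 1, A.shape[1]))
    inc = np.empty(T)
    total0 = n0.sum()
    v = n0 / total0
    states[0] = v
    for t in range(T):
        w = A[t] @ v
        s = w.sum()
        if not s > 0:
            raise DegenerateTrajectoryError(f"population total reached 0 at step {t + 1}")
        inc[t] = np.log(s)
        v = w / s
        states[t + 1] = v
    return PopulationTrajectory(states=states, log_increments=inc, initial_total=total0)


def stochastic_growth_rate(
    traj: PopulationTrajectory | np.ndarray, burn_in: int = DEFAULT_BURN_IN
) -> float:
    """lambda_s = exp(mean of post-burn-in log increments)."""
    inc = traj.log_increments if isinstance(traj, PopulationTrajectory) else np.asarray(traj)
    if burn_in >= inc.size:
        raise ValueError(f"burn_in ({burn_in}) must be < number of increments ({inc.size})")
    tail = inc[burn_in:]
    if not np.isfinite(tail).all():
        raise ValueError("non-finite log increments in the retained window")
    return float(np.exp(tail.mean()))


@dataclass(frozen=True)
class StochasticGrowthResult:
    lambda_s: float
    lambda_1: float
    burn_in: int
    T: int


def random_structure(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random population structure: uniform on the simplex (Dirichlet(1,..,1))."""
    g = rng.standard_exponential(n)
    return g / g.sum()


def stochastic_growth(
    kernels: KernelSequence | np.ndarray,
    n0: np.ndarray | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int | None = None,
) -> StochasticGrowthResult:
    """Convenience wrapper: lambda_s of a sequence plus lambda_1 of its mean kernel.

    With ``n0`` omitted, a seeded random structure initializes the projection.
    """
    A = _as_A(kernels)
    if n0 is None:
        n0 = random_structure(A.shape[1], np.random.default_rng(seed))
    lam_s = stochastic_growth_rate(project(A, n0), burn_in)
    lam_1 = dominant_eigenvalue(mean_kernel(A))
    return StochasticGrowthResult(lambda_s=lam_s, lambda_1=lam_1, burn_in=burn_in, T=A.shape[0])


def average_size_distribution(
    kernels: KernelSequence | np.ndarray,
    n_inits: int = 1000,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Average size distribution (ASD) under a stochastic kernel sequence.

    ``n_inits`` random structures (uniform on the simplex) are projected
    through the sequence with per-step normalization; the ASD is the mean
    of all retained states (those after steps ``burn_in``..T-1), so it sums
    to 1.
    """
    A = _as_A(kernels)
    T, n = A.shape[0], A.shape[1]
    if burn_in >= T:
        raise ValueError(f"burn_in ({burn_in}) must be < T ({T})")
    if rng is None:
        rng = np.random.default_rng(seed)
    G = rng.standard_exponential((n, n_inits))
    N = G / G.sum(axis=0, keepdims=True)
    acc = np.zeros(n)
    for t in range(T):
        N = A[t] @ N
        s = N.sum(axis=0)
        if not (s > 0).all():
            raise DegenerateTrajectoryError(f"a trajectory total reached 0 at step {t + 1}")
        N /= s
        if t >= burn_in:
            acc += N.sum(axis=1)
    asd = acc / (n_inits * (T - burn_in))
    return asd / asd.sum()
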