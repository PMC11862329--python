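"""AR(1) environmental timeseries with exact sample-moment targeting.

Colored environmental noise is generated by the first-order autoregression
``X_{t+1} = phi X_t + eps_{t+1}`` with standard-normal innovations and a
stationary start, then affinely rescaled so the *sample* mean and variance
hit the driver's target exactly (not just in expectation).  Variance
manipulation is proportional: the target variance is the driver's baseline
variance times a dimensionless multiplier sigma2_prop (1 reproduces the
fitted model, 0.9/1.1 are +-10%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ipm_core import EnvironmentalIPM

__all__ = [
    "AR1Config",
    "EnvironmentSeries",
    "generate_ar1",
    "rescale_to_moments",
    "proportional_target_variance",
    "generate_driver_matrix",
    "draw_white_noise",
    "child_seed_sequence",
]


@dataclass(frozen=True)
class AR1Config:
    """Configuration of one AR(1) noise stream."""

    phi: float
    T: int
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_phi(self.phi)
        if self.T < 2:
            raise ValueError(f"T must be >= 2, got {self.T}")


@dataclass(frozen=True)
class EnvironmentSeries:
    """A driver's raw AR(1) series and its moment-targeted rescaling."""

    name: str
    raw: np.ndarray
    scaled: np.ndarray
    target_mu: float
    target_sigma2: float


def _check_phi(phi: float) -> None:
    if not abs(phi) < 1:
        raise ValueError(f"|phi| must be < 1 for stationarity, got {phi}")


def generate_ar1(
    phi: float,
    T: int,
    seed: int | np.random.SeedSequence | None = None,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Generate a stationary AR(1) series of length ``T``.

    ``X_1`` is drawn from the stationary distribution N(0, 1/(1-phi^2)) so
    the raw series carries no initialization transient.  ``noise`` may
    supply the ``T`` standard-normal innovations explicitly (common random
    numbers across parameter settings); otherwise they are drawn from
    ``seed``.
    """
    _check_phi(phi)
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    if noise is None:
        noise = np.random.default_rng(seed).standard_normal(T)
    else:
        noise = np.asarray(noise, dtype=float)
        if noise.shape != (T,):
            raise ValueError(f"noise must have shape ({T},), got {noise.shape}")
    x = np.empty(T)
    x[0] = noise[0] / np.sqrt(1.0 - phi * phi)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + noise[t]
    return x


def rescale_to_moments(x: np.ndarray, mu: float, sigma2: float) -> np.ndarray:
    """Affinely map ``x`` so its sample mean is ``mu`` and sample variance
    (n-1 denominator) is ``sigma2``, exactly.

    ``sigma2 = 0`` returns the constant series ``mu``.
    """
    x = np.asarray(x, dtype=float)
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    if sigma2 == 0.0:
        return np.full_like(x, mu)
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("cannot rescale a constant series to positive variance")
    return mu + (x - x.mean()) * (np.sqrt(sigma2) / sd)


def proportional_target_variance(sigma2_init: float, sigma2_prop: float) -> float:
    """Target variance under proportional manipulation: sigma2_init * sigma2_prop."""
    if sigma2_init < 0 or sigma2_prop < 0:
        raise ValueError("variances and multipliers must be >= 0")
    return sigma2_init * sigma2_prop


def child_seed_sequence(seed: int | None, index: int) -> np.random.SeedSequence:
    """Deterministic per-driver child seed: SeedSequence keyed on (seed, index)."""
    return np.random.SeedSequence((0 if seed is None else int(seed), int(index)))


def draw_white_noise(T: int, d: int, seed: int | np.random.SeedSequence | None) -> np.ndarray:
    """Draw a (T, d) matrix of independent standard-normal innovations,
    one column per driver (column k uses the child seed for index k)."""
    if isinstance(seed, np.random.SeedSequence):
        children = seed.spawn(d)
        return np.column_stack(
            [np.random.default_rng(c).standard_normal(T) for c in children]
        )
    return np.column_stack(
        [
            np.random.default_rng(child_seed_sequence(seed, k)).standard_normal(T)
            for k in range(d)
        ]
    )


def generate_driver_matrix(
    ipm: EnvironmentalIPM,
    phi: float,
    sigma2_prop: float,
    T: int,
    seed: int | None = None,
    noise: np.ndarray | None = None,
    moment_window: slice | None = None,
) -> np.ndarray:
    """Simulate all of a model's drivers as independent AR(1) series.

    Returns a (T, d) matrix ordered by driver declaration; each column is
    rescaled to sample mean mu_d and sample variance sigma2_init_d *
    sigma2_prop.  The same autocorrelation phi and multiplier apply to all
    drivers.  ``noise`` may supply a (T, d) innovation matrix (shared
    across grid cells for common-random-numbers landscapes).

    ``moment_window`` restricts the sample-moment targeting to a slice of
    timesteps (e.g. the post-burn-in window a growth-rate estimate will
    actually measure); the affine map fitted on that window is applied to
    the whole series.  With autocorrelated noise the variance of a window
    can drift well away from the full-series variance, so targeting the
    measurement window is what holds the experimental variance manipulation
    exact where it matters.  ``None`` targets the full series.
    """
    d = len(ipm.drivers)
    if d == 0:
        raise ValueError("model declares no environmental drivers")
    if noise is not None:
        noise = np.asarray(noise, dtype=float)
        if noise.shape != (T, d):
            raise ValueError(f"noise must have shape ({T}, {d}), got {noise.shape}")
    cols = []
    for k, drv in enumerate(ipm.drivers):
        eps = noise[:, k] if noise is not None else None
        raw = generate_ar1(phi, T, seed=child_seed_sequence(seed, k), noise=eps)
        target = proportional_target_variance(drv.sigma2_init, sigma2_prop)
        if moment_window is None:
            cols.append(rescale_to_moments(raw, drv.mu, target))
        else:
            win = raw[moment_window]
            if win.size < 2:
                raise ValueError("moment window must contain at least 2 steps")
            if target == 0.0:
                cols.append(np.full_like(raw, drv.mu))
                continue
            sd = win.std(ddof=1)
            if sd == 0.0:
                raise ValueError("cannot rescale a constant window to positive variance")
            cols.append(drv.mu + (raw - win.mean()) * (np.sqrt(target) / sd))
    return np.column_stack(cols)
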