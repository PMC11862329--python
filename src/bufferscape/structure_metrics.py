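"""Population-structure diagnostics for demographic buffering.

Two numerical routes link environmental effects on buffering to
population structure:

* deviance-based — compare the stage-weighted expected buffering value
  (the per-stage buffering profile averaged under the average size
  distribution, ASD) with the plain summed elasticity across a landscape
  of simulations, after z-scoring both across grid cells;
* size-based — the mean buffered size (MBS), the elasticity-weighted
  centroid of the size domain expressed on a relative 0 (smallest size,
  alpha) to 1 (largest size, omega) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ipm_core import SizeMesh

__all__ = [
    "StructureMetrics",
    "expected_buffering_given_asd",
    "scaled_deviance",
    "mean_buffered_size",
]


@dataclass(frozen=True)
class StructureMetrics:
    """Structure diagnostics for one simulated environment."""

    asd: np.ndarray
    expected_buffering: float
    mean_buffered_size: float
    deviance: float | None = None  # filled at grid level


def expected_buffering_given_asd(profile: np.ndarray, asd: np.ndarray) -> float:
    """ASD-weighted expected buffering: sum_j asd_j * profile_j."""
    profile = np.asarray(profile, dtype=float)
    asd = np.asarray(asd, dtype=float)
    if profile.shape != asd.shape:
        raise ValueError(
            f"profile and ASD lengths differ: {profile.shape} vs {asd.shape}"
        )
    return float(asd @ profile)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("z-score undefined for a constant vector across grid cells")
    return (x - x.mean()) / sd


def scaled_deviance(expected: np.ndarray, sum_E: np.ndarray) -> np.ndarray:
    """Elementwise difference of z-scored expected buffering and z-scored
    summed elasticities across grid cells (mean 0 by construction).

    Invariant under positive affine transforms of either input; requires
    at least 3 cells and nonconstant inputs.
    """
    expected = np.asarray(expected, dtype=float)
    sum_E = np.asarray(sum_E, dtype=float)
    if expected.shape != sum_E.shape:
        raise ValueError("input vectors must have equal length")
    if expected.size < 3:
        raise ValueError("scaled deviance needs at least 3 grid cells")
    return _zscore(expected) - _zscore(sum_E)


def mean_buffered_size(
    profile: np.ndarray, mesh: SizeMesh, convention: str = "normalized"
) -> float:
    """Mean buffered size: elasticity-weighted centroid of the size domain.

    The per-stage buffering profile is normalized to weights w_j =
    profile_j / sum(profile); the centroid is c = sum_j z_j w_j over mesh
    midpoints.  ``normalized`` returns (c - alpha)/(omega - alpha) (0 at
    the smallest possible size, 1 at the largest); ``literal`` returns
    (c - alpha)/omega.  The two coincide when alpha = 0.  Mixed-sign
    profiles can push the value outside [0, 1]; that raises a warning,
    never an exception.
    """
    if convention not in ("normalized", "literal"):
        raise ValueError(f"unknown convention {convention!r}")
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (mesh.n_mesh,):
        raise ValueError(
            f"profile length {profile.shape} does not match mesh size {mesh.n_mesh}"
        )
    total = profile.sum()
    if total == 0.0:
        raise ValueError("profile sums to 0: centroid undefined")
    w = profile / total
    c = float(mesh.midpoints @ w)
    if convention == "normalized":
        mbs = (c - mesh.alpha) / (mesh.omega - mesh.alpha)
    else:
        mbs = (c - mesh.alpha) / mesh.omega
    if convention == "normalized" and not 0.0 <= mbs <= 1.0:
        warnings.warn(
            f"mean buffered size {mbs:.4g} outside [0, 1]; the buffering "
            "profile has mixed signs",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(mbs)
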