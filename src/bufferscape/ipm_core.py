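"""Environmentally explicit integral projection models (IPMs).

An IPM projects a size-structured population across discrete timesteps
through a kernel ``K(z', z)`` built from vital-rate regressions fitted
over size ``z`` and one or more named environmental drivers.  The kernel
splits into a progression subkernel ``P`` (survival times the probability
density of moving from size ``z`` to ``z'``) and a fertility subkernel
``F`` (per-capita recruit production times the recruit-size density).

Kernels are discretized with the midpoint rule on a regular size mesh:
the continuous densities are evaluated at cell midpoints and multiplied
by the cell width.  Probability mass falling outside the size domain is
lost ("eviction") unless column renormalization is requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SpecificationError",
    "InvalidModelError",
    "SizeMesh",
    "LinearPredictorSpec",
    "Driver",
    "EnvironmentalIPM",
    "KernelSet",
    "KernelSequence",
    "evaluate_predictor",
    "build_kernel",
    "build_kernel_sequence",
    "mean_kernel",
    "dominant_eigenvalue",
    "load_model",
    "save_model",
]

LINKS = ("identity", "log", "logit")


class SpecificationError(ValueError):
    """A vital-rate regression references an unresolvable variable."""


class InvalidModelError(ValueError):
    """The model definition violates a structural invariant."""


@dataclass(frozen=True)
class SizeMesh:
    """Regular midpoint mesh over the size domain [alpha, omega].

    Cell midpoints are ``z_j = alpha + (j - 1/2) h`` for ``j = 1..n_mesh``
    with width ``h = (omega - alpha) / n_mesh``.
    """

    alpha: float
    omega: float
    n_mesh: int

    def __post_init__(self) -> None:
        if not self.alpha < self.omega:
            raise InvalidModelError(f"alpha ({self.alpha}) must be < omega ({self.omega})")
        if self.n_mesh < 2:
            raise InvalidModelError(f"n_mesh must be >= 2, got {self.n_mesh}")

    @property
    def width(self) -> float:
        return (self.omega - self.alpha) / self.n_mesh

    @property
    def midpoints(self) -> np.ndarray:
        j = np.arange(1, self.n_mesh + 1, dtype=float)
        return self.alpha + (j - 0.5) * self.width


@dataclass(frozen=True)
class LinearPredictorSpec:
    """A generalized linear predictor over size and environmental drivers.

    ``terms`` maps variable names to coefficients.  Recognized variables:
    ``size``, ``size^2``, any declared driver name, and ``<driver>:size``
    interaction products.  The response is ``invlink(intercept + sum)``.
    """

    intercept: float
    terms: tuple[tuple[str, float], ...] = ()
    link: str = "identity"

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise InvalidModelError(f"link must be one of {LINKS}, got {self.link!r}")
        # canonical term order: evaluation is then bitwise-reproducible
        # regardless of how the spec was written or deserialized
        object.__setattr__(
            self, "terms", tuple(sorted((str(v), float(c)) for v, c in self.terms))
        )

    def driver_names(self) -> set[str]:
        """Names of environmental drivers this predictor references."""
        out = set()
        for var, _ in self.terms:
            if var in ("size", "size^2"):
                continue
            out.add(var.split(":", 1)[0] if var.endswith(":size") else var)
        return out


@dataclass(frozen=True)
class Driver:
    """An environmental driver with long-run mean and baseline variance."""

    name: str
    mu: float
    sigma2_init: float

    def __post_init__(self) -> None:
        if self.sigma2_init < 0:
            raise InvalidModelError(f"driver {self.name!r}: sigma2_init must be >= 0")


def _resolve(var: str, z: np.ndarray, drivers: Mapping[str, float]) -> np.ndarray | float:
    if var == "size":
        return z
    if var == "size^2":
        return z * z
    if var.endswith(":size"):
        name = var[: -len(":size")]
        if name not in drivers:
            raise SpecificationError(f"unresolvable variable {var!r}: unknown driver {name!r}")
        return drivers[name] * z
    if var in drivers:
        return drivers[var]
    raise SpecificationError(f"unresolvable variable {var!r}")


_INVLINK = {"identity": lambda x: x, "log": np.exp, "logit": expit}


def evaluate_predictor(
    spec: LinearPredictorSpec, z: float | np.ndarray, drivers: Mapping[str, float]
) -> np.ndarray | float:
    """Evaluate a linear predictor at size(s) ``z`` on the response scale."""
    z = np.asarray(z, dtype=float)
    eta = np.full_like(z, spec.intercept, dtype=float)
    for var, coeff in spec.terms:
        eta = eta + coeff * np.asarray(_resolve(var, z, drivers), dtype=float)
    out = _INVLINK[spec.link](eta)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnvironmentalIPM:
    """A size-structured IPM whose regressions respond to named drivers.

    Fertility is composed as ``p_repro(z) * offspring(z) * recruit-density``;
    a missing component contributes the identity value 1 (e.g. a model with
    no reproduction-probability regression treats reproduction as certain).
    """

    mesh: SizeMesh
    survival: LinearPredictorSpec
    growth_mean: LinearPredictorSpec
    growth_sd: float
    recruit_mean: float
    recruit_sd: float
    p_repro: LinearPredictorSpec | None = None
    offspring: LinearPredictorSpec | None = None
    drivers: tuple[Driver, ...] = ()

    def __post_init__(self) -> None:
        if self.growth_sd <= 0:
            raise InvalidModelError(f"growth_sd must be > 0, got {self.growth_sd}")
        if self.recruit_sd <= 0:
            raise InvalidModelError(f"recruit_sd must be > 0, got {self.recruit_sd}")
        if self.survival.link != "logit":
            raise InvalidModelError("survival must use the logit link")
        if self.growth_mean.link != "identity":
            raise InvalidModelError("growth_mean must use the identity link")
        if self.p_repro is not None and self.p_repro.link != "logit":
            raise InvalidModelError("p_repro must use the logit link")
        if self.offspring is not None and self.offspring.link != "log":
            raise InvalidModelError("offspring must use the log link")
        declared = {d.name for d in self.drivers}
        referenced = set()
        for spec in (self.survival, self.growth_mean, self.p_repro, self.offspring):
            if spec is not None:
                referenced |= spec.driver_names()
        missing = referenced - declared
        if missing:
            raise InvalidModelError(f"drivers referenced but not declared: {sorted(missing)}")

    @property
    def driver_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.drivers)

    def driver_means(self) -> dict[str, float]:
        return {d.name: d.mu for d in self.drivers}


@dataclass(frozen=True)
class KernelSet:
    """Discretized kernel triple; ``K = P + F`` exactly by construction."""

    P: np.ndarray
    F: np.ndarray
    K: np.ndarray


@dataclass(frozen=True)
class KernelSequence:
    """A temporal sequence of discretized kernels A_t = P_t + F_t.

    Arrays have shape ``(T, n_mesh, n_mesh)``.
    """

    A: np.ndarray
    P: np.ndarray | None = None
    F: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise InvalidModelError(f"kernel array must be (T, n, n), got {A.shape}")
        object.__setattr__(self, "A", A)

    def __len__(self) -> int:
        return self.A.shape[0]

    @property
    def n_mesh(self) -> int:
        return self.A.shape[1]

    def element_series(self, i: int, j: int) -> np.ndarray:
        """Timeseries a_ij,t of one kernel element."""
        return self.A[:, i, j]


def _gaussian_columns(mesh: SizeMesh, means: np.ndarray, sd: float) -> np.ndarray:
    """Matrix G[i, j] = density of N(means[j], sd) at midpoint z_i, times h."""
    z = mesh.midpoints
    return norm.pdf(z[:, None], loc=means[None, :], scale=sd) * mesh.width


def build_kernel(
    ipm: EnvironmentalIPM,
    driver_values: Mapping[str, float],
    renormalize_growth: bool = False,
) -> KernelSet:
    """Discretize the IPM at the given environment into (P, F, K) matrices.

    ``renormalize_growth`` rescales each growth column to unit mass before
    applying survival, so no survival probability is lost to eviction.
    """
    missing = [d.name for d in ipm.drivers if d.name not in driver_values]
    if missing:
        raise SpecificationError(f"driver values missing for: {missing}")
    z = ipm.mesh.midpoints
    s = np.asarray(evaluate_predictor(ipm.survival, z, driver_values))
    g_mean = np.asarray(evaluate_predictor(ipm.growth_mean, z, driver_values))
    G = _gaussian_columns(ipm.mesh, g_mean, ipm.growth_sd)
    if renormalize_growth:
        colsum = G.sum(axis=0)
        np.divide(G, colsum[None, :], out=G, where=colsum[None, :] > 0)
    P = G * s[None, :]

    p_rep = (
        np.ones_like(z)
        if ipm.p_repro is None
        else np.asarray(evaluate_predictor(ipm.p_repro, z, driver_values))
    )
    n_off = (
        np.ones_like(z)
        if ipm.offspring is None
        else np.asarray(evaluate_predictor(ipm.offspring, z, driver_values))
    )
    recruit_density = norm.pdf(z, loc=ipm.recruit_mean, scale=ipm.recruit_sd) * ipm.mesh.width
    F = recruit_density[:, None] * (p_rep * n_off)[None, :]

    if not (np.isfinite(P).all() and np.isfinite(F).all()):
        raise InvalidModelError("non-finite kernel entries; check regression coefficients")
    return KernelSet(P=P, F=F, K=P + F)


def build_kernel_sequence(
    ipm: EnvironmentalIPM, env: np.ndarray, renormalize_growth: bool = False
) -> KernelSequence:
    """Build the kernel timeseries for a (T, d) matrix of driver values.

    Columns of ``env`` follow the model's driver declaration order.
    """
    env = np.atleast_2d(np.asarray(env, dtype=float))
    names = ipm.driver_names
    if env.shape[1] != len(names):
        raise SpecificationError(
            f"environment matrix has {env.shape[1]} columns but model declares "
            f"{len(names)} drivers {list(names)}"
        )
    T, n = env.shape[0], ipm.mesh.n_mesh
    A = np.empty((T, n, n))
    P = np.empty((T, n, n))
    F = np.empty((T, n, n))
    for t in range(T):
        ks = build_kernel(ipm, dict(zip(names, env[t])), renormalize_growth)
        A[t], P[t], F[t] = ks.K, ks.P, ks.F
    return KernelSequence(A=A, P=P, F=F)


def mean_kernel(seq: KernelSequence | np.ndarray) -> np.ndarray:
    """Elementwise arithmetic mean of a kernel sequence over time."""
    A = seq.A if isinstance(seq, KernelSequence) else np.asarray(seq, dtype=float)
    if A.ndim != 3 or A.shape[0] < 1:
        raise InvalidModelError("mean_kernel needs a nonempty (T, n, n) sequence")
    return A.mean(axis=0)


def dominant_eigenvalue(M: np.ndarray, tol: float = 1e-10, max_iter: int = 10000) -> float:
    """Spectral radius of a nonnegative matrix via power iteration.

    Falls back to a full eigendecomposition when the iteration does not
    converge (periodic/reducible matrices).
    """
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise InvalidModelError("matrix has non-finite entries")
    n = M.shape[0]
    v = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        w = M @ v
        nw = np.linalg.norm(w)
        if nw == 0.0:
            return 0.0
        lam_new = v @ w / (v @ v)
        w /= nw
        if abs(lam_new - lam) <= tol * max(abs(lam_new), 1e-30) and lam_new > 0:
            return float(lam_new)
        lam, v = lam_new, w
    return float(np.max(np.abs(np.linalg.eigvals(M))))


# ---------------------------------------------------------------------------
# JSON model format


def _spec_to_dict(spec: LinearPredictorSpec) -> dict:
    return {
        "intercept": spec.intercept,
        "coefficients": {v: c for v, c in spec.terms},
        "link": spec.link,
    }


def _spec_from_dict(d: Mapping) -> LinearPredictorSpec:
    return LinearPredictorSpec(
        intercept=float(d["intercept"]),
        terms=tuple(sorted(d.get("coefficients", {}).items())),
        link=d.get("link", "identity"),
    )


def model_to_dict(ipm: EnvironmentalIPM) -> dict:
    vr: dict = {
        "survival": _spec_to_dict(ipm.survival),
        "growth_mean": _spec_to_dict(ipm.growth_mean),
        "growth_sd": ipm.growth_sd,
        "recruit_mean": ipm.recruit_mean,
        "recruit_sd": ipm.recruit_sd,
    }
    if ipm.p_repro is not None:
        vr["p_repro"] = _spec_to_dict(ipm.p_repro)
    if ipm.offspring is not None:
        vr["offspring"] = _spec_to_dict(ipm.offspring)
    return {
        "mesh": {"alpha": ipm.mesh.alpha, "omega": ipm.mesh.omega, "n_mesh": ipm.mesh.n_mesh},
        "drivers": [
            {"name": d.name, "mu": d.mu, "sigma2_init": d.sigma2_init} for d in ipm.drivers
        ],
        "vital_rates": vr,
    }


def model_from_dict(doc: Mapping) -> EnvironmentalIPM:
    try:
        mesh = SizeMesh(
            alpha=float(doc["mesh"]["alpha"]),
            omega=float(doc["mesh"]["omega"]),
            n_mesh=int(doc["mesh"]["n_mesh"]),
        )
        vr = doc["vital_rates"]
        return EnvironmentalIPM(
            mesh=mesh,
            survival=_spec_from_dict(vr["survival"]),
            growth_mean=_spec_from_dict(vr["growth_mean"]),
            growth_sd=float(vr["growth_sd"]),
            recruit_mean=float(vr["recruit_mean"]),
            recruit_sd=float(vr["recruit_sd"]),
            p_repro=_spec_from_dict(vr["p_repro"]) if "p_repro" in vr else None,
            offspring=_spec_from_dict(vr["offspring"]) if "offspring" in vr else None,
            drivers=tuple(
                Driver(name=d["name"], mu=float(d["mu"]), sigma2_init=float(d["sigma2_init"]))
                for d in doc.get("drivers", [])
            ),
        )
    except KeyError as exc:
        raise SpecificationError(f"model document missing field: {exc}") from exc


def load_model(path: str | Path) -> EnvironmentalIPM:
    """Read an IPM from the JSON model format."""
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def save_model(ipm: EnvironmentalIPM, path: str | Path) -> None:
    """Write an IPM to the JSON model format."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(ipm), fh, indent=2, sort_keys=True)
        fh.write("\n")
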