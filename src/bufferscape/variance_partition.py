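"""Polynomial-regression variance partitioning with AIC model selection.

Any landscape response (summed elasticity, deviance, mean buffered size,
P-F contribution, ...) is regressed on environmental autocorrelation and
proportional variance using a fixed suite of 18 candidate models: degrees
1-3 per predictor, with and without the linear-by-linear interaction.
The most parsimonious model is chosen by AIC, and the selected model's
variance is partitioned into autocorrelation, variance, interaction and
residual shares via sequential (Type I) sums of squares divided by the
total sum of squares.  On a fully factorial centered grid the two
predictor blocks are orthogonal, so their shares do not depend on entry
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "CandidateModel",
    "PartitionResult",
    "build_design",
    "fit_ols",
    "aic_select",
    "partition_contributions",
    "partition_response",
]

#: relative RSS floor keeping AIC finite on noiseless responses
RSS_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class CandidateModel:
    degree_auto: int
    degree_var: int
    interaction: bool
    k: int
    rss: float
    aic: float


@dataclass(frozen=True)
class PartitionResult:
    r_squared: float
    share_auto: float
    share_var: float
    share_interaction: float
    share_residual: float
    selected: CandidateModel


def _term_columns(
    phi: np.ndarray, var: np.ndarray, degree_auto: int, degree_var: int, interaction: bool
) -> tuple[list[np.ndarray], list[str]]:
    """Centered polynomial term columns in fixed entry order.

    Predictors are centered before powering; each power column (and the
    interaction product) is then re-centered to mean zero, which makes the
    autocorrelation and variance blocks exactly orthogonal on a fully
    factorial grid.
    """
    a = phi - phi.mean()
    v = var - var.mean()
    cols, names = [], []
    for p in range(1, degree_auto + 1):
        c = a**p
        cols.append(c - c.mean())
        names.append(f"auto^{p}")
    for p in range(1, degree_var + 1):
        c = v**p
        cols.append(c - c.mean())
        names.append(f"var^{p}")
    if interaction:
        c = a * v
        cols.append(c - c.mean())
        names.append("auto:var")
    return cols, names


def build_design(
    phi: np.ndarray,
    var: np.ndarray,
    degree_auto: int,
    degree_var: int,
    interaction: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept | centered power columns | interaction]."""
    phi = np.asarray(phi, dtype=float)
    var = np.asarray(var, dtype=float)
    if phi.shape != var.shape or phi.ndim != 1:
        raise ValueError("phi and var must be equal-length 1-D arrays")
    if not (1 <= degree_auto <= 3 and 1 <= degree_var <= 3):
        raise ValueError("polynomial degrees must be in {1, 2, 3}")
    cols, names = _term_columns(phi, var, degree_auto, degree_var, interaction)
    X = np.column_stack([np.ones_like(phi)] + cols)
    names = ["intercept"] + names
    if phi.size < X.shape[1]:
        raise ValueError(f"need at least {X.shape[1]} observations, got {phi.size}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns among {names}"
        )
    return X, names


def fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least squares fit: returns (coefficients, rss, fitted values)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < X.shape[1]:
        raise ValueError("more columns than rows")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"design is rank deficient (rank {rank} < {X.shape[1]})")
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return beta, rss, fitted


def _aic(n: int, rss: float, k: int, floor: float) -> float:
    # Gaussian log-likelihood up to additive constants; k + 2 counts the
    # intercept and the error variance.
    return n * np.log(max(rss, floor) / n) + 2.0 * (k + 2)


def aic_select(phi: np.ndarray, var: np.ndarray, y: np.ndarray) -> CandidateModel:
    """Fit all 18 candidates and return the minimum-AIC model.

    Ties break to the fewest parameters, then the lowest autocorrelation
    degree, then the lowest variance degree.
    """
    phi = np.asarray(phi, dtype=float)
    var = np.asarray(var, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError(f"AIC selection needs n >= 10, got {n}")
    floor = n * RSS_FLOOR_REL * float(np.var(y))
    candidates = []
    for da, dv, inter in product((1, 2, 3), (1, 2, 3), (False, True)):
        X, _ = build_design(phi, var, da, dv, inter)
        _, rss, _ = fit_ols(X, y)
        k = da + dv + int(inter)
        candidates.append(
            CandidateModel(
                degree_auto=da,
                degree_var=dv,
                interaction=inter,
                k=k,
                rss=rss,
                aic=_aic(n, rss, k, floor),
            )
        )
    return min(candidates, key=lambda c: (c.aic, c.k, c.degree_auto, c.degree_var))


def aic_table(phi: np.ndarray, var: np.ndarray, y: np.ndarray) -> list[CandidateModel]:
    """All 18 fitted candidates, sorted by the selection order."""
    phi, var, y = (np.asarray(x, dtype=float) for x in (phi, var, y))
    n = y.size
    floor = n * RSS_FLOOR_REL * float(np.var(y))
    out = []
    for da, dv, inter in product((1, 2, 3), (1, 2, 3), (False, True)):
        X, _ = build_design(phi, var, da, dv, inter)
        _, rss, _ = fit_ols(X, y)
        k = da + dv + int(inter)
        out.append(CandidateModel(da, dv, inter, k, rss, _aic(n, rss, k, floor)))
    return sorted(out, key=lambda c: (c.aic, c.k, c.degree_auto, c.degree_var))


def partition_contributions(
    phi: np.ndarray, var: np.ndarray, y: np.ndarray, selected: CandidateModel
) -> PartitionResult:
    """Sequential (Type I) sums-of-squares shares for the selected model.

    Terms enter in fixed order: autocorrelation powers ascending, variance
    powers ascending, then the interaction.  Each predictor's share is its
    terms' summed SS divided by the total sum of squares; the residual
    share is RSS/TSS, and the shares sum to 1.
    """
    phi = np.asarray(phi, dtype=float)
    var = np.asarray(var, dtype=float)
    y = np.asarray(y, dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("constant response: total sum of squares is 0")
    cols, names = _term_columns(
        phi, var, selected.degree_auto, selected.degree_var, selected.interaction
    )
    X = np.ones((y.size, 1))
    rss_prev = tss
    ss: dict[str, float] = {"auto": 0.0, "var": 0.0, "inter": 0.0}
    for col, name in zip(cols, names):
        X = np.column_stack([X, col])
        _, rss, _ = fit_ols(X, y)
        block = "inter" if name == "auto:var" else ("auto" if name.startswith("auto^") else "var")
        ss[block] += max(rss_prev - rss, 0.0)
        rss_prev = rss
    return PartitionResult(
        r_squared=1.0 - rss_prev / tss,
        share_auto=ss["auto"] / tss,
        share_var=ss["var"] / tss,
        share_interaction=ss["inter"] / tss,
        share_residual=rss_prev / tss,
        selected=selected,
    )


def partition_response(phi: np.ndarray, var: np.ndarray, y: np.ndarray) -> PartitionResult:
    """AIC-select the polynomial model for y and partition its variance."""
    selected = aic_select(phi, var, y)
    return partition_contributions(phi, var, y, selected)
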