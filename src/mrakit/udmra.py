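"""Unidirectional MRA: extending an inferred network with non-perturbed genes.

A gene X that was never perturbed can still be appended to an MRA network
as an (n+1)-th module: its outgoing connection coefficients are fixed at
zero (no perturbation data on X exists to estimate them), while its
incoming coefficients r_{n+1,j} solve the linear system

    (dx_{n+1}/x_{n+1})_{q_k} = sum_j r_{n+1,j} (dx_j/x_j)_{q_k},  k = 1..n,

i.e. the gene's observed responses to the n elementary perturbations are
expressed in the basis of the core modules' responses.  The fitted row then
predicts the gene's expression under any combined perturbation of the core
network (udMRA), optionally after optimizing the relative weights of the
elementary perturbations on held-out core-module observations (udMRA.ab).
Naive single-perturbation aggregates (mean, geometric mean, maximum) serve
as baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import gmean

from .core import (
    CombinedPerturbation,
    GlobalResponseMatrix,
    LocalResponseNetwork,
    predict_response,
)
from .exceptions import DataError, InferenceError, SaturationError

logger = logging.getLogger(__name__)

__all__ = [
    "AppendedGene",
    "UdmraRow",
    "WeightFit",
    "fit_udmra_row",
    "predict_gene",
    "optimize_weights",
    "naive_predictors",
    "benchmark_predictions",
    "BenchmarkResult",
]


@dataclass(frozen=True)
class AppendedGene:
    """A non-perturbed gene: its symmetric relative changes under each
    elementary perturbation (core module order) and its basal abundance."""

    gene: str
    responses: np.ndarray
    basal_abundance: float

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", resp)
        if resp.ndim != 1:
            raise DataError(f"{self.gene}: responses must form a vector")
        if not np.all(np.isfinite(resp)) or np.any(np.abs(resp) >= 2):
            raise DataError(
                f"{self.gene}: responses must be finite and lie in (-2, 2)"
            )
        if not self.basal_abundance > 0:
            raise DataError(f"{self.gene}: basal abundance must be positive")


@dataclass(frozen=True)
class UdmraRow:
    """Incoming connection coefficients of an appended gene; its outgoing
    coefficients are identically zero by construction and not stored."""

    gene: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )


@dataclass(frozen=True)
class WeightFit:
    """Optimized perturbation weights with the search trace."""

    weights: Mapping[str, float]
    objective_value: float
    trace: tuple = ()  # (weight vector tuple, objective) pairs

    def __post_init__(self) -> None:
        if self.trace:
            best = min(obj for _, obj in self.trace)
            if self.objective_value > best + 1e-12:
                raise DataError("objective_value must be the minimum over the trace")


def fit_udmra_row(R: GlobalResponseMatrix, gene: AppendedGene) -> UdmraRow:
    """Solve for the gene's incoming coefficients: ``responses = coeffs @ R``.

    Exact for consistent systems (an exactly determined n x n solve).
    """
    if gene.responses.shape != (R.n,):
        raise DataError(
            f"{gene.gene}: response vector length {gene.responses.shape[0]} "
            f"!= module count {R.n}"
        )
    cond = np.linalg.cond(R.values)
    if not np.isfinite(cond) or cond > 1e8:
        raise InferenceError(
            f"response matrix too ill-conditioned to fit {gene.gene!r} "
            f"(condition number {cond:.3g})"
        )
    # row-vector solve: responses = coeffs @ R  <=>  R^T coeffs^T = responses^T
    coeffs = np.linalg.solve(R.values.T, gene.responses)
    return UdmraRow(gene=gene.gene, coefficients=coeffs)


def predict_gene(
    row: UdmraRow,
    net: LocalResponseNetwork,
    c: CombinedPerturbation,
    basal_abundance: float,
) -> tuple[float, float]:
    """Predict the appended gene under combined perturbation *c*.

    Core-module changes ``v = -r^-1 diag(P) c``; the gene's relative change
    is ``u = coefficients . v`` and its abundance
    ``basal * (2 + u) / (2 - u)``.  Returns ``(abundance, u)``.
    """
    if not basal_abundance > 0:
        raise DataError(f"{row.gene}: basal abundance must be positive")
    v = predict_response(net, c)
    sat = np.flatnonzero(np.abs(v) >= 2)
    if sat.size:
        raise SaturationError(
            f"core module {net.modules[sat[0]]!r} predicted outside (-2, 2)"
        )
    u = float(row.coefficients @ v)
    if abs(u) >= 2:
        raise SaturationError(
            f"{row.gene}: predicted relative change {u:.4g} outside (-2, 2)"
        )
    return basal_abundance * (2.0 + u) / (2.0 - u), u


def optimize_weights(
    net: LocalResponseNetwork,
    observed_core: Sequence[float],
    free_modules: Sequence[str],
    *,
    base_weights: Mapping[str, float] | None = None,
    grid: tuple[float, float, float] = (0.0, 2.0, 0.05),
    objective: Literal["relative", "absolute"] = "relative",
) -> WeightFit:
    """Find perturbation weights minimizing core-module prediction error.

    *observed_core* holds the observed relative changes of the core modules
    under the combined perturbation.  Weights at *free_modules* are
    searched over a dense grid (then refined with a derivative-free local
    optimizer); the others stay at *base_weights* (default 0, i.e. only the
    listed modules are perturbed).  The default objective is the summed
    squared relative error ``sum_i ((pred_i - obs_i) / obs_i)^2``;
    "absolute" drops the normalization (required when observations are
    near zero).
    """
    obs = np.asarray(observed_core, dtype=float)
    if obs.shape != (net.n,):
        raise DataError(f"observed vector length {obs.shape} != module count {net.n}")
    if np.any(np.abs(obs) >= 2):
        raise DataError("observed relative changes must lie in (-2, 2)")
    free = list(free_modules)
    if not free:
        raise DataError("need at least one free module")
    unknown = set(free) - set(net.modules)
    if unknown:
        raise DataError(f"unknown modules: {sorted(unknown)}")
    if objective == "relative" and np.all(np.abs(obs) < 1e-12):
        raise DataError(
            "all observed changes are ~0: the relative-error objective is "
            "undefined; use objective='absolute'"
        )
    base = np.array(
        [float((base_weights or {}).get(m, 0.0)) for m in net.modules]
    )
    free_idx = np.array([net.modules.index(m) for m in free])

    # Precompute the linear map from weights to predicted responses:
    # v(c) = -r^-1 diag(P) c, so v = M c with M = -r^-1 diag(P).
    M = -np.linalg.solve(net.r, np.diag(net.P))
    if objective == "relative":
        denom = np.where(np.abs(obs) < 1e-12, np.nan, obs)

        def cost_many(W: np.ndarray) -> np.ndarray:  # W: (m, n_free)
            C = np.tile(base, (W.shape[0], 1))
            C[:, free_idx] = W
            V = C @ M.T
            err = (V - obs) / denom
            return np.nansum(err**2, axis=1)

    else:

        def cost_many(W: np.ndarray) -> np.ndarray:
            C = np.tile(base, (W.shape[0], 1))
            C[:, free_idx] = W
            V = C @ M.T
            return ((V - obs) ** 2).sum(axis=1)

    lo, hi, step = grid
    axis = np.arange(lo, hi + step / 2, step)
    mesh = np.stack(
        [g.ravel() for g in np.meshgrid(*([axis] * len(free)), indexing="ij")], axis=1
    )
    grid_costs = cost_many(mesh)
    trace = [(tuple(w), float(obj)) for w, obj in zip(mesh, grid_costs)]
    best_idx = int(np.argmin(grid_costs))
    x0 = mesh[best_idx]

    res = optimize.minimize(
        lambda w: float(cost_many(w[None, :])[0]),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    candidates = [(tuple(x0), float(grid_costs[best_idx])), (tuple(res.x), float(res.fun))]
    trace.append((tuple(res.x), float(res.fun)))
    best_w, best_obj = min(candidates, key=lambda t: t[1])
    return WeightFit(
        weights={m: float(w) for m, w in zip(free, best_w)},
        objective_value=best_obj,
        trace=tuple(trace),
    )


def naive_predictors(
    obs_single: Sequence[float],
    basal: float,
    *,
    space: Literal["abundance", "fold_change"] = "abundance",
) -> dict[str, float]:
    """Baseline predictions of the combined-perturbation abundance from the
    single-perturbation observations: their mean, geometric mean and
    maximum.

    By default the aggregates act on observed abundances directly; in
    "fold_change" space the observations are first divided by *basal*,
    aggregated, and scaled back.
    """
    obs = np.asarray(list(obs_single), dtype=float)
    if obs.size == 0:
        raise DataError("need at least one single-perturbation observation")
    if np.any(obs <= 0):
        raise DataError("observed abundances must be positive")
    if not basal > 0:
        raise DataError("basal abundance must be positive")
    x = obs / basal if space == "fold_change" else obs
    out = {"mean": float(np.mean(x)), "gMean": float(gmean(x)), "max": float(np.max(x))}
    if space == "fold_change":
        out = {k: v * basal for k, v in out.items()}
    return out


@dataclass(frozen=True)
class BenchmarkResult:
    """Relative-error distributions per method plus pairwise signed-rank tests."""

    errors: pd.DataFrame  # genes x methods, relative errors
    skipped_genes: tuple = ()

    @property
    def median_errors(self) -> pd.Series:
        return self.errors.median(axis=0)

    def wilcoxon(self, method_a: str, method_b: str) -> float:
        """Two-sided paired signed-rank p-value between two methods'
        per-gene relative errors.  Identical methods give p = 1."""
        diff = self.errors[method_a] - self.errors[method_b]
        if np.allclose(diff, 0):
            return 1.0
        res = stats.wilcoxon(
            self.errors[method_a], self.errors[method_b], alternative="two-sided"
        )
        return float(res.pvalue)


def benchmark_predictions(
    predicted: pd.DataFrame,
    observed: pd.Series | Mapping[str, float],
) -> BenchmarkResult:
    """Per-gene relative prediction error |pred - obs| / obs for each method.

    *predicted*: genes x methods abundance table; *observed*: per-gene
    observed abundances.  Genes with zero observed abundance are skipped
    with a warning.
    """
    observed = pd.Series(observed)
    genes = [g for g in predicted.index if g in observed.index]
    if len(genes) < 2:
        raise DataError("benchmark needs at least two genes with observations")
    skipped = tuple(g for g in genes if observed[g] == 0)
    for g in skipped:
        logger.warning("gene %s skipped: observed abundance is zero", g)
    kept = [g for g in genes if observed[g] != 0]
    errors = predicted.loc[kept].sub(observed[kept], axis=0).abs().div(
        observed[kept].abs(), axis=0
    )
    return BenchmarkResult(errors=errors, skipped_genes=skipped)
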