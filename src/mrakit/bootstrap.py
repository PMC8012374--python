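"""Parametric bootstrap confidence intervals for MRA parameters.

With only a handful of replicates, resampling the data directly is
hopeless; instead, noise is placed on the global response coefficients.
Each bootstrap draw is a full response matrix whose entries are sampled
independently from Normal(mean_R[j,k], sd_R[j,k]) — the per-cell standard
deviations typically come from the SPC range estimator, since in practice
different cells of R can show very different variances.  Every draw is run
through the exact MRA inversion; confidence intervals are plain empirical
percentiles (2.5th/97.5th at the default 95% level) of each parameter over
the draws that yielded an invertible system.

Draws whose response matrix is singular (or whose propagated relative
change leaves the representable (-2, 2) range, for abundance predictions)
are discarded and counted; a low valid fraction is itself a diagnostic
that the network is too noisy for percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CombinedPerturbation,
    ExperimentDesign,
    GlobalResponseMatrix,
    infer_network,
    inverse_symmetric_relative_change,
    predict_abundance,
)
from .exceptions import DataError, InstabilityError
from .spc import hartley_d2

__all__ = [
    "BootstrapConfig",
    "CiTable",
    "replicate_sd_matrix",
    "bootstrap_network",
    "bootstrap_prediction",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings.

    ``n_samples`` defaults to one million draws; scaled-down profiles
    (10,000) are used in tests and the CLI quick path.  ``sd_source``
    documents where the per-cell sd matrix came from (replicate-level SPC,
    gene-population SPC, or an explicitly supplied matrix); it does not
    change the computation, which always consumes the sd matrix it is
    handed.
    """

    n_samples: int = 1_000_000
    ci_level: float = 0.95
    seed: int = 0
    sd_source: str = "replicate_spc"
    min_valid_fraction: float = 0.5
    cond_threshold: float = 1e8
    chunk_size: int = 100_000

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise DataError(f"n_samples must be >= 100, got {self.n_samples}")
        if not 0.0 < self.ci_level < 1.0:
            raise DataError(f"ci_level must lie in (0, 1), got {self.ci_level}")


@dataclass(frozen=True)
class CiTable:
    """Per-parameter point estimates, CI bounds and significance flags.

    ``table`` columns: parameter, kind (r / P / abundance), estimate,
    lower, upper, significant (None for abundances), n_valid.  A parameter
    is significant iff its CI excludes zero.
    """

    table: pd.DataFrame
    level: float
    n_valid: int
    n_samples: int

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.n_samples

    def row(self, parameter: str) -> pd.Series:
        hit = self.table[self.table["parameter"] == parameter]
        if hit.empty:
            raise KeyError(parameter)
        return hit.iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def replicate_sd_matrix(
    per_replicate_Rs: list[GlobalResponseMatrix],
    design: ExperimentDesign,
) -> np.ndarray:
    """Cell-wise SPC sd over the per-replicate response matrices.

    Matrices must be ordered biological-major, as produced by
    ``build_global_response(..., mode="per_replicate")``: the k_t * n_r
    values of each cell are grouped into k_t subgroups of n_r technical
    replicates.  When n_r == 1 (e.g. duplicated RNA-seq runs with no
    technical replication) the biological replicates themselves form a
    single subgroup of size k_t.
    """
    k_t, n_r = design.replicates
    if len(per_replicate_Rs) != k_t * n_r:
        raise DataError(
            f"expected {k_t * n_r} replicate matrices for design ({k_t} x {n_r}), "
            f"got {len(per_replicate_Rs)}"
        )
    stack = np.stack([m.values for m in per_replicate_Rs])  # (k_t*n_r, n, n)
    if n_r == 1:
        if k_t < 2:
            raise DataError("a single replicate has no range; need k_t >= 2 when n_r == 1")
        grouped = stack.reshape(1, k_t, *stack.shape[1:])
        d2 = hartley_d2(k_t)
    else:
        grouped = stack.reshape(k_t, n_r, *stack.shape[1:])
        d2 = hartley_d2(n_r)
    ranges = grouped.max(axis=1) - grouped.min(axis=1)  # (groups, n, n)
    return ranges.mean(axis=0) / d2


def _sample_networks(
    mean: np.ndarray,
    sd: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    cond_threshold: float,
):
    """Draw response matrices and invert them; returns (r, P, valid mask).

    Invalid draws (near-singular R, estimated by the 1-norm condition
    number) carry NaNs in r and P.
    """
    n = mean.shape[0]
    draws = rng.normal(loc=mean, scale=sd, size=(n_draws, n, n))
    # 1-norm condition estimate is cheap and vectorises; exact SVD is not
    # needed to reject degenerate draws.
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        det = np.linalg.det(draws)
        valid = np.abs(det) > np.finfo(float).tiny * 1e4
        Rinv = np.full_like(draws, np.nan)
        if valid.any():
            Rinv[valid] = np.linalg.inv(draws[valid])
        norm_R = np.abs(draws).sum(axis=1).max(axis=1)
        norm_Rinv = np.abs(Rinv).sum(axis=1).max(axis=1)
        cond = norm_R * norm_Rinv
        valid &= np.isfinite(cond) & (cond <= cond_threshold)
        diag = np.diagonal(Rinv, axis1=1, axis2=2)  # (draws, n)
        valid &= np.all(diag != 0, axis=1) & np.all(np.isfinite(Rinv), axis=(1, 2))
        P = 1.0 / diag
        r = -Rinv / diag[:, :, None]
    idx = np.arange(n)
    r[:, idx, idx] = -1.0
    r[~valid] = np.nan
    P[~valid] = np.nan
    return r, P, valid


def _percentiles(samples: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    alpha = 100.0 * (1.0 - level) / 2.0
    lower = np.percentile(samples, alpha, axis=0)
    upper = np.percentile(samples, 100.0 - alpha, axis=0)
    return lower, upper


def _check_valid_fraction(n_valid: int, n_samples: int, config: BootstrapConfig) -> None:
    frac = n_valid / n_samples
    if frac < config.min_valid_fraction:
        raise InstabilityError(
            f"only {frac:.1%} of bootstrap draws were usable "
            f"(< {config.min_valid_fraction:.0%}): the network is too noisy "
            "for percentile confidence intervals"
        )


def bootstrap_network(
    mean_R: GlobalResponseMatrix,
    sd_R: np.ndarray,
    config: BootstrapConfig,
) -> CiTable:
    """Percentile CIs for every off-diagonal connection coefficient and
    every perturbation magnitude.

    Point estimates come from the deterministic inference on *mean_R*;
    intervals come from ``config.n_samples`` Normal draws around it with
    per-cell sd *sd_R*.
    """
    mean = mean_R.values
    sd = np.asarray(sd_R, dtype=float)
    if sd.shape != mean.shape:
        raise DataError(f"sd matrix shape {sd.shape} != mean shape {mean.shape}")
    if np.any(sd < 0) or not np.all(np.isfinite(sd)):
        raise DataError("sd matrix entries must be finite and >= 0")
    point = infer_network(mean_R, cond_threshold=config.cond_threshold)
    modules = mean_R.modules
    n = len(modules)

    rng = np.random.default_rng(config.seed)
    r_chunks, p_chunks = [], []
    n_valid = 0
    remaining = config.n_samples
    while remaining > 0:
        size = min(config.chunk_size, remaining)
        r, P, valid = _sample_networks(mean, sd, size, rng, config.cond_threshold)
        n_valid += int(valid.sum())
        r_chunks.append(r[valid])
        p_chunks.append(P[valid])
        remaining -= size
    _check_valid_fraction(n_valid, config.n_samples, config)
    r_samples = np.concatenate(r_chunks)
    p_samples = np.concatenate(p_chunks)

    rows = []
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    r_lower, r_upper = _percentiles(
        r_samples.reshape(n_valid, n * n)[:, [i * n + j for i, j in off]], config.ci_level
    )
    for (i, j), lo, up in zip(off, r_lower, r_upper):
        est = point.r[i, j]
        rows.append(
            {
                "parameter": f"r[{modules[i]},{modules[j]}]",
                "kind": "r",
                "estimate": est,
                "lower": lo,
                "upper": up,
                "significant": bool(lo > 0 or up < 0),
                "n_valid": n_valid,
            }
        )
    p_lower, p_upper = _percentiles(p_samples, config.ci_level)
    for i, (lo, up) in enumerate(zip(p_lower, p_upper)):
        rows.append(
            {
                "parameter": f"P[{modules[i]}]",
                "kind": "P",
                "estimate": point.P[i],
                "lower": lo,
                "upper": up,
                "significant": bool(lo > 0 or up < 0),
                "n_valid": n_valid,
            }
        )
    return CiTable(
        table=pd.DataFrame(rows),
        level=config.ci_level,
        n_valid=n_valid,
        n_samples=config.n_samples,
    )


def bootstrap_prediction(
    mean_R: GlobalResponseMatrix,
    sd_R: np.ndarray,
    c: CombinedPerturbation,
    basal: np.ndarray,
    config: BootstrapConfig,
) -> CiTable:
    """Percentile CIs for predicted module abundances under combined
    perturbation *c*, propagating each bootstrap draw through prediction.

    Draws whose predicted relative change reaches |v| >= 2 are invalid
    (the symmetric relative difference cannot represent them), with the
    same accounting as singular draws.
    """
    mean = mean_R.values
    sd = np.asarray(sd_R, dtype=float)
    basal = np.asarray(basal, dtype=float)
    modules = mean_R.modules
    n = len(modules)
    if basal.shape != (n,) or np.any(basal <= 0):
        raise DataError("basal must be a strictly positive vector of length n")
    point_net = infer_network(mean_R, cond_threshold=config.cond_threshold)
    point_abundance = predict_abundance(point_net, c, basal)

    rng = np.random.default_rng(config.seed)
    chunks = []
    n_valid = 0
    remaining = config.n_samples
    while remaining > 0:
        size = min(config.chunk_size, remaining)
        r, P, valid = _sample_networks(mean, sd, size, rng, config.cond_threshold)
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            rhs = -(P * c.weights[None, :])
            v = np.full_like(P, np.nan)
            if valid.any():
                v[valid] = np.linalg.solve(r[valid], rhs[valid][..., None])[..., 0]
            valid &= np.all(np.isfinite(v), axis=1) & np.all(np.abs(v) < 2, axis=1)
        n_valid += int(valid.sum())
        chunks.append(inverse_symmetric_relative_change(v[valid], basal[None, :]))
        remaining -= size
    _check_valid_fraction(n_valid, config.n_samples, config)
    samples = np.concatenate(chunks)
    lower, upper = _percentiles(samples, config.ci_level)

    rows = [
        {
            "parameter": f"x[{modules[i]}]",
            "kind": "abundance",
            "estimate": point_abundance[i],
            "lower": lower[i],
            "upper": upper[i],
            "significant": None,
            "n_valid": n_valid,
        }
        for i in range(n)
    ]
    return CiTable(
        table=pd.DataFrame(rows),
        level=config.ci_level,
        n_valid=n_valid,
        n_samples=config.n_samples,
    )
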