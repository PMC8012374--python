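"""Ground-truth generator for MRA benchmarks.

The generative model is the identifiable core of MRA itself: a known
connection-coefficient matrix ``r_true`` (diagonal -1) and perturbation
magnitudes ``P_true`` imply a global response matrix
``R_true = -r_true^-1 diag(P_true)``; noiseless perturbed abundances follow
by inverting the symmetric relative difference around known basal levels.
No ODE system is simulated — the linear local-response model *is* the
truth, matching exactly what MRA can identify.

Noise emulates a qPCR-style replicate hierarchy (default 3 biological x 2
technical): a biological component shared by the technical replicates of a
(reporter, condition, biological-replicate) cell and an independent
technical component.  Two noise spaces are supported: multiplicative
log-normal on abundances (realistic measurement error) and additive
Gaussian directly on the global response coefficients (the model the
bootstrap assumes).  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, CiTable, bootstrap_network
from .core import (
    AbundanceSet,
    CombinedPerturbation,
    ExperimentDesign,
    GlobalResponseMatrix,
    LocalResponseNetwork,
    inverse_symmetric_relative_change,
)
from .exceptions import DataError

__all__ = [
    "GroundTruth",
    "random_ground_truth",
    "design_for",
    "simulate_dataset",
    "GenePanel",
    "simulate_gene_panel",
    "recovery_report",
    "coverage_simulation",
]

NoiseSpace = Literal["log_abundance", "response"]


@dataclass(frozen=True)
class GroundTruth:
    """A synthetic network with basal abundances and a noise model."""

    r_true: np.ndarray
    P_true: np.ndarray
    basal: np.ndarray
    sigma_bio: float = 0.0
    sigma_tech: float = 0.0
    space: NoiseSpace = "log_abundance"
    seed: int = 0
    modules: tuple[str, ...] = ()
    gene_rows: tuple = ()  # (identifier, coefficient vector, basal abundance)
    cond_bound: float = 1e6

    def __post_init__(self) -> None:
        r = np.asarray(self.r_true, dtype=float)
        P = np.asarray(self.P_true, dtype=float)
        basal = np.asarray(self.basal, dtype=float)
        n = r.shape[0]
        object.__setattr__(self, "r_true", r)
        object.__setattr__(self, "P_true", P)
        object.__setattr__(self, "basal", basal)
        if not self.modules:
            object.__setattr__(self, "modules", tuple(f"M{i + 1}" for i in range(n)))
        else:
            object.__setattr__(self, "modules", tuple(self.modules))
        if r.shape != (n, n) or P.shape != (n,) or basal.shape != (n,):
            raise DataError("inconsistent truth dimensions")
        if not np.all(np.diag(r) == -1.0):
            raise DataError("r_true diagonal must be exactly -1")
        if np.any(P == 0):
            raise DataError("P_true entries must be nonzero")
        if np.any(basal <= 0):
            raise DataError("basal abundances must be positive")
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise DataError("noise sds must be >= 0")
        R = self.R_true
        cond = np.linalg.cond(R)
        if not np.isfinite(cond) or cond > self.cond_bound:
            raise DataError(
                f"implied response matrix is ill-conditioned (cond {cond:.3g})"
            )
        if np.any(np.abs(R) >= 2):
            raise DataError(
                "implied global responses leave (-2, 2): this truth cannot be "
                "represented by the symmetric relative difference"
            )

    @property
    def n(self) -> int:
        return self.r_true.shape[0]

    @property
    def R_true(self) -> np.ndarray:
        return -np.linalg.solve(self.r_true, np.diag(self.P_true))

    def network(self) -> LocalResponseNetwork:
        return LocalResponseNetwork(self.r_true.copy(), self.P_true.copy(), self.modules)


def random_ground_truth(
    n: int,
    seed: int,
    *,
    edge_scale: float = 0.6,
    p_range: tuple[float, float] = (0.3, 1.2),
    p_sign: float = -1.0,
    cond_bound: float = 1e3,
    sigma_bio: float = 0.0,
    sigma_tech: float = 0.0,
    space: NoiseSpace = "log_abundance",
    max_tries: int = 1000,
) -> GroundTruth:
    """Draw a well-conditioned random truth by rejection sampling.

    Off-diagonal coefficients are uniform on [-edge_scale, edge_scale];
    perturbation magnitudes have magnitude in *p_range* with sign *p_sign*
    (negative by default, emulating knockdown/ligand-removal
    perturbations).  Truths whose implied R is ill-conditioned (above
    *cond_bound*) or leaves (-2, 2) are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        r = rng.uniform(-edge_scale, edge_scale, size=(n, n))
        np.fill_diagonal(r, -1.0)
        P = p_sign * rng.uniform(*p_range, size=n)
        basal = rng.uniform(5.0, 50.0, size=n)
        try:
            return GroundTruth(
                r_true=r,
                P_true=P,
                basal=basal,
                sigma_bio=sigma_bio,
                sigma_tech=sigma_tech,
                space=space,
                seed=seed,
                cond_bound=cond_bound,
            )
        except DataError:
            continue
    raise DataError(
        f"could not draw an admissible {n}-module truth in {max_tries} tries"
    )


def design_for(
    truth: GroundTruth, k_t: int = 3, n_r: int = 2
) -> ExperimentDesign:
    """A matching elementary-perturbation design: one condition per module
    plus a basal condition, with the given replicate structure."""
    return ExperimentDesign(
        modules=truth.modules,
        basal_condition="basal",
        perturbation_map={f"pert_{m}": m for m in truth.modules},
        replicates=(k_t, n_r),
    )


def simulate_dataset(
    truth: GroundTruth,
    design: ExperimentDesign,
    rng: np.random.Generator | None = None,
) -> AbundanceSet:
    """Simulate a replicate-structured abundance dataset at steady state.

    Noiseless abundances invert the symmetric relative difference of
    ``R_true`` around the basal levels.  In ``log_abundance`` space every
    measurement (including basal) gets a multiplicative log-normal factor
    with a biological component shared within each (condition, biological
    replicate) and an independent technical component.  In ``response``
    space Gaussian noise is added to the global response coefficients
    themselves (biological + technical components, same sharing) and basal
    rows stay exact, so rebuilt response matrices carry exactly that noise.
    """
    if design.n != truth.n or design.modules != truth.modules:
        raise DataError("design does not match the ground truth's modules")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    k_t, n_r = design.replicates
    R = truth.R_true
    records: list[tuple[str, str, int, int, float]] = []
    conditions = [design.basal_condition] + [
        design.condition_for(m) for m in truth.modules
    ]
    # noiseless abundance of reporter j under condition index q (0 = basal)
    noiseless = np.column_stack(
        [truth.basal] + [inverse_symmetric_relative_change(R[:, k], truth.basal) for k in range(truth.n)]
    )
    for q, cond in enumerate(conditions):
        for bio in range(1, k_t + 1):
            if truth.space == "log_abundance":
                eps_bio = rng.normal(0.0, truth.sigma_bio, size=truth.n)
            else:
                eta_bio = rng.normal(0.0, truth.sigma_bio, size=truth.n)
            for tech in range(1, n_r + 1):
                if truth.space == "log_abundance":
                    eps = eps_bio + rng.normal(0.0, truth.sigma_tech, size=truth.n)
                    values = noiseless[:, q] * np.exp(eps)
                else:
                    if q == 0:
                        values = truth.basal
                    else:
                        eta = eta_bio + rng.normal(0.0, truth.sigma_tech, size=truth.n)
                        noisy_R = R[:, q - 1] + eta
                        if np.any(np.abs(noisy_R) >= 2):
                            raise DataError(
                                "response-space noise drove a coefficient outside "
                                "(-2, 2); lower sigma"
                            )
                        values = inverse_symmetric_relative_change(noisy_R, truth.basal)
                for j, m in enumerate(truth.modules):
                    records.append(
                        (design.reporters[m], cond, bio, tech, float(values[j]))
                    )
    return AbundanceSet.from_records(records)


@dataclass(frozen=True)
class GenePanel:
    """Synthetic non-perturbed genes tied to a ground truth.

    ``rows`` holds each gene's true incoming-coefficient vector;
    ``responses`` its (possibly noisy) relative changes under the
    elementary perturbations, ``basal`` its basal abundance.
    """

    genes: tuple[str, ...]
    rows: pd.DataFrame  # genes x modules, true coefficients
    responses: pd.DataFrame  # genes x modules, relative change under q_k
    basal: pd.Series
    truth: GroundTruth

    def true_abundance(self, gene: str, c: CombinedPerturbation) -> float:
        """Ground-truth abundance of *gene* under combined perturbation *c*."""
        v = -np.linalg.solve(self.truth.r_true, self.truth.P_true * c.weights)
        u = float(self.rows.loc[gene].to_numpy() @ v)
        if abs(u) >= 2:
            raise DataError(f"{gene}: true combined response saturates")
        return float(self.basal[gene] * (2.0 + u) / (2.0 - u))

    def single_perturbation_abundances(self, gene: str) -> dict[str, float]:
        """Observed abundance of *gene* under each elementary perturbation."""
        resp = self.responses.loc[gene]
        return {
            m: float(inverse_symmetric_relative_change(resp[m], self.basal[gene]))
            for m in self.rows.columns
        }


def simulate_gene_panel(
    truth: GroundTruth,
    design: ExperimentDesign,
    n_extra: int = 0,
    *,
    rng: np.random.Generator | None = None,
    coeff_scale: float = 0.8,
    sigma: float | None = None,
    mixed_sign: bool = False,
    max_tries: int = 200,
) -> GenePanel:
    """Generate appended genes for udMRA and screening fixtures.

    Uses ``truth.gene_rows`` plus *n_extra* random coefficient rows.  A
    gene's noiseless response to q_k is its row dotted with the core
    modules' responses (column k of R_true); Gaussian noise of sd *sigma*
    (default ``truth.sigma_tech``) is added in response space.  With
    *mixed_sign* each random row is forced to carry coefficients of both
    signs, producing the "complex dependency" regime where naive
    single-perturbation aggregates fail.  Rows implying |response| >= 2
    are rejected (explicit rows fatally, random rows are redrawn).
    """
    if design.modules != truth.modules:
        raise DataError("design does not match the ground truth's modules")
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 1)
    sigma = truth.sigma_tech if sigma is None else sigma
    R = truth.R_true
    rows: list[tuple[str, np.ndarray, float]] = []
    for gene, coeffs, basal in truth.gene_rows:
        coeffs = np.asarray(coeffs, dtype=float)
        resp = coeffs @ R
        if np.any(np.abs(resp) >= 2):
            raise DataError(f"gene row {gene!r} implies |response| >= 2")
        rows.append((gene, coeffs, float(basal)))
    width = len(str(max(n_extra, 1)))
    for i in range(n_extra):
        for _ in range(max_tries):
            coeffs = rng.uniform(-coeff_scale, coeff_scale, size=truth.n)
            if mixed_sign:
                signs = np.sign(coeffs)
                if not (np.any(signs > 0) and np.any(signs < 0)):
                    continue
                # guarantee two substantial opposite-sign dependencies
                order = np.argsort(-np.abs(coeffs))
                if abs(coeffs[order[1]]) < 0.3 * coeff_scale:
                    continue
                if np.sign(coeffs[order[0]]) == np.sign(coeffs[order[1]]):
                    coeffs[order[1]] *= -1.0
            resp = coeffs @ R
            if np.all(np.abs(resp) < 1.8):
                rows.append((f"G{i + 1:0{width}d}", coeffs, float(rng.uniform(5, 50))))
                break
        else:
            raise DataError("could not draw an admissible gene row")
    if not rows:
        raise DataError("no gene rows: supply truth.gene_rows or n_extra > 0")
    genes = tuple(g for g, _, _ in rows)
    coeff_df = pd.DataFrame(
        [c for _, c, _ in rows], index=list(genes), columns=list(truth.modules)
    )
    noiseless = coeff_df.to_numpy() @ R
    noisy = noiseless + rng.normal(0.0, sigma, size=noiseless.shape) if sigma > 0 else noiseless
    if np.any(np.abs(noisy) >= 2):
        raise DataError("panel noise drove a response outside (-2, 2); lower sigma")
    responses = pd.DataFrame(noisy, index=list(genes), columns=list(truth.modules))
    basal = pd.Series([b for _, _, b in rows], index=list(genes), name="basal")
    return GenePanel(
        genes=genes, rows=coeff_df, responses=responses, basal=basal, truth=truth
    )


def mixed_sign_gene_benchmark(
    seed: int = 0,
    n_genes: int = 60,
    *,
    n: int = 3,
    perturbed: tuple[int, int] = (1, 2),
) -> tuple[GroundTruth, GenePanel, CombinedPerturbation]:
    """Noiseless benchmark in the "complex dependency" regime.

    Builds a random truth, a panel of *n_genes* genes whose coefficient
    rows carry both signs (so single-perturbation aggregates mislead), and
    the double elementary perturbation of the two *perturbed* modules.
    Genes whose true combined response would saturate the (-2, 2) range
    are filtered out before selecting the first *n_genes*.
    """
    truth = random_ground_truth(n, seed=seed)
    design = design_for(truth)
    panel = simulate_gene_panel(
        truth, design, n_extra=4 * n_genes, sigma=0.0, mixed_sign=True
    )
    weights = np.zeros(n)
    weights[list(perturbed)] = 1.0
    c = CombinedPerturbation(weights)
    v = -np.linalg.solve(truth.r_true, truth.P_true * c.weights)
    keep = [
        g
        for g in panel.genes
        if abs(float(panel.rows.loc[g].to_numpy() @ v)) < 1.8
    ][:n_genes]
    if len(keep) < n_genes:
        raise DataError(f"only {len(keep)} admissible benchmark genes drawn")
    trimmed = GenePanel(
        genes=tuple(keep),
        rows=panel.rows.loc[keep],
        responses=panel.responses.loc[keep],
        basal=panel.basal[keep],
        truth=truth,
    )
    return truth, trimmed, c


def recovery_report(
    truth: GroundTruth,
    inferred: LocalResponseNetwork,
    ci: CiTable | None = None,
) -> dict:
    """Error summary of an inferred network against the ground truth.

    Returns max/mean absolute error separately for the off-diagonal
    connection coefficients and the perturbation magnitudes; with a CI
    table, adds per-parameter truth-in-CI indicators and their mean (the
    empirical coverage contribution of this dataset).
    """
    if inferred.n != truth.n:
        raise DataError("dimension mismatch between truth and inferred network")
    mask = ~np.eye(truth.n, dtype=bool)
    dr = np.abs(inferred.r - truth.r_true)[mask]
    dP = np.abs(inferred.P - truth.P_true)
    report = {
        "max_abs_error_r": float(dr.max()),
        "mean_abs_error_r": float(dr.mean()),
        "max_abs_error_P": float(dP.max()),
        "mean_abs_error_P": float(dP.mean()),
    }
    if ci is not None:
        covered = {}
        for i, mi in enumerate(truth.modules):
            for j, mj in enumerate(truth.modules):
                if i == j:
                    continue
                row = ci.row(f"r[{mi},{mj}]")
                covered[f"r[{mi},{mj}]"] = bool(
                    row["lower"] <= truth.r_true[i, j] <= row["upper"]
                )
        report["truth_in_ci"] = covered
        report["coverage_fraction"] = float(np.mean(list(covered.values())))
    return report


def coverage_simulation(
    n_datasets: int = 500,
    *,
    n: int = 3,
    sigma: float = 0.05,
    n_draws: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.Series:
    """Empirical CI coverage of the true connection coefficients.

    One fixed random truth; each dataset observes ``R_true`` with
    independent additive Gaussian response-space noise of sd *sigma* per
    cell, and the parametric bootstrap (at the generating sd, *n_draws*
    draws) produces a CI per off-diagonal coefficient.  Returns the
    fraction of datasets whose CI covered the truth, per parameter.
    Nominal calibration puts these near *level*.
    """
    truth = random_ground_truth(n, seed=seed)
    R_true = truth.R_true
    sd = np.full((n, n), sigma)
    rng = np.random.default_rng(seed + 1)
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for d in range(n_datasets):
        observed = R_true + rng.normal(0.0, sigma, size=(n, n))
        if np.any(np.abs(observed) >= 2):
            continue
        mean_R = GlobalResponseMatrix(observed, truth.modules)
        config = BootstrapConfig(
            n_samples=n_draws,
            ci_level=level,
            seed=int(rng.integers(0, 2**31 - 1)),
            sd_source="explicit",
        )
        ci = bootstrap_network(mean_R, sd, config)
        for i, mi in enumerate(truth.modules):
            for j, mj in enumerate(truth.modules):
                if i == j:
                    continue
                key = f"r[{mi},{mj}]"
                row = ci.row(key)
                totals[key] = totals.get(key, 0) + 1
                hits[key] = hits.get(key, 0) + int(
                    row["lower"] <= truth.r_true[i, j] <= row["upper"]
                )
    return pd.Series({k: hits[k] / totals[k] for k in totals}, name="coverage")
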