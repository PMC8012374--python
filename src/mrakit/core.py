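"""Core data model and linear algebra of modular response analysis (MRA).

MRA infers the direct, signed interactions between the modules of a
biological network from systematic perturbation experiments performed at
steady state.  Each module's activity is summarised by one measured
reporter.  Applying an elementary perturbation ``q_k`` (one that touches
only module ``k``) and recording the relative change of every reporter
yields the *global* response matrix ``R``; the *local* response
(connection-coefficient) matrix ``r`` — the network — is then obtained by
matrix inversion:

    r = -[diag(R^-1)]^-1 R^-1,      P_ii = 1 / (R^-1)_ii

with the convention ``r_ii = -1``.  ``P`` collects the magnitudes of the
elementary perturbations on their own modules.  The same linear model runs
forward: a combined perturbation with weight vector ``c`` produces module
relative changes ``-r^-1 diag(P) c``.

Relative changes are measured with the symmetric relative difference
``2 (x' - x) / (x' + x)``, which is bounded in (-2, 2) for positive
abundances and avoids division hazards near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, DesignError, InferenceError, SaturationError

__all__ = [
    "ExperimentDesign",
    "AbundanceSet",
    "GlobalResponseMatrix",
    "LocalResponseNetwork",
    "CombinedPerturbation",
    "symmetric_relative_change",
    "inverse_symmetric_relative_change",
    "build_global_response",
    "infer_network",
    "predict_response",
    "predict_abundance",
]

#: Default bound on cond(R) above which inference refuses to proceed.
DEFAULT_COND_THRESHOLD = 1e8


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Modules, reporters, and the condition-to-module perturbation map.

    Parameters
    ----------
    modules
        Ordered module identifiers; this order is preserved in every matrix
        and output (no re-sorting).
    reporters
        Map module -> reporter identifier (the measured quantity standing
        for the module's activity).  Defaults to the identity map.
    basal_condition
        The reference condition all perturbed conditions are compared to.
    perturbation_map
        Map condition identifier -> the module it perturbs.  Every module
        must be the target of exactly one condition (elementary
        perturbations).
    replicates
        ``(k_t, n_r)``: biological replicates and technical replicates per
        biological replicate.
    """

    modules: tuple[str, ...]
    basal_condition: str
    perturbation_map: Mapping[str, str]
    reporters: Mapping[str, str] = field(default_factory=dict)
    replicates: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        modules = tuple(self.modules)
        object.__setattr__(self, "modules", modules)
        if len(set(modules)) != len(modules):
            raise DesignError(f"duplicate module identifiers in {modules}")
        reporters = dict(self.reporters) or {m: m for m in modules}
        missing = [m for m in modules if m not in reporters]
        if missing:
            raise DesignError(f"modules without a reporter: {missing}")
        object.__setattr__(self, "reporters", reporters)
        pmap = dict(self.perturbation_map)
        object.__setattr__(self, "perturbation_map", pmap)
        if self.basal_condition in pmap:
            raise DesignError(
                f"basal condition {self.basal_condition!r} must not perturb a module"
            )
        targets = list(pmap.values())
        for m in modules:
            hits = targets.count(m)
            if hits != 1:
                raise DesignError(
                    f"module {m!r} must be targeted by exactly one condition, found {hits}"
                )
        unknown = [t for t in targets if t not in modules]
        if unknown:
            raise DesignError(f"perturbation targets are not modules: {unknown}")
        k_t, n_r = self.replicates
        if k_t < 1 or n_r < 1:
            raise DesignError(f"replicate counts must be >= 1, got {self.replicates}")

    @property
    def n(self) -> int:
        return len(self.modules)

    @property
    def k_t(self) -> int:
        return self.replicates[0]

    @property
    def n_r(self) -> int:
        return self.replicates[1]

    def condition_for(self, module: str) -> str:
        """The condition applying the elementary perturbation of *module*."""
        for cond, target in self.perturbation_map.items():
            if target == module:
                return cond
        raise DesignError(f"no perturbation condition for module {module!r}")

    @property
    def conditions(self) -> tuple[str, ...]:
        """Basal condition followed by the perturbation conditions in module order."""
        return (self.basal_condition,) + tuple(
            self.condition_for(m) for m in self.modules
        )


class AbundanceSet:
    """Replicate-structured positive abundance measurements.

    Values are keyed by ``(reporter, condition, bio_rep, tech_rep)``.  Units
    are arbitrary: MRA works with relative changes, so absolute quantitation
    is never needed.
    """

    COLUMNS = ("reporter", "condition", "bio_rep", "tech_rep", "value")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise DataError(f"abundance table lacks columns {missing}")
        table = table.loc[:, list(self.COLUMNS)].copy()
        table["bio_rep"] = table["bio_rep"].astype(int)
        table["tech_rep"] = table["tech_rep"].astype(int)
        table["value"] = table["value"].astype(float)
        bad = table[~np.isfinite(table["value"]) | (table["value"] <= 0)]
        if not bad.empty:
            row = bad.iloc[0]
            raise DataError(
                "abundances must be strictly positive and finite; offending cell "
                f"reporter={row['reporter']!r} condition={row['condition']!r} "
                f"bio={row['bio_rep']} tech={row['tech_rep']} value={row['value']!r}"
            )
        keys = list(
            zip(table["reporter"], table["condition"], table["bio_rep"], table["tech_rep"])
        )
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise DataError(f"duplicate measurement key {dup}")
        self._table = table.reset_index(drop=True)
        self._index = dict(zip(keys, table["value"]))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, int, float]]
    ) -> "AbundanceSet":
        return cls(pd.DataFrame(list(records), columns=list(cls.COLUMNS)))

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    def __len__(self) -> int:
        return len(self._table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceSet):
            return NotImplemented
        return self._index == other._index

    def value(self, reporter: str, condition: str, bio: int, tech: int) -> float:
        try:
            return self._index[(reporter, condition, bio, tech)]
        except KeyError:
            raise DataError(
                f"no measurement for reporter={reporter!r} condition={condition!r} "
                f"bio={bio} tech={tech}"
            ) from None

    def has(self, reporter: str, condition: str, bio: int, tech: int) -> bool:
        return (reporter, condition, bio, tech) in self._index

    def replicate_pairs(self) -> set[tuple[int, int]]:
        """All (bio, tech) pairs present anywhere in the table."""
        return set(zip(self._table["bio_rep"], self._table["tech_rep"]))


@dataclass(frozen=True)
class GlobalResponseMatrix:
    """Systems-level relative responses: ``values[j, k]`` is the symmetric
    relative change of module ``j``'s reporter under elementary perturbation
    of module ``k``."""

    values: np.ndarray
    modules: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "modules", tuple(self.modules))
        n = len(self.modules)
        if values.shape != (n, n):
            raise DataError(
                f"global response matrix must be {n}x{n} for {n} modules, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise DataError("global response matrix contains non-finite entries")
        if np.any(np.abs(values) >= 2):
            raise DataError(
                "global response entries must lie in (-2, 2); the symmetric "
                "relative difference of positive abundances cannot leave this range"
            )

    @property
    def n(self) -> int:
        return len(self.modules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.modules), columns=list(self.modules))


@dataclass(frozen=True)
class LocalResponseNetwork:
    """Inferred connection coefficients ``r`` (diagonal fixed at -1) and
    perturbation magnitudes ``P``."""

    r: np.ndarray
    P: np.ndarray
    modules: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "modules", tuple(self.modules))
        n = len(self.modules)
        if r.shape != (n, n) or P.shape != (n,):
            raise DataError(f"shape mismatch: r {r.shape}, P {P.shape}, {n} modules")
        if not np.all(np.diag(r) == -1.0):
            raise DataError("diagonal of r must be exactly -1")

    @property
    def n(self) -> int:
        return len(self.modules)

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.modules), columns=list(self.modules))

    def p_series(self) -> pd.Series:
        return pd.Series(self.P, index=list(self.modules), name="P")

    def reconstruct_global(self) -> np.ndarray:
        """The global response matrix implied by (r, P): ``-r^-1 diag(P)``."""
        return -np.linalg.solve(self.r, np.diag(self.P))


@dataclass(frozen=True)
class CombinedPerturbation:
    """Weights of the elementary perturbations composing a combined one.

    0 = absent, 1 = full elementary strength; fractional and negative
    weights are allowed (linearity of perturbation strength is assumed).
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1:
            raise DataError("perturbation weights must form a vector")
        if not np.all(np.isfinite(w)):
            raise DataError("perturbation weights must be finite")
        if not np.any(w != 0):
            raise DataError("a combined perturbation needs at least one nonzero weight")

    @classmethod
    def from_modules(
        cls, modules: Sequence[str], weights: Mapping[str, float]
    ) -> "CombinedPerturbation":
        unknown = set(weights) - set(modules)
        if unknown:
            raise DesignError(f"weights refer to unknown modules: {sorted(unknown)}")
        return cls(np.array([float(weights.get(m, 0.0)) for m in modules]))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def symmetric_relative_change(
    x_pert: float, x_basal: float, *, label: str = "value"
) -> float:
    """Symmetric relative difference ``2 (x_pert - x_basal) / (x_pert + x_basal)``.

    Bounded in (-2, 2) for positive inputs and antisymmetric under argument
    swap.  *label* names the reporter/condition in error messages.
    """
    if not (math.isfinite(x_pert) and math.isfinite(x_basal)):
        raise DataError(f"non-finite abundance for {label}: {x_pert!r}, {x_basal!r}")
    if x_pert <= 0 or x_basal <= 0:
        raise DataError(
            f"abundances must be strictly positive for {label}: {x_pert!r}, {x_basal!r}"
        )
    return 2.0 * (x_pert - x_basal) / (x_pert + x_basal)


def inverse_symmetric_relative_change(v: np.ndarray, basal: np.ndarray) -> np.ndarray:
    """Invert the symmetric relative difference: the abundance whose change
    relative to *basal* equals *v*, i.e. ``basal * (2 + v) / (2 - v)``.

    Valid for |v| < 2; callers are expected to have checked saturation.
    """
    v = np.asarray(v, dtype=float)
    basal = np.asarray(basal, dtype=float)
    return basal * (2.0 + v) / (2.0 - v)


def build_global_response(
    data: AbundanceSet,
    design: ExperimentDesign,
    mode: Literal["per_replicate", "pooled_mean"] = "pooled_mean",
):
    """Assemble global response matrices from abundance measurements.

    ``per_replicate`` pairs replicate ``(i, r)`` of each perturbed condition
    with the same ``(i, r)`` of the basal condition, yielding ``k_t * n_r``
    matrices ordered biological-major (bio 1 tech 1, bio 1 tech 2, ...).
    ``pooled_mean`` returns their element-wise mean as one matrix.

    Returns a list of :class:`GlobalResponseMatrix` (``per_replicate``) or a
    single one (``pooled_mean``).
    """
    if mode not in ("per_replicate", "pooled_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    k_t, n_r = design.replicates
    n = design.n
    conditions = [design.condition_for(m) for m in design.modules]
    reporters = [design.reporters[m] for m in design.modules]

    missing: list[tuple[str, str, int, int]] = []
    for rep in reporters:
        for cond in [design.basal_condition] + conditions:
            for bio in range(1, k_t + 1):
                for tech in range(1, n_r + 1):
                    if not data.has(rep, cond, bio, tech):
                        missing.append((rep, cond, bio, tech))
    if missing:
        shown = ", ".join(
            f"({r!r}, {c!r}, bio {b}, tech {t})" for r, c, b, t in missing[:10]
        )
        more = "" if len(missing) <= 10 else f" and {len(missing) - 10} more"
        raise DataError(f"missing measurement cells: {shown}{more}")

    matrices = []
    for bio in range(1, k_t + 1):
        for tech in range(1, n_r + 1):
            R = np.empty((n, n))
            for j, rep in enumerate(reporters):
                x0 = data.value(rep, design.basal_condition, bio, tech)
                for k, cond in enumerate(conditions):
                    xq = data.value(rep, cond, bio, tech)
                    R[j, k] = symmetric_relative_change(
                        xq, x0, label=f"{rep}@{cond} (bio {bio}, tech {tech})"
                    )
            matrices.append(GlobalResponseMatrix(R, design.modules))
    if mode == "per_replicate":
        return matrices
    mean = np.mean([m.values for m in matrices], axis=0)
    return GlobalResponseMatrix(mean, design.modules)


def _as_array(R) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(R, GlobalResponseMatrix):
        return R.values, R.modules
    return np.asarray(R, dtype=float), None


def infer_network(
    R, *, cond_threshold: float = DEFAULT_COND_THRESHOLD
) -> LocalResponseNetwork:
    """Solve the MRA system for connection coefficients and magnitudes.

    ``r = -[diag(R^-1)]^-1 R^-1`` and ``P_i = 1 / (R^-1)_ii``; the diagonal
    of ``r`` is set to exactly -1 after the division rather than being left
    to floating-point rounding.

    Raises :class:`InferenceError` when ``cond(R)`` exceeds *cond_threshold*
    (returning coefficients from a near-singular system would silently
    amplify measurement noise) or when a diagonal entry of ``R^-1``
    vanishes, leaving that module's perturbation magnitude undefined.
    """
    values, modules = _as_array(R)
    n = values.shape[0]
    if values.shape != (n, n):
        raise DataError(f"response matrix must be square, got {values.shape}")
    if modules is None:
        modules = tuple(f"M{i + 1}" for i in range(n))
    cond = np.linalg.cond(values)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise InferenceError(
            f"global response matrix is singular or ill-conditioned "
            f"(condition number {cond:.3g} > {cond_threshold:.3g})"
        )
    Rinv = np.linalg.inv(values)
    diag = np.diag(Rinv)
    zero = np.flatnonzero(diag == 0)
    if zero.size:
        raise InferenceError(
            f"perturbation magnitude undefined for module {modules[zero[0]]!r}: "
            "diagonal entry of R^-1 is zero"
        )
    P = 1.0 / diag
    r = -Rinv / diag[:, None]
    np.fill_diagonal(r, -1.0)
    return LocalResponseNetwork(r, P, modules)


def predict_response(
    net: LocalResponseNetwork, c: CombinedPerturbation
) -> np.ndarray:
    """Relative change of every module under combined perturbation *c*:
    ``-r^-1 diag(P) c``."""
    if c.weights.shape != (net.n,):
        raise DataError(
            f"weight vector length {c.weights.shape[0]} != module count {net.n}"
        )
    cond = np.linalg.cond(net.r)
    if not np.isfinite(cond) or cond > DEFAULT_COND_THRESHOLD:
        raise InferenceError(
            f"connection-coefficient matrix is singular (condition number {cond:.3g})"
        )
    return -np.linalg.solve(net.r, net.P * c.weights)


def predict_abundance(
    net: LocalResponseNetwork,
    c: CombinedPerturbation,
    basal: Sequence[float],
) -> np.ndarray:
    """Predicted reporter abundances under *c* given *basal* abundances.

    Inverts the symmetric relative difference in closed form:
    ``basal_i (2 + v_i) / (2 - v_i)`` with ``v = -r^-1 diag(P) c``.  A
    predicted |v_i| >= 2 cannot correspond to any positive abundance and
    raises :class:`SaturationError` naming the module.
    """
    basal = np.asarray(basal, dtype=float)
    if basal.shape != (net.n,):
        raise DataError(f"basal vector length {basal.shape} != module count {net.n}")
    if np.any(basal <= 0) or not np.all(np.isfinite(basal)):
        raise DataError("basal abundances must be strictly positive and finite")
    v = predict_response(net, c)
    sat = np.flatnonzero(np.abs(v) >= 2)
    if sat.size:
        raise SaturationError(
            f"predicted relative change {v[sat[0]]:.4g} of module "
            f"{net.modules[sat[0]]!r} is outside (-2, 2); no positive abundance "
            "realises it"
        )
    return inverse_symmetric_relative_change(v, basal)
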