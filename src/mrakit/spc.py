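"""Range-based standard-deviation estimation for very small replicate series.

Statistical process control (SPC) estimates the standard deviation of a
process from the *ranges* of small rational subgroups: the mean subgroup
range divided by Hartley's constant d2(n) — the expected range of n i.i.d.
standard normal variables — is an unbiased estimator of sigma.  With three
biological replicates of two technical replicates each, this is the only
practical per-cell variance estimator, and it respects the two-level
replicate hierarchy (ranges are taken *within* a biological replicate).

For sparser designs (RNA-seq duplicates) the estimator is pooled across a
population of genes measured under the same perturbation, with iterative
exclusion of genes whose replicates are out of control according to the
range chart (range above D4(n) times the mean range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "hartley_d2",
    "range_chart_d4",
    "SubgroupedSamples",
    "SpcEstimate",
    "ColumnVariance",
    "spc_intra_sd",
    "estimate_population_column_sd",
]

# Standard SPC constants for subgroup sizes 2..10 (embedded; no runtime
# table lookup).  d2(n) = E[range of n iid N(0,1)]; D4(n) is the upper
# range-chart control limit factor.
_D2 = {2: 1.128, 3: 1.693, 4: 2.059, 5: 2.326, 6: 2.534, 7: 2.704, 8: 2.847, 9: 2.970, 10: 3.078}
_D4 = {2: 3.267, 3: 2.574, 4: 2.282, 5: 2.114, 6: 2.004, 7: 1.924, 8: 1.864, 9: 1.816, 10: 1.777}
# Lower control limit factor D3 (zero below n=7).
_D3 = {2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0, 6: 0.0, 7: 0.076, 8: 0.136, 9: 0.184, 10: 0.223}


def hartley_d2(n_r: int) -> float:
    """Hartley's constant d2 for subgroup size *n_r* (2..10).

    d2(2) = 1.128; dividing a mean range of subgroups of two by it yields an
    unbiased standard-deviation estimate for normal data.
    """
    if n_r not in _D2:
        raise DataError(
            f"Hartley's d2 is tabulated for subgroup sizes 2..10, got {n_r} "
            "(a single observation has no range)"
        )
    return _D2[n_r]


def range_chart_d4(n_r: int) -> float:
    """Upper range-chart control factor D4 for subgroup size *n_r* (2..10)."""
    if n_r not in _D4:
        raise DataError(f"D4 is tabulated for subgroup sizes 2..10, got {n_r}")
    return _D4[n_r]


@dataclass(frozen=True)
class SubgroupedSamples:
    """``k_t`` subgroups of ``n_r`` values each: one subgroup per biological
    replicate, members are technical replicates, for one cell of R."""

    subgroups: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        groups = tuple(tuple(float(v) for v in g) for g in self.subgroups)
        object.__setattr__(self, "subgroups", groups)
        if not groups:
            raise DataError("need at least one subgroup")
        sizes = {len(g) for g in groups}
        if len(sizes) != 1:
            raise DataError(f"ragged subgroups: sizes {sorted(sizes)}")
        if sizes.pop() < 2:
            raise DataError("subgroups need at least two members to have a range")

    @property
    def k_t(self) -> int:
        return len(self.subgroups)

    @property
    def n_r(self) -> int:
        return len(self.subgroups[0])


@dataclass(frozen=True)
class SpcEstimate:
    """Result of the range-based intra-subgroup sd estimate."""

    s_intra: float
    mean_range: float
    d2: float
    k_t: int
    n_r: int


def spc_intra_sd(samples: SubgroupedSamples) -> SpcEstimate:
    """Intra-subgroup standard deviation: mean subgroup range over d2(n_r).

    ``s = (sum_i range_i) / (k_t * d2(n_r))`` where ``range_i`` is max - min
    within subgroup i.
    """
    arr = np.asarray(samples.subgroups, dtype=float)
    ranges = arr.max(axis=1) - arr.min(axis=1)
    d2 = hartley_d2(samples.n_r)
    mean_range = float(ranges.mean())
    return SpcEstimate(
        s_intra=mean_range / d2,
        mean_range=mean_range,
        d2=d2,
        k_t=samples.k_t,
        n_r=samples.n_r,
    )


@dataclass(frozen=True)
class ColumnVariance:
    """Pooled gene-population sd for one perturbation column, with the
    iterative out-of-control exclusion trace."""

    sigma: float
    retained_genes: tuple = ()
    excluded_genes: tuple = ()  # (gene, iteration excluded)
    n_iterations: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DataError("pooled sigma cannot be negative")


ExclusionRule = Literal["range_chart", "zscore", "none"]


def estimate_population_column_sd(
    responses: pd.DataFrame | np.ndarray,
    *,
    rule: ExclusionRule = "range_chart",
    two_sided: bool = False,
    min_retained: int = 5,
    zscore_limit: float = 3.0,
) -> ColumnVariance:
    """Pooled sd of per-gene responses under one perturbation, with
    iterative exclusion of out-of-control genes.

    *responses*: rows = genes, columns = replicate measurements of the
    gene's global response under this perturbation (>= 2 replicates,
    >= 10 genes).  Each gene's replicates form one subgroup.

    Iterates: pool the mean range over retained genes and convert to sigma
    via d2; flag genes whose subgroup is out of control under *rule*
    ("range_chart": range > D4(n) * mean range, optionally also below
    D3(n) * mean range when *two_sided*; "zscore": gene mean further than
    *zscore_limit* sigmas from the retained-population mean; "none":
    no exclusion); remove them and repeat until the retained set is a
    fixed point.
    """
    if isinstance(responses, pd.DataFrame):
        genes = list(responses.index)
        values = responses.to_numpy(dtype=float)
    else:
        values = np.asarray(responses, dtype=float)
        genes = list(range(values.shape[0]))
    if values.ndim != 2 or values.shape[1] < 2:
        raise DataError("need a genes x replicates table with >= 2 replicates")
    if values.shape[0] < 10:
        raise DataError(
            f"population pooling needs >= 10 genes, got {values.shape[0]}"
        )
    n_rep = values.shape[1]
    d2 = hartley_d2(n_rep)
    ranges = values.max(axis=1) - values.min(axis=1)

    retained = np.ones(len(genes), dtype=bool)
    excluded: list[tuple] = []
    iteration = 0
    while True:
        iteration += 1
        if retained.sum() < min_retained:
            raise DataError(
                f"only {int(retained.sum())} genes retained (< {min_retained}): "
                "population too heterogeneous to pool"
            )
        mean_range = float(ranges[retained].mean())
        sigma = mean_range / d2
        if rule == "none":
            break
        if rule == "range_chart":
            upper = range_chart_d4(n_rep) * mean_range
            out = retained & (ranges > upper)
            if two_sided:
                out |= retained & (ranges < _D3[n_rep] * mean_range)
        elif rule == "zscore":
            means = values.mean(axis=1)
            center = float(means[retained].mean())
            out = retained & (np.abs(means - center) > zscore_limit * sigma)
        else:
            raise DataError(f"unknown exclusion rule {rule!r}")
        if not out.any():
            break
        for idx in np.flatnonzero(out):
            excluded.append((genes[idx], iteration))
        retained &= ~out

    return ColumnVariance(
        sigma=sigma,
        retained_genes=tuple(genes[i] for i in np.flatnonzero(retained)),
        excluded_genes=tuple(excluded),
        n_iterations=iteration,
    )
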