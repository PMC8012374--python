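"""Screen gene panels for proximity to a reference MRA network.

Each candidate gene takes the place of one module's reporter: the row of
the global response matrix belonging to the replaced module is overwritten
with the candidate's own responses to the elementary perturbations, the
network is re-inferred, and its connection coefficients are compared to
the reference network by Euclidean distance and 1 - Pearson correlation.
Genes whose inferred network sits closest to the reference are candidates
for tight transcriptional control by the same regulatory core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import GlobalResponseMatrix, LocalResponseNetwork, infer_network
from .exceptions import DataError, InferenceError, UnscreenableError

__all__ = [
    "infer_candidate_network",
    "network_distance",
    "rank_candidates",
    "ScreenResult",
]


def infer_candidate_network(
    candidate_responses: Sequence[float],
    reference_R: GlobalResponseMatrix,
    replaced_module: str,
    *,
    cond_threshold: float = 1e8,
) -> LocalResponseNetwork:
    """Re-infer the network with a candidate gene as the replaced module's
    reporter.

    The candidate's response vector (its symmetric relative change under
    each elementary perturbation, in module order) overwrites the replaced
    module's row of R; the other modules' responses are unchanged.  A
    singular assembled matrix raises :class:`UnscreenableError`.
    """
    if replaced_module not in reference_R.modules:
        raise DataError(f"unknown module {replaced_module!r}")
    resp = np.asarray(candidate_responses, dtype=float)
    if resp.shape != (reference_R.n,):
        raise DataError(
            f"candidate response vector length {resp.shape} != module count {reference_R.n}"
        )
    idx = reference_R.modules.index(replaced_module)
    R = reference_R.values.copy()
    R[idx, :] = resp
    try:
        assembled = GlobalResponseMatrix(R, reference_R.modules)
        return infer_network(assembled, cond_threshold=cond_threshold)
    except (InferenceError, DataError) as exc:
        raise UnscreenableError(str(exc)) from exc


def _off_diagonal(net: LocalResponseNetwork, include_diagonal: bool) -> np.ndarray:
    if include_diagonal:
        return net.r.ravel()
    n = net.n
    mask = ~np.eye(n, dtype=bool)
    return net.r[mask]  # row-major order of the off-diagonal entries


def network_distance(
    a: LocalResponseNetwork,
    b: LocalResponseNetwork,
    metric: Literal["euclidean", "one_minus_correlation"] = "euclidean",
    *,
    include_diagonal: bool = False,
) -> float:
    """Distance between two networks' connection coefficients.

    Both metrics act on the off-diagonal entries of r flattened row-major
    (the -1 diagonal is constant by construction and carries no
    information; *include_diagonal* restores it for parity experiments).
    """
    if a.modules != b.modules:
        raise DataError(
            f"module order mismatch: {a.modules} vs {b.modules}"
        )
    va = _off_diagonal(a, include_diagonal)
    vb = _off_diagonal(b, include_diagonal)
    if metric == "euclidean":
        return float(np.linalg.norm(va - vb))
    if metric == "one_minus_correlation":
        if np.std(va) == 0 or np.std(vb) == 0:
            raise DataError(
                "correlation undefined: a coefficient vector has zero variance"
            )
        return float(1.0 - np.corrcoef(va, vb)[0, 1])
    raise DataError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class ScreenResult:
    """Ranked panel: per-gene distances to the reference network under both
    metrics, plus the genes that could not be screened (singular R)."""

    table: pd.DataFrame  # columns: gene, euclidean, one_minus_correlation, rank_euclid, rank_corr
    unscreenable: tuple = ()  # (gene, reason)

    def top(self, k: int, by: str = "rank_euclid") -> pd.DataFrame:
        return self.table.nsmallest(k, by)


def rank_candidates(
    reference: LocalResponseNetwork,
    panel: pd.DataFrame,
    reference_R: GlobalResponseMatrix,
    replaced_module: str,
    *,
    include_diagonal: bool = False,
) -> ScreenResult:
    """Screen every panel gene and rank by both distance metrics.

    *panel*: rows = genes, columns = the gene's responses to the elementary
    perturbations in module order.  Ranks are 1-based; ties are broken by
    gene identifier order, so the ranking does not depend on the panel's
    input order.
    """
    if panel.empty:
        raise DataError("candidate panel is empty")
    records = []
    unscreenable = []
    for gene in panel.index:
        try:
            net = infer_candidate_network(
                panel.loc[gene].to_numpy(dtype=float), reference_R, replaced_module
            )
            records.append(
                {
                    "gene": gene,
                    "euclidean": network_distance(
                        net, reference, "euclidean", include_diagonal=include_diagonal
                    ),
                    "one_minus_correlation": network_distance(
                        net,
                        reference,
                        "one_minus_correlation",
                        include_diagonal=include_diagonal,
                    ),
                }
            )
        except (UnscreenableError, DataError) as exc:
            unscreenable.append((gene, str(exc)))
    if not records:
        raise DataError("no candidate could be screened (all singular)")
    table = pd.DataFrame(records)
    for col, rank_col in [
        ("euclidean", "rank_euclid"),
        ("one_minus_correlation", "rank_corr"),
    ]:
        order = sorted(range(len(table)), key=lambda i: (table[col][i], str(table["gene"][i])))
        ranks = np.empty(len(table), dtype=int)
        ranks[order] = np.arange(1, len(table) + 1)
        table[rank_col] = ranks
    table = table.sort_values("rank_euclid").reset_index(drop=True)
    return ScreenResult(table=table, unscreenable=tuple(unscreenable))
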