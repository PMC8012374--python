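"""File formats: condition maps, measurement tables, design files, network
tables and graph export.

The condition-map grammar binds free-text condition labels to the modules
they perturb, one entry per line::

    E2+RA -> 0              # the basal condition (target "0")
    E2+RA+siLCoR -> LCoR    # perturbation of module LCoR

The arrow accepts both "->" and the spaced variant "- >"; '+' is an
ordinary character inside condition names.  Exactly one entry must target
"0" and no module may be targeted twice.

Measurement tables come in a long dialect (columns reporter, condition,
bio_rep, tech_rep, value) and a wide dialect (rows = reporters, columns =
"condition.bio.tech").  All numeric output is written at full double
precision so read/write round-trips are exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd
import yaml

from .bootstrap import CiTable
from .core import (
    AbundanceSet,
    ExperimentDesign,
    GlobalResponseMatrix,
    LocalResponseNetwork,
)
from .exceptions import DataError, ParseError

__all__ = [
    "ConditionMapEntry",
    "parse_condition_map",
    "load_design",
    "read_measurements",
    "write_measurements",
    "read_network",
    "write_network",
    "export_graph",
]

BASAL_MARKER = "0"
_ARROW = re.compile(r"^(.*\S)\s*-\s*>\s*(\S.*?)\s*$")
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class ConditionMapEntry:
    """One condition-map line: a condition and the module it perturbs
    (or the basal marker "0")."""

    condition: str
    target: str


def parse_condition_map(lines: Iterable[str] | str) -> list[ConditionMapEntry]:
    """Parse condition-map text into validated entries.

    Blank lines and '#' comments are skipped.  Raises :class:`ParseError`
    with the line number on malformed lines, a missing or duplicated basal
    entry, or two conditions targeting the same module.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    entries: list[ConditionMapEntry] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _ARROW.match(line)
        if not m:
            raise ParseError(
                f"line {lineno}: expected 'CONDITION -> TARGET', got {raw!r}"
            )
        entries.append(ConditionMapEntry(m.group(1).strip(), m.group(2).strip()))
    basal = [e for e in entries if e.target == BASAL_MARKER]
    if len(basal) != 1:
        raise ParseError(
            f"expected exactly one basal entry (target '0'), found {len(basal)}"
        )
    conds = [e.condition for e in entries]
    if len(set(conds)) != len(conds):
        dup = next(c for c in conds if conds.count(c) > 1)
        raise ParseError(f"condition {dup!r} appears more than once")
    targets = [e.target for e in entries if e.target != BASAL_MARKER]
    if len(set(targets)) != len(targets):
        dup = next(t for t in targets if targets.count(t) > 1)
        raise ParseError(f"module {dup!r} is targeted by more than one condition")
    return entries


def load_design(path: str | Path) -> ExperimentDesign:
    """Load an experiment design from a YAML file.

    Expected keys: ``modules`` (ordered list), ``condition_map`` (text in
    the condition-map grammar or a list of lines), optional ``reporters``
    (map module -> reporter) and ``replicates``
    (``{biological: k_t, technical: n_r}``).  Module order in the file is
    preserved everywhere.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: design file must be a YAML mapping")
    try:
        modules = tuple(str(m) for m in doc["modules"])
        cmap_raw = doc["condition_map"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing design key {exc}") from None
    if isinstance(cmap_raw, list):
        cmap_raw = "\n".join(str(line) for line in cmap_raw)
    entries = parse_condition_map(str(cmap_raw))
    basal = next(e.condition for e in entries if e.target == BASAL_MARKER)
    pmap = {e.condition: e.target for e in entries if e.target != BASAL_MARKER}
    reps = doc.get("replicates", {})
    replicates = (int(reps.get("biological", 1)), int(reps.get("technical", 1)))
    return ExperimentDesign(
        modules=modules,
        basal_condition=basal,
        perturbation_map=pmap,
        reporters={str(k): str(v) for k, v in doc.get("reporters", {}).items()},
        replicates=replicates,
    )


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------


def read_measurements(
    path: str | Path, dialect: Literal["long", "wide"] = "long"
) -> AbundanceSet:
    """Read an abundance table (tab-delimited).

    Long dialect: columns reporter, condition, bio_rep, tech_rep, value.
    Wide dialect: first column = reporter, remaining column labels
    "condition.bio.tech" (the condition label may itself contain dots; the
    last two dot-fields are the replicate indices).
    """
    if dialect == "long":
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        try:
            return AbundanceSet(table)
        except DataError as exc:
            raise DataError(f"{path}: {exc}") from exc
    if dialect == "wide":
        wide = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        records = []
        for col in wide.columns:
            parts = str(col).rsplit(".", 2)
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: column {col!r} is not 'condition.bio.tech'"
                )
            cond, bio, tech = parts
            try:
                bio_i, tech_i = int(bio), int(tech)
            except ValueError:
                raise ParseError(
                    f"{path}: column {col!r} has non-integer replicate indices"
                ) from None
            for reporter, value in wide[col].items():
                records.append((str(reporter), cond, bio_i, tech_i, float(value)))
        try:
            return AbundanceSet.from_records(records)
        except DataError as exc:
            raise DataError(f"{path}: {exc}") from exc
    raise DataError(f"unknown dialect {dialect!r}")


def write_measurements(
    data: AbundanceSet,
    path: str | Path,
    dialect: Literal["long", "wide"] = "long",
) -> None:
    """Write an abundance table; round-trips exactly through
    :func:`read_measurements`."""
    table = data.table
    if dialect == "long":
        table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        return
    if dialect == "wide":
        wide = table.pivot_table(
            index="reporter",
            columns=["condition", "bio_rep", "tech_rep"],
            values="value",
            sort=False,
        )
        wide.columns = [f"{c}.{b}.{t}" for c, b, t in wide.columns]
        wide.index.name = "reporter"
        wide.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
        return
    raise DataError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Network tables
# ---------------------------------------------------------------------------


def write_network(net: LocalResponseNetwork, r_path: str | Path, p_path: str | Path) -> None:
    """Write r (TSV matrix, module headers) and P (TSV vector)."""
    net.r_frame().to_csv(r_path, sep="\t", float_format=_FLOAT_FMT)
    net.p_series().to_frame().to_csv(p_path, sep="\t", float_format=_FLOAT_FMT)


def read_network(r_path: str | Path, p_path: str | Path) -> LocalResponseNetwork:
    r = pd.read_csv(r_path, sep="\t", index_col=0, float_precision="round_trip")
    P = pd.read_csv(p_path, sep="\t", index_col=0, float_precision="round_trip")["P"]
    modules = tuple(str(m) for m in r.index)
    if tuple(str(c) for c in r.columns) != modules or tuple(str(i) for i in P.index) != modules:
        raise ParseError("module order differs between r and P tables")
    return LocalResponseNetwork(r.to_numpy(dtype=float), P.to_numpy(dtype=float), modules)


def write_response_matrix(R: GlobalResponseMatrix, path: str | Path) -> None:
    R.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_response_matrix(path: str | Path) -> GlobalResponseMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    modules = tuple(str(m) for m in frame.index)
    if tuple(str(c) for c in frame.columns) != modules:
        raise ParseError(f"{path}: row and column headers differ")
    return GlobalResponseMatrix(frame.to_numpy(dtype=float), modules)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------


def _build_graph(
    net: LocalResponseNetwork,
    ci: CiTable | None,
    edge_filter,
) -> nx.DiGraph:
    G = nx.DiGraph()
    for m in net.modules:
        G.add_node(m)
    for i, target in enumerate(net.modules):
        for j, source in enumerate(net.modules):
            if i == j:
                continue  # the -1 diagonal is a normalization, not an interaction
            w = float(net.r[i, j])
            if not edge_filter(w):
                continue
            attrs = {"weight": w, "sign": "+" if w > 0 else "-"}
            if ci is not None:
                attrs["significant"] = bool(
                    ci.row(f"r[{target},{source}]")["significant"]
                )
            G.add_edge(source, target, **attrs)
    return G


def export_graph(
    net: LocalResponseNetwork,
    ci: CiTable | None = None,
    fmt: Literal["graphml", "gml"] = "graphml",
    path: str | Path | None = None,
    edge_filter=None,
) -> str:
    """Serialize the network as GraphML or GML (Cytoscape / yEd ready).

    Edges run source module -> target module with attributes ``weight``
    (the connection coefficient), ``sign`` and, when a CI table is given,
    ``significant`` (CI excludes zero).  Self-loops are omitted.
    *edge_filter* takes a weight and returns whether to keep the edge
    (default: nonzero weights).  Returns the serialized document; writes
    it to *path* when given.
    """
    if edge_filter is None:
        edge_filter = lambda w: w != 0
    if fmt not in ("graphml", "gml"):
        raise DataError(f"unknown graph format {fmt!r}")
    G = _build_graph(net, ci, edge_filter)
    if fmt == "graphml":
        text = "\n".join(nx.generate_graphml(G, named_key_ids=True))
    else:
        text = "\n".join(nx.generate_gml(G))
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
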