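"""Readers and writers for the tabular and network formats the pipeline touches.

All tabular formats are UTF-8, tab-delimited.  Interaction tables may be
either a SIF dialect (``A <relation> B [C D ...]``) or a BioGRID-tab-style
export (columns ``INTERACTOR_A``/``INTERACTOR_B``); the dialect is
auto-detected from the header line.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import ComparisonSpec, ExpressionMatrix, GeneAnnotation, StudyDesign

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "read_design",
    "read_comparisons",
    "read_interactions",
    "read_localization",
    "write_network",
    "read_network",
    "file_checksum",
]


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, recorded in the provenance manifest."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_expression_matrix(path: str | Path, linear_input: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Values are taken as log2 scale; pass ``linear_input=True`` to apply
    log2 on load.  Duplicate ids and non-numeric or missing cells are hard
    errors naming the offending record.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene id(s): {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        rows, cols = bad.to_numpy().nonzero()
        gene, sample = df.index[rows[0]], df.columns[cols[0]]
        raw = df.iat[rows[0], cols[0]]
        what = "empty cell" if pd.isna(raw) else f"non-numeric value {raw!r}"
        raise ValueError(f"{path}: {what} at gene {gene!r}, sample {sample!r}")
    if linear_input:
        import numpy as np

        if (numeric.to_numpy() <= 0).any():
            raise ValueError(f"{path}: non-positive value cannot be log2-transformed")
        numeric = np.log2(numeric)
    return ExpressionMatrix(numeric)


def read_design(
    path: str | Path,
    expr: ExpressionMatrix | None = None,
    factor_names: tuple[str, str] = ("genotype", "treatment"),
) -> StudyDesign:
    """Read a design TSV with columns sample_id, <factor1>, <factor2>, replicate.

    When an expression matrix is supplied, sample sets must match exactly.
    Conditions with a single replicate load with a warning flag that the
    differential-expression stage consumes (their p-values are absent).
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    design = StudyDesign(table, factor_names=factor_names)
    if expr is not None:
        design.validate_against(expr)
    for cond in sorted(design.single_replicate_conditions):
        log.warning("condition %s has a single replicate; p-values will be absent", cond)
    return design


def read_comparisons(path: str | Path) -> list[ComparisonSpec]:
    """Read a comparisons TSV: id, numerator, denominator, perturbed_factor, order_index."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id", "numerator", "denominator", "perturbed_factor", "order_index"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: comparisons file missing column(s): {missing}")
    specs = [
        ComparisonSpec(
            row["id"], row["numerator"], row["denominator"],
            row["perturbed_factor"], int(row["order_index"]),
        )
        for _, row in table.iterrows()
    ]
    return sorted(specs, key=lambda s: s.order_index)


def write_comparisons(specs: list[ComparisonSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": s.id, "numerator": s.numerator, "denominator": s.denominator,
                "perturbed_factor": s.perturbed_factor, "order_index": s.order_index,
            }
            for s in specs
        ]
    ).to_csv(path, sep="\t", index=False)


def _is_biogrid_header(line: str) -> bool:
    upper = line.upper()
    return "INTERACTOR_A" in upper or "INTERACTOR A" in upper


def read_interactions(path: str | Path) -> list[tuple[str, str, str]]:
    """Read physical interactions from SIF or BioGRID-tab into an edge list.

    Returns undirected, deduplicated ``(gene_a, gene_b, source_tag)`` triples
    with ``gene_a < gene_b``; self-interactions are dropped with a logged
    count.  SIF lines may list several targets (``A pp B C``).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    edges: dict[tuple[str, str], str] = {}
    n_self = 0

    def record(a: str, b: str, tag: str) -> None:
        nonlocal n_self
        if a == b:
            n_self += 1
            return
        key = (a, b) if a < b else (b, a)
        edges.setdefault(key, tag)

    if _is_biogrid_header(lines[0]):
        header = lines[0].split("\t")
        upper = [h.strip().upper() for h in header]
        ia = next(i for i, h in enumerate(upper) if "INTERACTOR_A" in h or "INTERACTOR A" in h)
        ib = next(i for i, h in enumerate(upper) if "INTERACTOR_B" in h or "INTERACTOR B" in h)
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) <= max(ia, ib):
                raise ValueError(f"{path}:{lineno}: unparseable BioGRID line")
            record(fields[ia].strip(), fields[ib].strip(), "biogrid")
    else:
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: unparseable SIF line (need >= 3 fields)")
            src = fields[0]
            for target in fields[2:]:
                record(src, target, "sif")
    if n_self:
        log.info("dropped %d self-interaction(s) from %s", n_self, path)
    return [(a, b, tag) for (a, b), tag in sorted(edges.items())]


def read_localization(
    path: str | Path,
    synonyms: dict[str, str] | None = None,
    vocabulary: set[str] | None = None,
) -> GeneAnnotation:
    """Read gene -> compartment labels from a 2-column TSV or a GAF subset.

    GAF rows (detected by a ``!gaf-version`` header or 15+ columns) are
    filtered to the cellular-component aspect ("C"); the GO id / term column
    is mapped through the synonym table.  Nothing here is fatal:
    unrecognised labels land in ``annotation.unrecognized``.
    """
    path = Path(path)
    ann = GeneAnnotation(synonyms=synonyms, vocabulary=vocabulary)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    is_gaf = any(line.startswith("!gaf-version") for line in lines[:5])
    if not is_gaf:
        data = [l for l in lines if l.strip() and not l.startswith(("!", "#"))]
        if data and len(data[0].split("\t")) >= 15:
            is_gaf = True
    for line in lines:
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.split("\t")
        if is_gaf:
            if len(fields) < 9 or fields[8] != "C":
                continue  # keep only cellular-component rows
            ann.add(fields[2], fields[4])
        else:
            if len(fields) < 2:
                continue
            ann.add(fields[0], fields[1])
    if ann.unrecognized:
        log.info(
            "%d unrecognized compartment label(s) mapped to 'unknown': %s",
            len(ann.unrecognized), sorted(ann.unrecognized)[:10],
        )
    return ann


def write_network(network: nx.MultiGraph, path: str | Path, format: str = "graphml") -> None:
    """Export the integrated network as GraphML (attribute-preserving) or SIF.

    SIF keeps only node/edge identity (weights and fold changes are dropped;
    documented limitation of the format).  GraphML serialises set-valued
    node attributes as comma-joined strings so the export round-trips.
    """
    fmt = format.lower()
    path = Path(path)
    if fmt == "graphml":
        g = nx.MultiGraph()
        for node, attrs in network.nodes(data=True):
            flat: dict[str, object] = {}
            for k, v in attrs.items():
                if isinstance(v, (set, frozenset)):
                    flat[k] = ",".join(sorted(v))
                elif isinstance(v, dict):
                    for kk, vv in v.items():
                        flat[f"{k}_{kk}"] = vv
                else:
                    flat[k] = v
            g.add_node(node, **flat)
        for a, b, key, attrs in network.edges(data=True, keys=True):
            g.add_edge(a, b, key=key, **attrs)
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            isolated = []
            for a, b, key in network.edges(keys=True):
                fh.write(f"{a}\t{key}\t{b}\n")
            for node in network.nodes:
                if network.degree(node) == 0:
                    isolated.append(node)
            for node in isolated:
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown network format {format!r} (use 'graphml' or 'sif')")


def read_network(path: str | Path) -> nx.MultiGraph:
    """Re-import a GraphML export."""
    g = nx.read_graphml(path, force_multigraph=True)
    return nx.MultiGraph(g)
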