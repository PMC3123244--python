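"""Assembly of the integrated regulatory network.

Two edge types are combined in a :class:`networkx.MultiGraph` whose edge
keys are the type tags: ``ppi`` edges taken from a physical-interaction
table, and ``coexpr`` edges between genes whose expression profiles have a
Pearson correlation above the cutoff (0.9 by default).  Nodes carry the
gene's compartment annotation and its per-comparison log2 fold changes.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneAnnotation, Parameters, StudyDesign

log = logging.getLogger(__name__)

__all__ = ["ppi_subnetwork", "coexpression_edges", "merge_network"]


def ppi_subnetwork(
    genes: set[str],
    interactions: list[tuple[str, str, str]],
    include_neighbors: bool = False,
) -> list[tuple[str, str, str]]:
    """Physical-interaction edges for a query gene set.

    By default the induced subgraph (both endpoints in the query set);
    with ``include_neighbors`` also first-level edges from query genes to
    direct interactors (the neighbour nodes are tagged ``context`` by
    :func:`merge_network`).  An empty result is valid.
    """
    if not genes:
        raise ValueError("query gene set is empty")
    out = []
    for a, b, _tag in interactions:
        if a in genes and b in genes:
            out.append((a, b, "ppi"))
        elif include_neighbors and (a in genes or b in genes):
            out.append((a, b, "ppi"))
    return out


def expression_profiles(
    expr: ExpressionMatrix,
    genes: set[str] | None = None,
    fc: pd.DataFrame | None = None,
    mode: str = "samples",
) -> pd.DataFrame:
    """Per-gene profile vectors used for coexpression.

    ``samples`` mode (default) uses the per-sample log2 values across all
    arrays; ``fc`` mode uses the per-comparison log2 fold changes, which
    requires the fold-change table.
    """
    if mode == "samples":
        prof = expr.values
    elif mode == "fc":
        if fc is None:
            raise ValueError("fc mode requires a fold-change table")
        prof = fc.pivot(index="gene", columns="comparison_id", values="log2fc")
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    if genes is not None:
        prof = prof.loc[[g for g in prof.index if g in genes]]
    return prof


def coexpression_edges(
    profiles: pd.DataFrame,
    params: Parameters | None = None,
) -> list[tuple[str, str, float]]:
    """Coexpression edges: unordered gene pairs with Pearson r above cutoff.

    ``signed`` mode keeps r >= cutoff, ``absolute`` mode \\|r\\| >= cutoff.
    Genes with a zero-variance profile are skipped with a logged warning
    (their correlation is undefined).  The result is sorted by gene pair,
    so it is independent of input row order.
    """
    params = params or Parameters()
    if profiles.shape[1] < 3:
        raise ValueError("profiles need length >= 3 for a meaningful correlation")
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 0
    dropped = list(profiles.index[~keep])
    if dropped:
        log.warning("skipping %d zero-variance gene(s): %s", len(dropped), dropped[:10])
    arr = arr[keep]
    names = list(profiles.index[keep])
    if len(names) < 2:
        return []
    # per-pair normalised dot products: bit-identical under row reordering
    dev = arr - arr.mean(axis=1, keepdims=True)
    dev = np.ascontiguousarray(dev)
    norms = np.sqrt((dev * dev).sum(axis=1))
    edges = []
    for i, j in combinations(range(len(names)), 2):
        rij = float(np.dot(dev[i], dev[j]) / (norms[i] * norms[j]))
        value = abs(rij) if params.corr_mode == "absolute" else rij
        if value >= params.corr_cutoff:
            a, b = names[i], names[j]
            if b < a:
                a, b = b, a
            edges.append((a, b, rij))
    edges.sort(key=lambda e: (e[0], e[1]))
    return edges


def merge_network(
    ppi_edges: list[tuple[str, str, str]],
    coexpr_edges: list[tuple[str, str, float]],
    annotations: GeneAnnotation,
    fc: pd.DataFrame,
    genes: set[str] | None = None,
) -> nx.MultiGraph:
    """Union of PPI and coexpression edges with node attributes attached.

    Parallel ppi+coexpr edges between the same pair are retained as two
    typed edges (distinct MultiGraph keys).  Node attributes: compartment
    set, per-comparison log2fc dict, and a ``context`` flag for PPI
    neighbours outside the analysis gene set.  Genes without fold-change
    rows get a zero vector and are flagged ``fc_missing``.
    """
    g = nx.MultiGraph()
    core = set(genes) if genes is not None else None
    if core is None:
        core = {a for a, b, _ in ppi_edges} | {b for a, b, _ in ppi_edges}
        core |= {a for a, b, _ in coexpr_edges} | {b for a, b, _ in coexpr_edges}
    comparison_ids = list(pd.unique(fc["comparison_id"])) if len(fc) else []
    fc_map = {
        gene: dict(zip(sub["comparison_id"], sub["log2fc"]))
        for gene, sub in fc.groupby("gene", sort=False)
    }

    def add_node(node: str) -> None:
        if node in g:
            return
        vec = fc_map.get(node)
        missing = vec is None
        if missing:
            vec = {c: 0.0 for c in comparison_ids}
            log.warning("gene %s has no fold-change rows; log2fc set to 0", node)
        g.add_node(
            node,
            compartments=annotations.compartments(node),
            log2fc={k: float(v) for k, v in vec.items()},
            context=node not in core,
            fc_missing=missing,
        )

    for node in sorted(core):
        add_node(node)
    for a, b, _tag in ppi_edges:
        add_node(a)
        add_node(b)
        if not g.has_edge(a, b, key="ppi"):
            g.add_edge(a, b, key="ppi", type="ppi")
    for a, b, r in coexpr_edges:
        add_node(a)
        add_node(b)
        if not g.has_edge(a, b, key="coexpr"):
            g.add_edge(a, b, key="coexpr", type="coexpr", pearson_r=float(r))
    return g
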