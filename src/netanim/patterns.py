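"""Sign-pattern classification and regulator role inference.

Each gene's ordered sequence of up/down/no-change calls across the
pairwise comparisons is reduced to evidence about the two perturbed
regulators.  The inference rule is the loss-of-function logic: if a gene
goes *down* when a regulator's function is lost, that regulator was
(directly or indirectly) an activator of the gene; if it goes *up*, a
repressor.  Genes whose evidence is consistent across all comparisons get
one of four labels:

========  ==============  ============
pattern   Hsp90 role      p23 role
========  ==============  ============
A         activator       repressor
B         repressor       activator
C         repressor       repressor
D         activator       activator
========  ==============  ============

Genes with any no-change call, or with conflicting evidence for a factor,
fall in the catch-all pattern E; genes with no-change calls everywhere are
reported as ``unresponsive`` (they never entered the analysis set).

This automates the by-eye detection of recurring red/green colour
patterns in the animated network view: with the canonical comparison
order, pattern A is the colour string red, green, green, red and pattern
B its complement, C is all red, D all green.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import ComparisonSpec

log = logging.getLogger(__name__)

__all__ = ["SignSequence", "PatternCall", "sign_sequence", "role_evidence", "classify", "classify_all"]

PATTERN_LOOKUP: dict[tuple[str, str], str] = {
    ("act", "rep"): "A",
    ("rep", "act"): "B",
    ("rep", "rep"): "C",
    ("act", "act"): "D",
}


@dataclass(frozen=True)
class SignSequence:
    """Ordered U/D/N calls for one gene, in comparison ``order_index`` order."""

    gene: str
    calls: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [c for c in self.calls if c not in ("U", "D", "N")]
        if bad:
            raise ValueError(f"invalid call(s) {bad} for gene {self.gene}")


@dataclass(frozen=True)
class PatternCall:
    """Pattern label plus the inferred role of each regulator."""

    gene: str
    pattern: str  # A-E or 'unresponsive'
    roles: dict[str, str]  # factor -> act | rep | ambiguous

    def __post_init__(self) -> None:
        if self.pattern not in ("A", "B", "C", "D", "E", "unresponsive"):
            raise ValueError(f"invalid pattern {self.pattern!r}")


def sign_sequence(
    gene: str,
    fc: pd.DataFrame,
    specs: list[ComparisonSpec],
) -> SignSequence:
    """Extract a gene's call sequence from the fold-change table.

    Comparisons are taken in ``order_index`` order; a missing (gene,
    comparison) row contributes ``N`` with a warning.
    """
    sub = fc.loc[fc["gene"] == gene]
    by_comparison = dict(zip(sub["comparison_id"], sub["call"]))
    calls = []
    for spec in sorted(specs, key=lambda s: s.order_index):
        if spec.id not in by_comparison:
            log.warning("gene %s has no row for comparison %s; treating as N", gene, spec.id)
            calls.append("N")
        else:
            calls.append(by_comparison[spec.id])
    return SignSequence(gene, tuple(calls))


def role_evidence(call: str, spec: ComparisonSpec) -> tuple[str, str]:
    """One comparison's evidence about the perturbed regulator.

    Up-regulation under loss of a factor means the factor was repressing
    the gene; down-regulation means it was activating it.  ``N`` carries
    no evidence and is rejected here.
    """
    if call == "U":
        return (spec.perturbed_factor, "rep")
    if call == "D":
        return (spec.perturbed_factor, "act")
    raise ValueError("no role evidence from an N call")


def classify(
    seq: SignSequence,
    specs: list[ComparisonSpec],
    factors: tuple[str, str] = ("hsp90", "p23"),
) -> PatternCall:
    """Reduce a call sequence to a pattern label and role map.

    Evidence is gathered comparison by comparison.  A gene is A-D only
    when every call is U or D and each factor's evidence is unanimous;
    any N call or any conflict yields pattern E with the conflicting
    factor(s) marked ambiguous.  All-N sequences are ``unresponsive``.
    A factor never covered by the comparisons stays ambiguous, forcing E.
    """
    ordered = sorted(specs, key=lambda s: s.order_index)
    if len(seq.calls) != len(ordered):
        raise ValueError(
            f"sequence length {len(seq.calls)} != number of comparisons {len(ordered)}"
        )
    evidence: dict[str, set[str]] = {f: set() for f in factors}
    has_n = False
    for call, spec in zip(seq.calls, ordered):
        if call == "N":
            has_n = True
            continue
        factor, role = role_evidence(call, spec)
        evidence.setdefault(factor, set()).add(role)

    if all(call == "N" for call in seq.calls):
        return PatternCall(seq.gene, "unresponsive", {f: "ambiguous" for f in factors})

    roles = {}
    for f in factors:
        ev = evidence.get(f, set())
        roles[f] = next(iter(ev)) if len(ev) == 1 else "ambiguous"

    if has_n or any(r == "ambiguous" for r in roles.values()):
        return PatternCall(seq.gene, "E", roles)
    pattern = PATTERN_LOOKUP[(roles[factors[0]], roles[factors[1]])]
    return PatternCall(seq.gene, pattern, roles)


def classify_all(
    fc: pd.DataFrame,
    specs: list[ComparisonSpec],
    genes: list[str] | None = None,
    factors: tuple[str, str] = ("hsp90", "p23"),
) -> pd.DataFrame:
    """Classify every gene; returns the pattern table.

    Columns: gene, calls (joined sequence), pattern, <factor>_role per
    factor — the layout of a per-gene pattern annotation table.
    """
    if genes is None:
        genes = list(pd.unique(fc["gene"]))
    rows = []
    for gene in genes:
        seq = sign_sequence(gene, fc, specs)
        call = classify(seq, specs, factors)
        row = {"gene": gene, "calls": "".join(seq.calls), "pattern": call.pattern}
        for f in factors:
            row[f"{f}_role"] = call.roles[f]
        rows.append(row)
    return pd.DataFrame(rows)
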