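"""Core domain types shared across the pipeline.

The study design this package targets is a two-factor factorial expression
experiment (e.g. genotype x drug in yeast, wild type vs a p23/Sba1 deletion,
vehicle vs the Hsp90 inhibitor radicicol), profiled with replicates, from
which ordered pairwise contrasts between conditions are analysed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "StudyDesign",
    "ComparisonSpec",
    "Parameters",
    "GeneAnnotation",
    "condition_id",
]


def condition_id(level1: str, level2: str) -> str:
    """Canonical condition identifier for a pair of factor levels."""
    return f"{level1}.{level2}"


@dataclass(frozen=True)
class Parameters:
    """Analysis parameter bundle.

    Attributes
    ----------
    fc_threshold:
        Linear fold-change cutoff for calling a gene up/down in a
        comparison (symmetric: >= fc_threshold or <= 1/fc_threshold).
    p_threshold:
        Raw p-value cutoff accompanying the fold-change filter.
    corr_cutoff:
        Pearson correlation cutoff for coexpression edges.
    corr_mode:
        ``signed`` keeps pairs with r >= cutoff; ``absolute`` keeps
        pairs with \\|r\\| >= cutoff.
    upstream_length:
        Promoter length (nt upstream of the TSS) for motif analysis.
    color_saturation:
        \\|log2 fold change\\| at which the node colour ramp saturates.
    seed:
        Seed for every stochastic step (layout initialisation,
        simulation).
    """

    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    corr_cutoff: float = 0.9
    corr_mode: str = "signed"
    upstream_length: int = 1000
    color_saturation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if not 0 < self.corr_cutoff <= 1:
            raise ValueError(f"corr_cutoff must be in (0, 1], got {self.corr_cutoff}")
        if self.corr_mode not in ("signed", "absolute"):
            raise ValueError(f"corr_mode must be 'signed' or 'absolute', got {self.corr_mode!r}")
        if not self.upstream_length > 0:
            raise ValueError(f"upstream_length must be > 0, got {self.upstream_length}")
        if not self.color_saturation > 0:
            raise ValueError(f"color_saturation must be > 0, got {self.color_saturation}")


class ExpressionMatrix:
    """Log2-scale expression values, genes x samples.

    Values are contractually on the log2 scale; readers offer a flag to
    log-transform linear input on load.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix must be numeric")
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {values.index[r]!r}, sample {values.columns[c]!r}"
            )
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError(f"need at least 2 genes and 2 samples, got shape {values.shape}")
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class StudyDesign:
    """Maps samples to factor levels and replicate indices.

    Parameters
    ----------
    table:
        DataFrame with columns ``sample_id``, the two factor columns and
        ``replicate``.
    factor_names:
        Names of the two factor columns (default ``genotype``/``treatment``).
    """

    def __init__(self, table: pd.DataFrame, factor_names: tuple[str, str] = ("genotype", "treatment")):
        self.factor_names = tuple(factor_names)
        required = ["sample_id", *self.factor_names, "replicate"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"design table missing column(s): {missing}")
        if table["sample_id"].duplicated().any():
            dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample id(s) in design: {dupes}")
        self.table = table.reset_index(drop=True)
        counts = self.table.groupby(list(self.factor_names), sort=False).size()
        # conditions with a single replicate load, but statistics are impossible
        self.single_replicate_conditions = {
            condition_id(*idx) for idx, n in counts.items() if n < 2
        }

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in design")
        f1, f2 = self.factor_names
        return condition_id(row[f1].iloc[0], row[f2].iloc[0])

    def conditions(self) -> list[str]:
        f1, f2 = self.factor_names
        seen: list[str] = []
        for _, row in self.table.iterrows():
            cid = condition_id(row[f1], row[f2])
            if cid not in seen:
                seen.append(cid)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        f1, f2 = self.factor_names
        lv1, lv2 = condition.split(".", 1)
        mask = (self.table[f1] == lv1) & (self.table[f2] == lv2)
        return list(self.table.loc[mask, "sample_id"])

    def factor_levels(self) -> dict[str, list[str]]:
        return {f: list(pd.unique(self.table[f])) for f in self.factor_names}

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Every matrix sample must have exactly one design row and vice versa."""
        design_samples = set(self.sample_ids)
        matrix_samples = set(expr.sample_ids)
        missing = matrix_samples - design_samples
        if missing:
            raise ValueError(f"sample(s) in matrix but absent from design: {sorted(missing)}")
        extra = design_samples - matrix_samples
        if extra:
            raise ValueError(f"sample(s) in design but absent from matrix: {sorted(extra)}")

    def __repr__(self) -> str:
        return (
            f"StudyDesign({len(self.table)} samples, "
            f"factors={self.factor_names}, conditions={len(self.conditions())})"
        )


@dataclass(frozen=True)
class ComparisonSpec:
    """An ordered pairwise contrast between two conditions.

    ``perturbed_factor`` names the regulator whose function is lost in the
    numerator relative to the denominator; it drives the activator/repressor
    role inference.  ``order_index`` is the position of this comparison in
    the animation.
    """

    id: str
    numerator: str
    denominator: str
    perturbed_factor: str
    order_index: int

    def __post_init__(self) -> None:
        num = self.numerator.split(".")
        den = self.denominator.split(".")
        if len(num) != len(den):
            raise ValueError(f"comparison {self.id}: malformed condition ids")
        n_diff = sum(a != b for a, b in zip(num, den))
        if n_diff != 1:
            raise ValueError(
                f"comparison {self.id}: {self.numerator} vs {self.denominator} "
                f"must differ in exactly one factor level (differ in {n_diff})"
            )


def canonical_comparisons(
    wt: str = "WT",
    mutant: str = "d_p23",
    vehicle: str = "vehicle",
    drug: str = "hsp90i",
) -> list[ComparisonSpec]:
    """The default four pairwise contrasts of the 2x2 design, in animation order.

    c1 compares the p23 deletion to wild type (p23 lost), c2 the inhibitor to
    vehicle in wild type (Hsp90 lost), c3 the combined perturbation to the
    deletion alone (Hsp90 lost), c4 the combined perturbation to the inhibitor
    alone (p23 lost).  This ordering renders the pattern-A colour string
    red, green, green, red consistent with Hsp90-activator / p23-repressor
    roles.  Fully overridable via a comparisons file.
    """
    return [
        ComparisonSpec("c1", condition_id(mutant, vehicle), condition_id(wt, vehicle), "p23", 0),
        ComparisonSpec("c2", condition_id(wt, drug), condition_id(wt, vehicle), "hsp90", 1),
        ComparisonSpec("c3", condition_id(mutant, drug), condition_id(mutant, vehicle), "hsp90", 2),
        ComparisonSpec("c4", condition_id(mutant, drug), condition_id(wt, drug), "p23", 3),
    ]


#: default mapping of common GO cellular-component labels onto the layer vocabulary
DEFAULT_COMPARTMENT_SYNONYMS: dict[str, str] = {
    "extracellular region": "extracellular",
    "extracellular space": "extracellular",
    "GO:0005576": "extracellular",
    "cell wall": "extracellular",
    "plasma membrane": "plasma membrane",
    "GO:0005886": "plasma membrane",
    "cell periphery": "plasma membrane",
    "cytoplasm": "cytoplasm",
    "cytosol": "cytoplasm",
    "GO:0005737": "cytoplasm",
    "GO:0005829": "cytoplasm",
    "ribosome": "cytoplasm",
    "mitochondrion": "mitochondrion",
    "GO:0005739": "mitochondrion",
    "mitochondrial matrix": "mitochondrion",
    "endoplasmic reticulum": "ER/Golgi",
    "GO:0005783": "ER/Golgi",
    "golgi apparatus": "ER/Golgi",
    "Golgi apparatus": "ER/Golgi",
    "GO:0005794": "ER/Golgi",
    "vacuole": "ER/Golgi",
    "nucleus": "nucleus",
    "GO:0005634": "nucleus",
    "nucleolus": "nucleus",
    "chromatin": "nucleus",
}


class GeneAnnotation:
    """Gene -> set of intracellular compartment labels.

    Unannotated genes resolve lazily to ``{"unknown"}``.  Labels outside the
    layer vocabulary are passed through a synonym table; still-unrecognised
    labels are recorded in :attr:`unrecognized` and mapped to ``unknown``.
    """

    def __init__(
        self,
        mapping: dict[str, set[str]] | None = None,
        synonyms: dict[str, str] | None = None,
        vocabulary: set[str] | None = None,
    ):
        from .layout import DEFAULT_LAYERS  # deferred: avoid cycle

        self.synonyms = dict(DEFAULT_COMPARTMENT_SYNONYMS if synonyms is None else synonyms)
        self.vocabulary = set(DEFAULT_LAYERS if vocabulary is None else vocabulary)
        self.unrecognized: set[str] = set()
        self._map: dict[str, set[str]] = {}
        for gene, comps in (mapping or {}).items():
            for c in comps:
                self.add(gene, c)

    def add(self, gene: str, compartment: str) -> None:
        label = self.synonyms.get(compartment, compartment)
        if label not in self.vocabulary:
            self.unrecognized.add(compartment)
            label = "unknown"
        self._map.setdefault(gene, set()).add(label)

    def compartments(self, gene: str) -> set[str]:
        return self._map.get(gene, {"unknown"})

    def genes(self) -> list[str]:
        return sorted(self._map)

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    def __repr__(self) -> str:
        return f"GeneAnnotation({len(self._map)} genes)"
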