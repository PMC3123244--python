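"""Synthetic factorial study generator with known ground truth.

Emulates the shape of a 2x2 genotype x drug yeast expression study (four
conditions, triplicate arrays): genes are planted in the regulatory
patterns A-E (plus unresponsive), with condition means constructed so
that the canonical pairwise comparisons reproduce each pattern's intended
up/down string, Gaussian replicate noise on top, PPI cliques within
same-pattern modules plus a sparse random background, compartment labels
drawn per pattern group, and promoter sequences with a stress-element
style motif planted in flagged genes.  Every stage of the pipeline is
testable against the returned truth table with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ComparisonSpec,
    ExpressionMatrix,
    GeneAnnotation,
    StudyDesign,
    canonical_comparisons,
    condition_id,
)

__all__ = ["SyntheticConfig", "SyntheticStudy", "simulate_study", "recovery_report", "write_study"]

# intended U/D string per pattern under the canonical comparison order
PATTERN_SIGNS: dict[str, tuple[int, int, int, int]] = {
    # order: c1 (p23 lost), c2 (hsp90 lost), c3 (hsp90 lost), c4 (p23 lost)
    "A": (+1, -1, -1, +1),  # hsp90 activator, p23 repressor: red green green red
    "B": (-1, +1, +1, -1),  # hsp90 repressor, p23 activator
    "C": (+1, +1, +1, +1),  # both repressors: all red
    "D": (-1, -1, -1, -1),  # both activators: all green
}

#: compartment sampling weights per pattern group (loosely: iron/ion genes
#: at the membrane and cytoplasm, respiration in mitochondria, stress
#: response cytoplasmic/nuclear, protein import mitochondrial)
COMPARTMENT_WEIGHTS: dict[str, dict[str, float]] = {
    "A": {"plasma membrane": 0.4, "cytoplasm": 0.3, "nucleus": 0.3},
    "B": {"mitochondrion": 0.5, "nucleus": 0.3, "cytoplasm": 0.2},
    "C": {"cytoplasm": 0.5, "nucleus": 0.4, "extracellular": 0.1},
    "D": {"mitochondrion": 0.6, "cytoplasm": 0.4},
    "E": {"cytoplasm": 0.3, "nucleus": 0.3, "mitochondrion": 0.2, "ER/Golgi": 0.2},
    "unresponsive": {"cytoplasm": 0.4, "nucleus": 0.3, "ER/Golgi": 0.3},
}

# stress-response-element-like consensus planted in flagged promoters
PLANTED_MOTIF_CONSENSUS = "AAGGGGCG"
PROMOTER_BASE_FREQS = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}  # yeast-like AT-rich


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults: 50 genes per pattern class, effect size 2 log2 units
    (4-fold, comfortably past the 1.5-fold calling threshold), replicate
    noise SD 0.25 log2 units, triplicates — the regime where an
    expression change of this size is essentially always detectable, as
    in a clean microarray experiment.
    """

    genes_per_pattern: dict[str, int] = field(
        default_factory=lambda: {
            "A": 50, "B": 50, "C": 50, "D": 50, "E": 50, "unresponsive": 50,
        }
    )
    effect_size: float = 2.0  # delta, log2 units
    noise_sd: float = 0.25  # sigma, log2 units
    replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    module_size: int = 5  # PPI clique size within a pattern group
    background_edge_p: float = 0.01
    promoter_length: int = 1000
    n_decoy_motifs: int = 4
    motif_pattern: str = "C"  # flagged (motif-planted) genes: up under every perturbation

    def __post_init__(self) -> None:
        if self.effect_size <= 0 or self.noise_sd <= 0:
            raise ValueError("effect_size and noise_sd must be > 0")
        if any(n < 0 for n in self.genes_per_pattern.values()):
            raise ValueError("gene counts must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for statistics")


@dataclass
class SyntheticStudy:
    """A generated study plus its ground truth."""

    expr: ExpressionMatrix
    design: StudyDesign
    truth: pd.DataFrame  # gene, pattern, module, motif_planted, signs
    interactions: list[tuple[str, str, str]]
    annotation: GeneAnnotation
    promoters: dict[str, str]
    motif_meme: str  # MEME minimal text: planted motif + decoys
    comparisons: list[ComparisonSpec]


def _condition_means_for_signs(
    signs: tuple[int, int, int, int] | None,
    baseline: float,
    delta: float,
) -> tuple[float, float, float, float] | None:
    """Condition means (WT.veh, d_p23.veh, WT.drug, d_p23.drug) realising a sign string.

    The four canonical contrasts telescope (d1 + d3 == d2 + d4), so for
    consistent patterns equal magnitudes work directly; ``None`` signs
    mean no effect.
    """
    if signs is None:
        return (baseline,) * 4
    d1, d2, d3, _ = (s * delta for s in signs)
    return (baseline, baseline + d1, baseline + d2, baseline + d1 + d3)


def _e_pattern_signs(rng: np.random.Generator, delta: float) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """An inconsistent sign string with realisable magnitudes.

    Start from a consistent pattern, flip one comparison, then search a
    small grid of magnitude multiples for d1, d2, d3 such that the implied
    d4 = d1 + d3 - d2 has the flipped string's sign and |d4| >= delta.
    Single-flip strings are always realisable (the two unrealisable
    alternating strings differ from every consistent pattern in >= 2
    positions).
    """
    base = PATTERN_SIGNS[("A", "B", "C", "D")[rng.integers(4)]]
    flip = int(rng.integers(4))
    target = tuple(-s if i == flip else s for i, s in enumerate(base))
    for m1 in (1, 2, 3):
        for m2 in (1, 2, 3):
            for m3 in (1, 2, 3):
                d1 = target[0] * m1 * delta
                d2 = target[1] * m2 * delta
                d3 = target[2] * m3 * delta
                d4 = d1 + d3 - d2
                if np.sign(d4) == target[3] and abs(d4) >= delta:
                    return target, (d1, d2, d3, d4)
    raise RuntimeError("unreachable: single-flip sign string not realisable")


def simulate_study(
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a complete study with planted ground truth.

    Per gene: baseline ~ Normal(8, 1) log2 units; condition means shifted
    by ±delta so the canonical comparisons yield the planted pattern's
    U/D string (E genes get one contradictory shift with magnitudes
    solved so the four contrasts stay mutually consistent); replicate
    noise Normal(0, sigma).  Deterministic for a fixed seed.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    delta, sigma, r = config.effect_size, config.noise_sd, config.replicates

    genes: list[str] = []
    truth_rows = []
    cond_means: dict[str, tuple[float, float, float, float]] = {}
    idx = 0
    for pattern in ("A", "B", "C", "D", "E", "unresponsive"):
        for _ in range(config.genes_per_pattern.get(pattern, 0)):
            gene = f"G{idx:04d}"
            idx += 1
            baseline = float(rng.normal(config.baseline_mean, config.baseline_sd))
            if pattern in PATTERN_SIGNS:
                signs = PATTERN_SIGNS[pattern]
                means = _condition_means_for_signs(signs, baseline, delta)
            elif pattern == "E":
                signs, (d1, d2, d3, _) = _e_pattern_signs(rng, delta)
                means = (baseline, baseline + d1, baseline + d2, baseline + d1 + d3)
            else:
                signs = (0, 0, 0, 0)
                means = _condition_means_for_signs(None, baseline, delta)
            genes.append(gene)
            cond_means[gene] = means
            truth_rows.append(
                {
                    "gene": gene,
                    "pattern": pattern,
                    "signs": "".join({1: "U", -1: "D", 0: "N"}[s] for s in signs),
                    "motif_planted": pattern == config.motif_pattern,
                }
            )
    if len(genes) < 2:
        raise ValueError("need at least 2 genes in total")

    conditions = [
        condition_id("WT", "vehicle"),
        condition_id("d_p23", "vehicle"),
        condition_id("WT", "hsp90i"),
        condition_id("d_p23", "hsp90i"),
    ]
    sample_rows = []
    data = {}
    for ci, cond in enumerate(conditions):
        geno, treat = cond.split(".")
        for rep in range(1, r + 1):
            sid = f"{geno}_{treat}_r{rep}"
            sample_rows.append(
                {"sample_id": sid, "genotype": geno, "treatment": treat, "replicate": rep}
            )
            noise = rng.normal(0.0, sigma, size=len(genes))
            data[sid] = np.array([cond_means[g][ci] for g in genes]) + noise
    expr = ExpressionMatrix(pd.DataFrame(data, index=genes))
    design = StudyDesign(pd.DataFrame(sample_rows))
    truth = pd.DataFrame(truth_rows)

    # PPI: cliques of module_size within each pattern group + random background
    interactions: list[tuple[str, str, str]] = []
    module_of: dict[str, int] = {}
    module_id = 0
    for pattern, sub in truth.groupby("pattern", sort=False):
        members = list(sub["gene"])
        for start in range(0, len(members), config.module_size):
            module = members[start : start + config.module_size]
            module_id += 1
            for g in module:
                module_of[g] = module_id
            for i in range(len(module)):
                for j in range(i + 1, len(module)):
                    interactions.append((module[i], module[j], "synthetic"))
    n = len(genes)
    background_pairs = rng.random((n, n)) < config.background_edge_p
    for i in range(n):
        for j in range(i + 1, n):
            if background_pairs[i, j] and module_of.get(genes[i]) != module_of.get(genes[j]):
                interactions.append((genes[i], genes[j], "synthetic"))
    truth["module"] = truth["gene"].map(module_of).fillna(0).astype(int)

    # localization sampled per pattern group
    annotation = GeneAnnotation()
    for row in truth.itertuples():
        weights = COMPARTMENT_WEIGHTS[row.pattern]
        comps = list(weights)
        p = np.array(list(weights.values()))
        annotation.add(row.gene, comps[rng.choice(len(comps), p=p / p.sum())])

    # promoters: iid background with the motif planted once in flagged genes
    bases = np.array(list("ACGT"))
    freqs = np.array([PROMOTER_BASE_FREQS[b] for b in "ACGT"])
    promoters = {}
    motif = PLANTED_MOTIF_CONSENSUS
    for row in truth.itertuples():
        seq = "".join(rng.choice(bases, size=config.promoter_length, p=freqs))
        if row.motif_planted:
            pos = int(rng.integers(0, config.promoter_length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        promoters[row.gene] = seq
    motif_meme = _meme_text(rng, config.n_decoy_motifs)

    return SyntheticStudy(
        expr=expr,
        design=design,
        truth=truth,
        interactions=interactions,
        annotation=annotation,
        promoters=promoters,
        motif_meme=motif_meme,
        comparisons=canonical_comparisons(),
    )


def _meme_text(rng: np.random.Generator, n_decoys: int) -> str:
    """MEME minimal text for the planted motif plus random decoy PWMs."""
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "Background letter frequencies",
        "A 0.31 C 0.19 G 0.19 T 0.31", "",
    ]

    def add(name: str, rows: list[list[float]]) -> None:
        lines.append(f"MOTIF {name}")
        lines.append(f"letter-probability matrix: alength= 4 w= {len(rows)} nsites= 20 E= 0")
        for row in rows:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")

    planted_rows = []
    for base in PLANTED_MOTIF_CONSENSUS:
        row = [0.02, 0.02, 0.02, 0.02]
        row["ACGT".index(base)] = 0.94
        planted_rows.append(row)
    add("planted_STRE_like", planted_rows)
    for d in range(n_decoys):
        w = int(rng.integers(6, 10))
        rows = []
        for _ in range(w):
            raw = rng.dirichlet([0.8, 0.8, 0.8, 0.8])
            rows.append(list(raw))
        add(f"decoy_{d + 1}", rows)
    return "\n".join(lines)


def recovery_report(truth: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Confusion matrix and per-pattern sensitivity/precision.

    ``calls`` is the classifier output table (columns gene, pattern).  A
    gene in ``calls`` missing from the truth table is an error.
    """
    labels = ["A", "B", "C", "D", "E", "unresponsive"]
    truth_map = dict(zip(truth["gene"], truth["pattern"]))
    unknown = [g for g in calls["gene"] if g not in truth_map]
    if unknown:
        raise ValueError(f"gene(s) in calls but not in truth: {unknown[:5]}")
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    for row in calls.itertuples():
        confusion.loc[truth_map[row.gene], row.pattern] += 1
    sensitivity = {}
    precision = {}
    for lab in labels:
        planted = confusion.loc[lab].sum()
        called = confusion[lab].sum()
        correct = confusion.loc[lab, lab]
        sensitivity[lab] = float(correct / planted) if planted else float("nan")
        precision[lab] = float(correct / called) if called else float("nan")
    return {"confusion": confusion, "sensitivity": sensitivity, "precision": precision}


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study in the exact file formats the readers consume."""
    from .io import write_comparisons

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
        "interactions": out / "interactions.sif",
        "localization": out / "localization.tsv",
        "promoters_fg": out / "promoters_foreground.fasta",
        "promoters_bg": out / "promoters_background.fasta",
        "motifs": out / "motifs.meme",
        "comparisons": out / "comparisons.tsv",
        "truth": out / "truth.tsv",
    }
    study.expr.values.rename_axis("gene").to_csv(paths["expression"], sep="\t")
    study.design.table.to_csv(paths["design"], sep="\t", index=False)
    with open(paths["interactions"], "w", encoding="utf-8") as fh:
        for a, b, _tag in study.interactions:
            fh.write(f"{a}\tpp\t{b}\n")
    with open(paths["localization"], "w", encoding="utf-8") as fh:
        for gene in study.annotation.genes():
            for comp in sorted(study.annotation.compartments(gene)):
                fh.write(f"{gene}\t{comp}\n")
    flagged = set(study.truth.loc[study.truth["motif_planted"], "gene"])
    with open(paths["promoters_fg"], "w", encoding="utf-8") as fh:
        for gene, seq in study.promoters.items():
            if gene in flagged:
                fh.write(f">{gene}\n{seq}\n")
    with open(paths["promoters_bg"], "w", encoding="utf-8") as fh:
        for gene, seq in study.promoters.items():
            fh.write(f">{gene}\n{seq}\n")
    paths["motifs"].write_text(study.motif_meme, encoding="utf-8")
    write_comparisons(study.comparisons, paths["comparisons"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
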