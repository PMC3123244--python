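"""Per-gene statistics over the factorial design.

Two layers of filtering are supported, mirroring common microarray practice:
a per-gene two-way ANOVA over the full 2x2xr design, and per-comparison
volcano statistics (linear fold change + Welch t-test on log2 replicate
values).  A gene is called up (``U``) in a comparison when its linear fold
change is at least ``fc_threshold`` and its p-value below ``p_threshold``,
down (``D``) for the reciprocal threshold, else no-change (``N``).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st

from .core import ComparisonSpec, ExpressionMatrix, Parameters, StudyDesign

log = logging.getLogger(__name__)

__all__ = [
    "condition_means",
    "pairwise_comparison",
    "fold_change_table",
    "two_way_anova",
    "select_responsive",
]

# tolerance on the log2 scale so the inclusive FC boundary (FC == threshold
# passes) survives float round-trip through 2**log2(threshold)
_LOG2_TOL = 1e-9


def condition_means(expr: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    """Mean log2 value per (gene, condition), averaging over replicates."""
    cols = {}
    for cond in design.conditions():
        samples = design.samples_for(cond)
        if len(samples) == 1:
            log.warning("condition %s has a single replicate", cond)
        cols[cond] = expr.values[samples].mean(axis=1)
    return pd.DataFrame(cols, index=expr.values.index)


def _calls(log2fc: np.ndarray, p: np.ndarray, params: Parameters) -> np.ndarray:
    thr = np.log2(params.fc_threshold) - _LOG2_TOL
    sig = p < params.p_threshold  # NaN p compares False -> N
    calls = np.full(log2fc.shape, "N", dtype=object)
    calls[(log2fc >= thr) & sig] = "U"
    calls[(log2fc <= -thr) & sig] = "D"
    return calls


def pairwise_comparison(
    expr: ExpressionMatrix,
    design: StudyDesign,
    spec: ComparisonSpec,
    params: Parameters | None = None,
    test: str = "student",
) -> pd.DataFrame:
    """Volcano statistics for one contrast: per gene FC, log2fc, t-test p, call.

    log2fc is mean(numerator) - mean(denominator) on the log2 scale; the
    p-value comes from a two-sample t-test on the log2 replicate values —
    pooled-variance Student's t by default (exactly calibrated under the
    null for the balanced replicate groups this design yields; Welch's
    Satterthwaite approximation is visibly miscalibrated at triplicate
    scale), or Welch's unequal-variance test with ``test="welch"``.
    Conditions with fewer than two replicates yield absent p-values and
    hence call ``N`` (conservative).
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r} (use 'student' or 'welch')")
    params = params or Parameters()
    num_samples = design.samples_for(spec.numerator)
    den_samples = design.samples_for(spec.denominator)
    if not num_samples:
        raise ValueError(f"comparison {spec.id}: condition {spec.numerator!r} has no samples")
    if not den_samples:
        raise ValueError(f"comparison {spec.id}: condition {spec.denominator!r} has no samples")
    num = expr.values[num_samples].to_numpy()
    den = expr.values[den_samples].to_numpy()
    log2fc = num.mean(axis=1) - den.mean(axis=1)
    if len(num_samples) >= 2 and len(den_samples) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance genes
            _, p = st.ttest_ind(num, den, axis=1, equal_var=(test == "student"))
        p = np.asarray(p, dtype=float)
        # identical zero-variance groups: no evidence of change
        same = np.isnan(p) & np.isclose(log2fc, 0.0)
        p[same] = 1.0
    else:
        p = np.full(log2fc.shape, np.nan)
    return pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "comparison_id": spec.id,
            "fc_linear": np.exp2(log2fc),
            "log2fc": log2fc,
            "p": p,
            "call": _calls(log2fc, p, params),
        }
    )


def fold_change_table(
    expr: ExpressionMatrix,
    design: StudyDesign,
    specs: list[ComparisonSpec],
    params: Parameters | None = None,
    test: str = "student",
) -> pd.DataFrame:
    """Stacked :func:`pairwise_comparison` rows over all comparisons."""
    frames = [
        pairwise_comparison(expr, design, s, params, test)
        for s in sorted(specs, key=lambda s: s.order_index)
    ]
    return pd.concat(frames, ignore_index=True)


def two_way_anova(expr: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    """Classical two-way ANOVA per gene over the balanced 2x2xr design.

    Returns per gene the F statistic and p-value for each main effect and
    the interaction, plus the residual degrees of freedom.  The sum-of-
    squares decomposition is the textbook one for a balanced layout
    (Type I = Type III there); F ratios are taken against the residual
    mean square.  Genes with zero residual variance get p = 0 for effects
    with nonzero SS and p = 1 otherwise, with a logged warning.

    Unbalanced designs are rejected with a pointer to pairwise mode.
    """
    f1, f2 = design.factor_names
    levels = design.factor_levels()
    if len(levels[f1]) != 2 or len(levels[f2]) != 2:
        raise ValueError("two_way_anova requires a 2x2 design")
    cells = {}
    r = None
    for a in levels[f1]:
        for b in levels[f2]:
            mask = (design.table[f1] == a) & (design.table[f2] == b)
            samples = list(design.table.loc[mask, "sample_id"])
            if r is None:
                r = len(samples)
            elif len(samples) != r:
                raise ValueError(
                    "unbalanced design: unequal replicates per cell; "
                    "use pairwise comparisons instead"
                )
            cells[(a, b)] = expr.values[samples].to_numpy()
    if r < 2:
        raise ValueError("two_way_anova needs >= 2 replicates per cell")

    # genes x 2 x 2 x r
    data = np.stack(
        [np.stack([cells[(a, b)] for b in levels[f2]], axis=1) for a in levels[f1]],
        axis=1,
    )
    grand = data.mean(axis=(1, 2, 3))
    mean_a = data.mean(axis=(2, 3))          # genes x 2
    mean_b = data.mean(axis=(1, 3))          # genes x 2
    mean_cell = data.mean(axis=3)            # genes x 2 x 2

    n_per_a = 2 * r
    ss_a = n_per_a * ((mean_a - grand[:, None]) ** 2).sum(axis=1)
    ss_b = n_per_a * ((mean_b - grand[:, None]) ** 2).sum(axis=1)
    inter = (
        mean_cell
        - mean_a[:, :, None]
        - mean_b[:, None, :]
        + grand[:, None, None]
    )
    ss_ab = r * (inter ** 2).sum(axis=(1, 2))
    ss_res = ((data - mean_cell[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))

    df_effect = 1
    df_res = 4 * (r - 1)
    ms_res = ss_res / df_res

    def f_and_p(ss_effect: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_effect / df_effect) / ms_res
        p = st.f.sf(F, df_effect, df_res)
        degenerate = ms_res == 0
        if degenerate.any():
            F = F.copy()
            p = p.copy()
            nonzero = degenerate & (ss_effect > 0)
            zero = degenerate & (ss_effect == 0)
            F[degenerate] = np.inf
            F[zero] = 0.0
            p[nonzero] = 0.0
            p[zero] = 1.0
        return F, p

    degenerate_genes = int((ms_res == 0).sum())
    if degenerate_genes:
        log.warning("%d gene(s) with zero residual variance in ANOVA", degenerate_genes)

    F_a, p_a = f_and_p(ss_a)
    F_b, p_b = f_and_p(ss_b)
    F_ab, p_ab = f_and_p(ss_ab)
    return pd.DataFrame(
        {
            f"F_{f1}": F_a, f"p_{f1}": p_a,
            f"F_{f2}": F_b, f"p_{f2}": p_b,
            "F_interaction": F_ab, "p_interaction": p_ab,
            "df_residual": df_res,
        },
        index=expr.values.index,
    )


def select_responsive(
    fc: pd.DataFrame,
    params: Parameters | None = None,
    anova: pd.DataFrame | None = None,
    anova_p_threshold: float | None = None,
) -> set[str]:
    """Genes called U or D in at least one comparison.

    The fold-change and p gates are those already baked into the calls.
    Optionally, an ANOVA gate can additionally be applied: with ``anova``
    given, a gene must also have at least one ANOVA effect p below
    ``anova_p_threshold`` (default: the pairwise p threshold).  Both gates
    are independently switchable since common practice varies.
    """
    params = params or Parameters()
    hit = set(fc.loc[fc["call"].isin(["U", "D"]), "gene"])
    if anova is not None:
        thr = params.p_threshold if anova_p_threshold is None else anova_p_threshold
        p_cols = [c for c in anova.columns if c.startswith("p_")]
        keep = anova.index[(anova[p_cols] < thr).any(axis=1)]
        hit &= set(keep)
    return hit


def write_fold_change_table(fc: pd.DataFrame, path) -> None:
    """TSV export: gene, comparison_id, fc_linear, log2fc, p, call."""
    fc.to_csv(path, sep="\t", index=False)
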