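"""Differential-expression statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

from netanim.core import ComparisonSpec, Parameters
from netanim.diffexpr import (
    condition_means,
    fold_change_table,
    pairwise_comparison,
    select_responsive,
    two_way_anova,
)

from conftest import make_design, make_matrix


def welch_p_oracle(a, b):
    """Welch two-sided p via the t statistic and the regularized incomplete beta.

    Independent of the implementation path: explicit moment arithmetic and
    the identity  P(|T| > t) = I_{nu/(nu+t^2)}(nu/2, 1/2).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    nu = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return betainc(nu / 2.0, 0.5, nu / (nu + t * t))


def anova_oracle(cells):
    """Two-way ANOVA F statistics by explicit mean/SS arithmetic.

    ``cells[(i, j)]`` holds the replicate values of factor-level cell (i, j).
    """
    r = len(next(iter(cells.values())))
    all_values = [v for vals in cells.values() for v in vals]
    grand = sum(all_values) / len(all_values)
    mean_a = {i: sum(v for (ii, _), vals in cells.items() if ii == i for v in vals) / (2 * r) for i in (0, 1)}
    mean_b = {j: sum(v for (_, jj), vals in cells.items() if jj == j for v in vals) / (2 * r) for j in (0, 1)}
    mean_cell = {k: sum(vals) / r for k, vals in cells.items()}
    ss_a = 2 * r * sum((mean_a[i] - grand) ** 2 for i in (0, 1))
    ss_b = 2 * r * sum((mean_b[j] - grand) ** 2 for j in (0, 1))
    ss_ab = r * sum(
        (mean_cell[(i, j)] - mean_a[i] - mean_b[j] + grand) ** 2 for i in (0, 1) for j in (0, 1)
    )
    ss_res = sum((v - mean_cell[k]) ** 2 for k, vals in cells.items() for v in vals)
    ms_res = ss_res / (4 * (r - 1))
    return ss_a / ms_res, ss_b / ms_res, ss_ab / ms_res


class TestConditionMeans:
    @pytest.mark.parametrize(
        "replicate_values, expected",
        [((4.0, 4.0, 4.0), 4.0), ((3.0, 5.0, 4.0), 4.0)],
    )
    def test_mean_over_replicates(self, design3, replicate_values, expected):
        values = np.ones((2, 12))
        values[0, :3] = replicate_values  # first condition of the first gene
        expr = make_matrix(design3, values)
        means = condition_means(expr, design3)
        first_cond = design3.conditions()[0]
        assert means.loc["g0", first_cond] == pytest.approx(expected)


class TestPairwiseComparison:
    def spec(self):
        return ComparisonSpec("c2", "WT.hsp90i", "WT.vehicle", "hsp90", 1)

    def test_identical_groups_give_unit_fc_and_n_call(self, design3):
        expr = make_matrix(design3, np.full((2, 12), 5.0))
        rows = pairwise_comparison(expr, design3, self.spec())
        assert (rows["fc_linear"] == 1.0).all()
        assert (rows["log2fc"] == 0.0).all()
        assert (rows["call"] == "N").all()

    def test_one_log2_unit_shift_is_twofold_up(self, design3):
        values = np.full((2, 12), 2.0)
        cols = [design3.sample_ids.index(s) for s in design3.samples_for("WT.hsp90i")]
        values[0, cols] = [3.0 - 0.01, 3.0, 3.0 + 0.01]  # tight triplicate around 3
        expr = make_matrix(design3, values)
        rows = pairwise_comparison(expr, design3, self.spec()).set_index("gene")
        assert rows.loc["g0", "fc_linear"] == pytest.approx(2.0)
        assert rows.loc["g0", "p"] < 0.05
        assert rows.loc["g0", "call"] == "U"

    def test_welch_p_matches_incomplete_beta_oracle(self, design3):
        num, den = [5.1, 5.3, 4.9], [4.0, 4.2, 3.8]
        values = np.full((2, 12), 4.0)
        num_cols = [design3.sample_ids.index(s) for s in design3.samples_for("WT.hsp90i")]
        den_cols = [design3.sample_ids.index(s) for s in design3.samples_for("WT.vehicle")]
        values[0, num_cols] = num
        values[0, den_cols] = den
        expr = make_matrix(design3, values)
        rows = pairwise_comparison(expr, design3, self.spec(), test="welch").set_index("gene")
        assert rows.loc["g0", "p"] == pytest.approx(welch_p_oracle(num, den), abs=1e-9)

    def test_welch_p_matches_oracle_on_random_instances(self, design3):
        rng = np.random.default_rng(1)
        values = rng.normal(8, 1, size=(40, 12))
        expr = make_matrix(design3, values)
        rows = pairwise_comparison(expr, design3, self.spec(), test="welch")
        num_cols = [design3.sample_ids.index(s) for s in design3.samples_for("WT.hsp90i")]
        den_cols = [design3.sample_ids.index(s) for s in design3.samples_for("WT.vehicle")]
        for i, p in enumerate(rows["p"]):
            assert p == pytest.approx(welch_p_oracle(values[i, num_cols], values[i, den_cols]), abs=1e-9)

    def test_default_null_pvalues_are_uniform(self, design3):
        """Under a no-effect simulation the default test's p-values are uniform."""
        import scipy.stats as st

        rng = np.random.default_rng(7)
        expr = make_matrix(design3, rng.normal(8, 1, size=(1500, 12)))
        rows = pairwise_comparison(expr, design3, self.spec())
        assert st.kstest(rows["p"], "uniform").pvalue > 0.01

    def test_antisymmetry_under_contrast_swap(self, design3):
        rng = np.random.default_rng(2)
        expr = make_matrix(design3, rng.normal(8, 1, size=(30, 12)))
        fwd = pairwise_comparison(expr, design3, self.spec())
        rev = pairwise_comparison(
            expr, design3, ComparisonSpec("c2r", "WT.vehicle", "WT.hsp90i", "hsp90", 1)
        )
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        swap = {"U": "D", "D": "U", "N": "N"}
        assert [swap[c] for c in fwd["call"]] == list(rev["call"])

    def test_missing_condition_is_error(self, design3):
        expr = make_matrix(design3, np.full((2, 12), 1.0))
        bad = ComparisonSpec("cx", "WT.other", "WT.vehicle", "hsp90", 0)
        with pytest.raises(ValueError, match="WT.other"):
            pairwise_comparison(expr, design3, bad)

    def test_single_replicate_gives_absent_p_and_n_call(self):
        design = make_design(3)
        table = design.table[~((design.table["genotype"] == "WT")
                               & (design.table["treatment"] == "hsp90i")
                               & (design.table["replicate"] > 1))]
        from netanim.core import StudyDesign

        design1 = StudyDesign(table)
        values = np.full((2, len(design1.table)), 2.0)
        cols = [design1.sample_ids.index(s) for s in design1.samples_for("WT.hsp90i")]
        values[0, cols] = 10.0  # huge shift, but unsupported by replication
        expr = make_matrix(design1, values)
        rows = pairwise_comparison(expr, design1, self.spec()).set_index("gene")
        assert np.isnan(rows.loc["g0", "p"])
        assert rows.loc["g0", "call"] == "N"


class TestTwoWayAnova:
    def test_constant_data_gives_zero_f_unit_p(self, design3):
        expr = make_matrix(design3, np.full((2, 12), 3.0))
        res = two_way_anova(expr, design3)
        assert (res["F_genotype"] == 0).all()
        assert (res[["p_genotype", "p_treatment", "p_interaction"]] == 1).all().all()

    def test_f_matches_brute_force_decomposition(self, design3):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, size=(25, 12))
        expr = make_matrix(design3, values)
        res = two_way_anova(expr, design3)
        f1, f2 = design3.factor_names
        levels = design3.factor_levels()
        for g in range(25):
            cells = {}
            for i, la in enumerate(levels[f1]):
                for j, lb in enumerate(levels[f2]):
                    mask = (design3.table[f1] == la) & (design3.table[f2] == lb)
                    samples = design3.table.loc[mask, "sample_id"]
                    cols = [design3.sample_ids.index(s) for s in samples]
                    cells[(i, j)] = list(values[g, cols])
            fa, fb, fab = anova_oracle(cells)
            assert res["F_genotype"].iloc[g] == pytest.approx(fa, abs=1e-9)
            assert res["F_treatment"].iloc[g] == pytest.approx(fb, abs=1e-9)
            assert res["F_interaction"].iloc[g] == pytest.approx(fab, abs=1e-9)

    def test_planted_main_effect_detected(self, design3):
        """A factor-1 shift of 10 noise SDs is detected in >=99% of genes."""
        rng = np.random.default_rng(1)
        n = 1000
        values = rng.normal(0, 1, size=(n, 12))
        mutant_cols = [i for i, s in enumerate(design3.sample_ids) if s.startswith("d_p23")]
        values[:, mutant_cols] += 10.0
        expr = make_matrix(design3, values)
        res = two_way_anova(expr, design3)
        assert (res["p_genotype"] < 1e-3).mean() >= 0.99

    def test_unbalanced_design_rejected(self, design3):
        from netanim.core import StudyDesign

        table = design3.table.drop(index=0)
        design = StudyDesign(table)
        expr = make_matrix(design3, np.ones((2, 12)))
        with pytest.raises(ValueError, match="pairwise"):
            two_way_anova(expr, design)

    def test_degrees_of_freedom(self, design3):
        expr = make_matrix(design3, np.random.default_rng(0).normal(size=(3, 12)))
        res = two_way_anova(expr, design3)
        assert (res["df_residual"] == 8).all()  # 4 cells x (3 - 1)


class TestSelectResponsive:
    def _fc(self, design3, fcs):
        """One comparison; genes with given linear fold changes, tiny noise."""
        values = np.full((len(fcs) + 1, 12), 8.0)  # plus a flat dummy gene
        num_cols = [design3.sample_ids.index(s) for s in design3.samples_for("WT.hsp90i")]
        for i, f in enumerate(fcs):
            values[i, num_cols] += np.log2(f) + np.array([-1e-4, 0, 1e-4])
        expr = make_matrix(design3, values)
        spec = ComparisonSpec("c2", "WT.hsp90i", "WT.vehicle", "hsp90", 1)
        return pairwise_comparison(expr, design3, spec)

    def test_boundary_fold_change_is_inclusive(self, design3):
        fc = self._fc(design3, [1.5])
        assert select_responsive(fc) == {"g0"}

    def test_below_threshold_excluded(self, design3):
        fc = self._fc(design3, [1.49])
        assert select_responsive(fc) == set()

    def test_monotone_in_fc_threshold(self, design3):
        rng = np.random.default_rng(1)
        expr = make_matrix(design3, rng.normal(8, 1.5, size=(60, 12)))
        spec = ComparisonSpec("c2", "WT.hsp90i", "WT.vehicle", "hsp90", 1)
        loose = pairwise_comparison(expr, design3, spec, Parameters(fc_threshold=1.5))
        strict = pairwise_comparison(expr, design3, spec, Parameters(fc_threshold=2.0))
        assert select_responsive(strict, Parameters(fc_threshold=2.0)) <= select_responsive(
            loose, Parameters(fc_threshold=1.5)
        )

    def test_anova_gate_only_restricts(self, design3, specs):
        rng = np.random.default_rng(5)
        expr = make_matrix(design3, rng.normal(8, 1.5, size=(40, 12)))
        fc = fold_change_table(expr, design3, specs)
        anova = two_way_anova(expr, design3)
        without = select_responsive(fc)
        gated = select_responsive(fc, anova=anova)
        assert gated <= without
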