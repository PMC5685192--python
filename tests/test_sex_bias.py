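"""Category statistics on differential-expression summaries."""

import numpy as np
import pandas as pd
import pytest

from xci import sex_bias
from xci.sex_bias import (
    ExpressionFilterRule,
    direction_bias_test,
    direction_consistency,
    flag_escape_like,
    gene_directions,
    paired_category_comparison,
    proportion_sexbiased_by_category,
    run_differential_expression,
    xy_combined_retest,
)
from xci.synthetic_data import SimConfig, simulate_sex_expression


def _de(rows):
    """rows: (gene, tissue, effect, q, expressed)"""
    df = pd.DataFrame(rows, columns=["gene_id", "tissue", "effect_size", "q_value", "expressed"])
    df["p_value"] = df["q_value"]
    df["effect_direction"] = np.where(df["effect_size"] > 0, "female_higher", "male_higher")
    return df


def _catalog(d):
    return pd.DataFrame(
        [{"gene_id": g, "gene_name": g, "status": s, "source": "prior"} for g, s in d.items()]
    )


class TestProportions:
    def test_hand_counted(self):
        de = _de(
            [
                ("E1", "t1", 1.0, 0.001, True),
                ("E2", "t1", 1.0, 0.5, True),
                ("I1", "t1", -0.1, 0.9, True),
                ("I2", "t1", 0.1, 0.002, True),
            ]
        )
        cat = _catalog({"E1": "escape", "E2": "escape", "I1": "inactive", "I2": "inactive"})
        props = proportion_sexbiased_by_category(de, cat)
        assert props.loc["t1", "escape"] == pytest.approx(0.5)
        assert props.loc["t1", "inactive"] == pytest.approx(0.5)

    def test_zero_assessed_is_nan_not_zero(self):
        de = _de([("E1", "t1", 1.0, 0.001, True)])
        cat = _catalog({"E1": "escape", "V1": "variable"})
        props = proportion_sexbiased_by_category(de, cat)
        assert "variable" not in props.columns or np.isnan(props.loc["t1", "variable"])

    def test_no_significance_all_zero(self):
        de = _de([("E1", "t1", 1.0, 0.9, True), ("E1", "t2", 1.0, 0.8, True)])
        props = proportion_sexbiased_by_category(de, _catalog({"E1": "escape"}))
        assert (props["escape"] == 0).all()


class TestPairedComparison:
    def test_all_positive_29_tissues(self):
        rows = []
        for i in range(29):
            rows.append({"tissue": f"t{i}", "escape": 0.5 + 0.01 * i, "inactive": 0.05})
        props = pd.DataFrame(rows).set_index("tissue")
        res = paired_category_comparison(props, "escape", "inactive")
        assert res.p_value == pytest.approx(2 / 2**29, rel=1e-12)

    def test_identical_vectors_surface_error(self):
        props = pd.DataFrame({"escape": [0.2, 0.2], "inactive": [0.2, 0.2]})
        with pytest.raises(ValueError, match="zero"):
            paired_category_comparison(props, "escape", "inactive")


class TestDirections:
    def test_bias_test_reference_counts(self):
        rows = []
        for i in range(52):
            rows.append((f"F{i}", "t1", 1.0, 0.001, True))
        for i in range(15):
            rows.append((f"M{i}", "t1", -1.0, 0.001, True))
        res = direction_bias_test(_de(rows))
        assert (res.statistic, res.n) == (52, 67)
        assert res.p_value == pytest.approx(6.46e-6, rel=1e-3)

    def test_even_split_p_one(self):
        rows = [(f"F{i}", "t1", 1.0, 0.001, True) for i in range(5)]
        rows += [(f"M{i}", "t1", -1.0, 0.001, True) for i in range(5)]
        assert direction_bias_test(_de(rows)).p_value == 1.0

    def test_symmetry(self):
        rows_a = [(f"G{i}", "t1", 1.0 if i < 12 else -1.0, 0.001, True) for i in range(15)]
        rows_b = [(f"G{i}", "t1", -1.0 if i < 12 else 1.0, 0.001, True) for i in range(15)]
        assert direction_bias_test(_de(rows_a)).p_value == pytest.approx(
            direction_bias_test(_de(rows_b)).p_value
        )

    def test_majority_falls_back_to_expressed(self):
        rows = [("G1", f"t{i}", -1.0, 0.5, True) for i in range(4)]
        dirs = gene_directions(_de(rows))
        assert dirs.iloc[0]["direction"] == "male_higher"


class TestConsistency:
    def test_uniform_direction(self):
        rows = [("G1", f"t{i}", 1.0, 0.5, True) for i in range(10)]
        assert direction_consistency(_de(rows))["G1"] == 1.0

    def test_even_split_half(self):
        rows = [("G1", f"t{i}", 1.0 if i < 5 else -1.0, 0.5, True) for i in range(10)]
        assert direction_consistency(_de(rows))["G1"] == 0.5

    def test_nine_of_ten(self):
        rows = [("G1", f"t{i}", 1.0 if i < 9 else -1.0, 0.5, True) for i in range(10)]
        assert direction_consistency(_de(rows))["G1"] == pytest.approx(0.9)

    def test_min_tissues_gate(self):
        rows = [("G1", f"t{i}", 1.0, 0.5, True) for i in range(4)]
        assert "G1" not in direction_consistency(_de(rows), min_tissues=5)


class TestEscapeLike:
    def _rows(self, q_sig):
        rows = [("G1", f"t{i}", 1.0, 0.5, True) for i in range(9)]
        rows.append(("G1", "t9", 1.0, q_sig, True))
        return rows

    def test_inactive_concordant_significant_flagged(self):
        flags = flag_escape_like(_de(self._rows(0.001)), _catalog({"G1": "inactive"}))
        assert list(flags["gene_id"]) == ["G1"]

    def test_without_significance_not_flagged(self):
        flags = flag_escape_like(_de(self._rows(0.5)), _catalog({"G1": "inactive"}))
        assert len(flags) == 0

    def test_escape_catalogued_excluded(self):
        flags = flag_escape_like(_de(self._rows(0.001)), _catalog({"G1": "escape"}))
        assert len(flags) == 0


class TestDE:
    def test_null_gene_not_significant(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(60)]
        expr = pd.DataFrame(rng.lognormal(3, 0.3, (5, 60)), columns=cols,
                            index=[f"G{i}" for i in range(5)])
        sheet = pd.DataFrame(
            {"sample": cols, "sex": ["female"] * 30 + ["male"] * 30, "tissue": "t1"}
        )
        de = run_differential_expression(expr, sheet)
        assert (de["q_value"] > 0.01).all()

    def test_planted_effect_recovered(self):
        cfg = SimConfig(n_genes=60, n_tissues=2, n_samples_per_sex=50, seed=21)
        expr, sheet, effect, genes, truth = simulate_sex_expression(cfg)
        de = run_differential_expression(expr, sheet)
        escape = [g for g, s in truth.gene_status.items() if s == "escape"]
        sig = de[(de["gene_id"].isin(escape)) & (de["q_value"] < 0.01)]
        # strong escape genes should be detected as female-biased
        assert len(sig) > 0
        assert (sig["effect_direction"] == "female_higher").mean() > 0.9

    def test_single_sex_errors(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["s1", "s2"])
        sheet = pd.DataFrame({"sample": ["s1", "s2"], "sex": ["female", "female"], "tissue": "t"})
        with pytest.raises(ValueError, match="single-sex"):
            run_differential_expression(expr, sheet)

    def test_constant_zero_gene_filtered(self):
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(40)]
        expr = pd.DataFrame(
            np.vstack([np.zeros(40), rng.lognormal(3, 0.3, (1, 40))]),
            index=["Gzero", "Gok"],
            columns=cols,
        )
        sheet = pd.DataFrame(
            {"sample": cols, "sex": ["female"] * 20 + ["male"] * 20, "tissue": "t1"}
        )
        de = run_differential_expression(expr, sheet)
        assert not de[de["gene_id"] == "Gzero"]["expressed"].iloc[0]


class TestXYRetest:
    def _setup(self, y_level):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(80)]
        female = np.array([1.0] * 40 + [0.0] * 40)
        base = rng.lognormal(4, 0.2, 80)
        x_expr = base * (1 + 0.5 * female)  # female-biased X homolog
        y_expr = np.where(female == 1, 0.0, y_level * base[0])
        expr_x = pd.DataFrame([x_expr], index=["XG"], columns=cols)
        expr_y = pd.DataFrame([y_expr], index=["YG"], columns=cols)
        sheet = pd.DataFrame(
            {"sample": cols, "sex": ["female"] * 40 + ["male"] * 40, "tissue": "t1"}
        )
        return expr_x, expr_y, sheet

    def test_zero_y_identical_to_x_only(self):
        expr_x, expr_y, sheet = self._setup(0.0)
        expr_y.loc["YG"] = 0.0
        de_x = run_differential_expression(expr_x, sheet)
        de_xy = xy_combined_retest(expr_x, expr_y, {"XG": "YG"}, sheet)
        assert de_xy.iloc[0]["effect_size"] == pytest.approx(de_x.iloc[0]["effect_size"])

    def test_large_y_flips_direction(self):
        expr_x, expr_y, sheet = self._setup(2.0)
        de_xy = xy_combined_retest(expr_x, expr_y, {"XG": "YG"}, sheet)
        assert de_xy.iloc[0]["effect_direction"] == "male_higher"

    def test_unmatched_pair_errors(self):
        expr_x, expr_y, sheet = self._setup(0.0)
        with pytest.raises(ValueError, match="missing"):
            xy_combined_retest(expr_x, expr_y, {"XG": "NOPE"}, sheet)


def test_expression_filter_rule():
    rule = ExpressionFilterRule()
    assert rule.passes(np.full(50, 5.0))
    assert not rule.passes(np.zeros(50))
    with pytest.raises(ValueError):
        ExpressionFilterRule(min_median_rpkm=-1)
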