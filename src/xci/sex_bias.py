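"""Category-level statistics on male-female differential expression.

Escape from XCI leaves a population-level footprint: genes expressed from
both X copies in females tend to be female-biased in the X-specific
region, while PAR1 genes — whose Xi output stays below Xa — come out
male-biased relative to the male X+Y total. This module turns per-gene,
per-tissue differential-expression (DE) summaries into those category
statistics: proportions of sex-biased genes by prior XCI status, paired
cross-tissue comparisons between categories, direction-bias binomial
tests, cross-tissue direction concordance, escape-like flagging of
nominally inactive genes, and the X+Y combined re-test for X-Y homolog
pairs.

The DE fit itself is pluggable: any table with (gene_id, tissue,
effect_size, q_value, expressed) columns works. The built-in backend is
an ordinary linear model of log2 expression on sex plus supplied
covariates — deliberately simple, since everything this module
contributes is downstream of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats_core
from .stats_core import TestResult

DE_COLUMNS = ["gene_id", "tissue", "effect_size", "effect_direction", "p_value", "q_value", "expressed"]


@dataclass
class ExpressionFilterRule:
    """Expression filters applied before the DE fit."""

    min_median_rpkm: float = 0.1
    min_individuals: int = 10
    min_cpm: float = 1.0

    def __post_init__(self) -> None:
        if self.min_median_rpkm < 0 or self.min_cpm < 0 or self.min_individuals < 0:
            raise ValueError("thresholds must be >= 0")

    def passes(self, values: np.ndarray) -> bool:
        return (
            float(np.median(values)) > self.min_median_rpkm
            and int((values > self.min_cpm).sum()) > self.min_individuals
        )


def run_differential_expression(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    filter_rule: ExpressionFilterRule | None = None,
) -> pd.DataFrame:
    """Per-gene, per-tissue male-female DE via OLS on log2 expression.

    ``expr`` is genes x samples (abundance scale); ``samples`` has columns
    sample, sex, tissue plus any covariate columns. The female-minus-male
    coefficient is the signed effect; q-values are computed within each
    tissue. Genes failing the expression filter in a tissue are reported
    with expressed=False and no test.
    """
    filter_rule = filter_rule or ExpressionFilterRule()
    covariates = covariates or []
    rows = []
    for tissue, sheet in samples.groupby("tissue"):
        cols = sheet["sample"].tolist()
        sex = (sheet["sex"] == "female").to_numpy(dtype=float)
        if sex.min() == sex.max():
            raise ValueError(f"tissue {tissue}: single-sex design")
        X = np.column_stack(
            [np.ones(len(cols)), sex]
            + [sheet[c].to_numpy(dtype=float) for c in covariates]
        )
        sub = expr[cols]
        for gene_id, values in sub.iterrows():
            v = values.to_numpy(dtype=float)
            if not filter_rule.passes(v):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "tissue": tissue,
                        "effect_size": np.nan,
                        "p_value": np.nan,
                        "expressed": False,
                    }
                )
                continue
            y = np.log2(v + 1.0)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = len(y) - X.shape[1]
            sigma2 = float(resid @ resid) / dof
            cov = sigma2 * np.linalg.inv(X.T @ X)
            t = beta[1] / np.sqrt(cov[1, 1])
            p = 2.0 * sps.t.sf(abs(t), dof)
            rows.append(
                {
                    "gene_id": gene_id,
                    "tissue": tissue,
                    "effect_size": float(beta[1]),
                    "p_value": float(p),
                    "expressed": True,
                }
            )
    de = pd.DataFrame(rows)
    de["q_value"] = np.nan
    for tissue, idx in de[de["expressed"]].groupby("tissue").groups.items():
        de.loc[idx, "q_value"] = stats_core.fdr_qvalues(de.loc[idx, "p_value"]).q_values
    de["effect_direction"] = np.where(de["effect_size"] > 0, "female_higher", "male_higher")
    de.loc[~de["expressed"], "effect_direction"] = pd.NA
    return de[DE_COLUMNS]


def proportion_sexbiased_by_category(
    de: pd.DataFrame, catalog: pd.DataFrame, q_thresh: float = 0.01
) -> pd.DataFrame:
    """Per-tissue, per-XCI-status proportion of significantly sex-biased
    genes among assessed (expressed) genes. Statuses with zero assessed
    genes in a tissue yield NaN — undefined, not zero."""
    status = catalog.set_index("gene_id")["status"]
    d = de[de["expressed"]].copy()
    d["status"] = d["gene_id"].map(status)
    d = d.dropna(subset=["status"])
    d["significant"] = d["q_value"] < q_thresh

    def prop(sub: pd.DataFrame) -> float:
        return float(sub["significant"].mean()) if len(sub) else np.nan

    table = (
        d.groupby(["tissue", "status"])
        .apply(prop, include_groups=False)
        .unstack("status")
    )
    return table


def paired_category_comparison(
    proportions: pd.DataFrame, status_a: str, status_b: str
) -> TestResult:
    """Two-sided exact Wilcoxon signed-rank on the per-tissue difference in
    sex-biased proportions between two XCI categories. Tissues where
    either proportion is undefined are dropped; identical vectors (all
    zero differences) surface the underlying no-information error."""
    sub = proportions[[status_a, status_b]].dropna()
    if len(sub) < 1:
        raise ValueError("no tissue has both categories defined")
    diffs = (sub[status_a] - sub[status_b]).to_numpy()
    return stats_core.wilcoxon_signed_rank_exact(diffs, sided="two_sided")


def gene_directions(
    de: pd.DataFrame, q_thresh: float = 0.01, use: str = "significant_first"
) -> pd.DataFrame:
    """Reduce each gene to one direction across tissues.

    The majority direction over significant tissues, falling back to the
    majority over expressed tissues when no tissue is significant
    (``use='significant_first'``); or always over expressed tissues
    (``use='expressed'``). Exact ties yield direction 'tied'.
    """
    rows = []
    for gene, sub in de[de["expressed"]].groupby("gene_id"):
        sig = sub[sub["q_value"] < q_thresh]
        basis = sig if (len(sig) and use == "significant_first") else sub
        n_f = int((basis["effect_direction"] == "female_higher").sum())
        n_m = len(basis) - n_f
        direction = "tied" if n_f == n_m else ("female_higher" if n_f > n_m else "male_higher")
        rows.append(
            {
                "gene_id": gene,
                "direction": direction,
                "n_significant": len(sig),
                "n_expressed": len(sub),
            }
        )
    return pd.DataFrame(rows)


def direction_bias_test(
    de: pd.DataFrame, gene_subset: set[str] | None = None, q_thresh: float = 0.01
) -> TestResult:
    """Two-sided exact binomial test of the count of female-biased genes
    against an even split. Each gene contributes its single majority
    direction; tied genes are excluded from both k and n."""
    dirs = gene_directions(de, q_thresh)
    if gene_subset is not None:
        dirs = dirs[dirs["gene_id"].isin(gene_subset)]
    dirs = dirs[dirs["direction"] != "tied"]
    n = len(dirs)
    if n == 0:
        raise ValueError("zero assessed genes")
    k = int((dirs["direction"] == "female_higher").sum())
    return stats_core.binom_test_exact(k, n, 0.5, "two_sided")


def direction_consistency(de: pd.DataFrame, min_tissues: int = 5) -> pd.Series:
    """Per-gene concordance: the fraction of expressed tissues sharing the
    gene's majority direction. An exact split scores 0.5. Genes expressed
    in fewer than ``min_tissues`` tissues are omitted."""
    out = {}
    for gene, sub in de[de["expressed"]].groupby("gene_id"):
        if len(sub) < min_tissues:
            continue
        n_f = int((sub["effect_direction"] == "female_higher").sum())
        n_m = len(sub) - n_f
        out[gene] = 0.5 if n_f == n_m else max(n_f, n_m) / len(sub)
    return pd.Series(out, name="concordance")


def flag_escape_like(
    de: pd.DataFrame,
    catalog: pd.DataFrame,
    concordance_thresh: float = 0.9,
    q_thresh: float = 0.01,
    min_tissues: int = 5,
) -> pd.DataFrame:
    """Flag genes not catalogued as escape whose sex-bias profile looks
    like escape: direction concordance above the threshold AND significant
    sex bias in at least one tissue."""
    conc = direction_consistency(de, min_tissues)
    status = catalog.set_index("gene_id")["status"]
    sig_any = (
        de[de["expressed"]].groupby("gene_id")["q_value"].apply(lambda q: bool((q < q_thresh).any()))
    )
    rows = []
    for gene, c in conc.items():
        cat = status.get(gene, "absent")
        if cat == "escape":
            continue
        if c > concordance_thresh and sig_any.get(gene, False):
            rows.append({"gene_id": gene, "concordance": c, "catalog_status": cat})
    return pd.DataFrame(rows, columns=["gene_id", "concordance", "catalog_status"])


def xy_combined_retest(
    expr_x: pd.DataFrame,
    expr_y: pd.DataFrame,
    pair_map: dict[str, str],
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    filter_rule: ExpressionFilterRule | None = None,
) -> pd.DataFrame:
    """Re-run the sex-bias DE replacing each X homolog's expression with
    the combined X + Y expression of the pair. ``pair_map`` maps X gene id
    to its Y homolog; both members must be present in their matrices.
    Y expression is zero in females, so a male Y contribution can cancel
    or flip an apparent female bias of the X member."""
    for x_gene, y_gene in pair_map.items():
        if x_gene not in expr_x.index:
            raise ValueError(f"X member {x_gene} missing from expression matrix")
        if y_gene not in expr_y.index:
            raise ValueError(f"Y member {y_gene} missing from expression matrix")
    combined = expr_x.loc[list(pair_map)].copy()
    for x_gene, y_gene in pair_map.items():
        combined.loc[x_gene] = combined.loc[x_gene] + expr_y.loc[y_gene].reindex(
            combined.columns
        ).fillna(0.0)
    return run_differential_expression(combined, samples, covariates, filter_rule)
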