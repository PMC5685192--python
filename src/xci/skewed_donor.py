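"""Multi-tissue XCI inference from a single fully-skewed donor.

In a female whose cells all inactivate the same X, allelic read counts at
heterozygous X sites separate cleanly into Xa and Xi output: the allele
with the lower combined relative expression across tissues is taken to be
the Xi allele (XIST, expressed exclusively from Xi, is oriented the other
way). Per (gene, tissue), Xi expression significantly above the empirical
allele-miscall bound (one-sided binomial vs p0 = 0.025, FDR within each
tissue separately, q < 0.01) marks incomplete inactivation; the
cross-tissue pattern of significant tissues then classifies each gene as
fully inactivated, incompletely inactivated with tissue-shared or
heterogeneous Xi levels, or escaping in a single tissue context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats_core
from .io_formats import GeneModel, map_sites_to_genes, validate_allele_counts

logger = logging.getLogger(__name__)

XCIStatus = str  # full | incomplete_shared | incomplete_heterogeneous | incomplete_single_context


@dataclass
class CallingConfig:
    """Thresholds of the per-tissue escape test."""

    p0: float = 0.025  # empirical upper bound on allele miscalls
    q_thresh: float = 0.01
    min_tissue_coverage: int = 8  # ">7 reads" site-selection rule
    heterogeneity_ratio: float = 3.0  # max/min significant Xi fraction for "shared"
    power_target: float = 0.8
    power_xi_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 0.5):
            raise ValueError("p0 must be in (0, 0.5)")
        if not (0.0 < self.q_thresh < 1.0):
            raise ValueError("q_thresh must be in (0, 1)")


@dataclass
class XCICall:
    gene_id: str
    status: XCIStatus
    site_id: str
    per_tissue: pd.DataFrame = field(repr=False)  # tissue, xi, xa, xi_fraction, p, q, ci_lo, ci_hi


def select_site_per_gene(
    table: pd.DataFrame, genes: list[GeneModel], min_coverage: int = 8
) -> pd.DataFrame:
    """Pick one representative site per gene: the site with coverage of at
    least ``min_coverage`` reads (">7") in the largest number of tissues.
    Ties break to the smallest genomic position so the choice is invariant
    to input row order. Genes without any site are omitted with a log line.

    Returns a DataFrame (gene_id, site_id) sorted by gene.
    """
    validate_allele_counts(table)
    site_gene = map_sites_to_genes(table, genes)
    t = table.assign(
        total=table["ref_count"] + table["alt_count"],
        gene_id=table["site_id"].map(site_gene),
    ).dropna(subset=["gene_id"])
    per_site = (
        t.groupby(["gene_id", "site_id", "pos"], as_index=False)
        .agg(n_covered=("total", lambda x: int((x >= min_coverage).sum())))
    )
    picked = (
        per_site.sort_values(["gene_id", "n_covered", "pos"], ascending=[True, False, True])
        .groupby("gene_id", as_index=False)
        .first()
    )
    n_missing = len({g.gene_id for g in genes} - set(site_gene.values))
    if n_missing:
        logger.info("select_site_per_gene: %d genes had no ASE site", n_missing)
    return picked[["gene_id", "site_id"]]


def assign_xi_allele(
    table: pd.DataFrame,
    selection: pd.DataFrame,
    xist_gene_id: str = "XIST",
) -> pd.DataFrame:
    """Orient each gene's selected site to Xa/Xi.

    The allele with the lower summed relative expression across tissues is
    taken as Xi; at XIST the higher-expressing allele is Xi. Exactly equal
    pooled expression leaves the gene unresolved and excluded.

    Returns (gene_id, site_id, xi_allele, xa_allele) with xi_allele in
    {'ref', 'alt'}.
    """
    rows = []
    by_site = table.groupby("site_id")[["ref_count", "alt_count"]].sum()
    for _, rec in selection.iterrows():
        if rec["site_id"] not in by_site.index:
            continue
        pooled = by_site.loc[rec["site_id"]]
        ref_tot, alt_tot = int(pooled["ref_count"]), int(pooled["alt_count"])
        if ref_tot + alt_tot == 0 or ref_tot == alt_tot:
            logger.info("assign_xi_allele: %s unresolved (equal pooled counts)", rec["gene_id"])
            continue
        minor = "ref" if ref_tot < alt_tot else "alt"
        major = "alt" if minor == "ref" else "ref"
        xi = major if rec["gene_id"] == xist_gene_id else minor
        rows.append(
            {
                "gene_id": rec["gene_id"],
                "site_id": rec["site_id"],
                "xi_allele": xi,
                "xa_allele": "ref" if xi == "alt" else "alt",
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "site_id", "xi_allele", "xa_allele"])


def gene_tissue_ase(table: pd.DataFrame, orientation: pd.DataFrame) -> pd.DataFrame:
    """Xi/Xa counts per (gene, tissue) at the oriented selected sites."""
    merged = table.merge(orientation, on="site_id")
    xi = np.where(merged["xi_allele"] == "ref", merged["ref_count"], merged["alt_count"])
    xa = np.where(merged["xi_allele"] == "ref", merged["alt_count"], merged["ref_count"])
    out = merged.assign(xi_count=xi, xa_count=xa)[
        ["gene_id", "site_id", "unit_id", "xi_count", "xa_count"]
    ].rename(columns={"unit_id": "tissue"})
    return out


def call_xi_per_tissue(ase: pd.DataFrame, config: CallingConfig | None = None) -> pd.DataFrame:
    """One-sided binomial test of Xi expression above the error bound for
    every (gene, tissue) observation; FDR correction within each tissue
    separately. Observations with zero total reads are skipped.

    Returns the input with added xi_fraction, p, q, significant, ci_lo/hi.
    """
    config = config or CallingConfig()
    df = ase.copy()
    total = df["xi_count"] + df["xa_count"]
    df = df[total > 0].copy()
    total = df["xi_count"] + df["xa_count"]
    df["xi_fraction"] = df["xi_count"] / total
    # P(X >= xi) under Binomial(total, p0)
    df["p"] = sps.binom.sf(df["xi_count"] - 1, total, config.p0)
    df["q"] = np.nan
    for tissue, idx in df.groupby("tissue").groups.items():
        df.loc[idx, "q"] = stats_core.fdr_qvalues(df.loc[idx, "p"]).q_values
    df["significant"] = df["q"] < config.q_thresh
    ci = [stats_core.jeffreys_interval(int(k), int(n)) for k, n in zip(df["xi_count"], total)]
    df["ci_lo"] = [c[0] for c in ci]
    df["ci_hi"] = [c[1] for c in ci]
    return df


def is_powered(n_reads: int, config: CallingConfig) -> bool:
    """Whether coverage ``n_reads`` gives at least the target power to
    detect the reference Xi fraction at the nominal q threshold (treated
    as the per-test level for the power computation)."""
    if n_reads < 1:
        return False
    # smallest k with one-sided tail p <= q_thresh
    k_crit = int(sps.binom.isf(config.q_thresh, n_reads, config.p0)) + 1
    power = sps.binom.sf(k_crit - 1, n_reads, config.power_xi_fraction)
    return bool(power >= config.power_target)


def _simes(pvals: np.ndarray) -> float:
    p = np.sort(np.asarray(pvals, dtype=float))
    m = p.size
    return float(min(1.0, (m * p / np.arange(1, m + 1)).min()))


def classify_xci(calls: pd.DataFrame, config: CallingConfig | None = None) -> pd.DataFrame:
    """Cross-tissue XCI status per gene from the per-tissue calls.

    A gene is incompletely inactivated only when its cross-tissue evidence
    survives a gene-level FDR: each gene's per-tissue binomial p-values
    are combined with Simes' method and BH-corrected across genes at
    ``q_thresh``. This bounds the rate of genes falsely called non-full —
    per-tissue q-values alone control errors per observation, and a union
    over many tissues would accumulate them. Among non-full genes:
    incomplete_single_context — exactly one significant tissue among at
    least two adequately powered tissues; incomplete_shared — significant
    tissues' Xi fractions agree within the heterogeneity ratio;
    incomplete_heterogeneous otherwise. Invariant to tissue order.
    """
    config = config or CallingConfig()
    gene_ids = sorted(calls["gene_id"].unique())
    simes_p = np.array(
        [_simes(calls.loc[calls["gene_id"] == g, "p"].to_numpy()) for g in gene_ids]
    )
    gene_q = pd.Series(stats_core.fdr_qvalues(simes_p).q_values, index=gene_ids)
    rows = []
    for gene, sub in calls.groupby("gene_id"):
        sig = sub[sub["significant"]]
        n_sig = len(sig) if gene_q[gene] < config.q_thresh else 0
        n_powered = int(
            sum(is_powered(int(n), config) for n in sub["xi_count"] + sub["xa_count"])
        )
        if n_sig == 0:
            status = "full"
        elif n_sig == 1:
            status = "incomplete_single_context" if n_powered >= 2 else "incomplete_shared"
        else:
            fr = sig["xi_fraction"]
            lo = float(fr.min())
            status = (
                "incomplete_shared"
                if lo > 0 and float(fr.max()) / lo <= config.heterogeneity_ratio
                else "incomplete_heterogeneous"
            )
        rows.append(
            {
                "gene_id": gene,
                "status": status,
                "gene_q": float(gene_q[gene]),
                "n_significant": n_sig,
                "n_tissues": len(sub),
                "n_powered": n_powered,
                "mean_xi_fraction": float(sub["xi_fraction"].mean()),
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def run_donor_pipeline(
    table: pd.DataFrame,
    genes: list[GeneModel],
    config: CallingConfig | None = None,
    xist_gene_id: str = "XIST",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """site selection -> Xi orientation -> per-tissue tests -> gene status.

    Returns (per-observation calls, per-gene classification).
    """
    config = config or CallingConfig()
    selection = select_site_per_gene(table, genes, config.min_tissue_coverage)
    orientation = assign_xi_allele(table, selection, xist_gene_id)
    ase = gene_tissue_ase(table, orientation)
    calls = call_xi_per_tissue(ase, config)
    return calls, classify_xci(calls, config)


def estimate_skew(
    table: pd.DataFrame,
    genes: list[GeneModel],
    inactive_gene_ids: set[str],
    min_sites: int = 5,
) -> tuple[pd.Series, float | None]:
    """Read-weighted XCI skew from inactive-catalogued nonPAR sites.

    For each tissue the estimate is the read-weighted major-allele fraction
    across informative sites, folded to [0.5, 1.0] (parental labelling is
    discarded; unphased donors carry no orientation). Returns (per-tissue
    series, donor-level pooled estimate); both are None/empty when fewer
    than ``min_sites`` informative sites are available.
    """
    site_gene = map_sites_to_genes(table, genes)
    nonpar = {
        g.gene_id for g in genes if g.region_class in ("nonPAR_Xp", "nonPAR_Xq")
    }
    keep_genes = (nonpar & inactive_gene_ids) if inactive_gene_ids else nonpar
    t = table.assign(gene_id=table["site_id"].map(site_gene)).dropna(subset=["gene_id"])
    t = t[t["gene_id"].isin(keep_genes)]
    n_sites = t["site_id"].nunique()
    if n_sites < min_sites:
        logger.info("estimate_skew: only %d informative sites (< %d)", n_sites, min_sites)
        return pd.Series(dtype=float), None
    pooled = t.groupby("site_id")[["ref_count", "alt_count"]].sum()
    major_is_ref = pooled["ref_count"] >= pooled["alt_count"]

    def folded(sub: pd.DataFrame) -> float:
        maj = np.where(sub["site_id"].map(major_is_ref), sub["ref_count"], sub["alt_count"])
        tot = (sub["ref_count"] + sub["alt_count"]).to_numpy()
        x = maj.sum() / tot.sum()
        return float(max(x, 1.0 - x))

    per_tissue = t.groupby("unit_id").apply(folded, include_groups=False)
    donor = folded(t)
    return per_tissue, donor
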