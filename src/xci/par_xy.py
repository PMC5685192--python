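"""X vs Y expression at PAR1 genes in males.

PAR1 is shared between X and Y, so in a male every PAR1 heterozygous site
whose genotype is trio-phased separates reads by chromosome: the
maternally inherited allele sits on the X, the paternally inherited one
on the Y. Summing reads per gene across its informative sites and testing
the X fraction against 0.5 (two-sided exact binomial, with a Jeffreys CI
on the read ratio) asks whether PAR1 dosage is balanced between the sex
chromosomes. Recombination between an assayed site and the
sex-determining region would break the maternal-equals-X assumption; such
events are out of model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import stats_core
from .io_formats import GeneModel, PhasedGenotype, map_sites_to_genes
from .stats_core import TestResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParGeneXY:
    gene_id: str
    x_count: int
    y_count: int


def assign_par_reads(
    table: pd.DataFrame,
    genotypes: list[PhasedGenotype],
    genes: list[GeneModel],
) -> list[ParGeneXY]:
    """Assign PAR1 allelic reads to X (maternal) and Y (paternal), summed
    per gene over informative sites.

    Sites outside PAR1 gene models are rejected from the analysis (region
    guard); unphased sites are skipped with a log line.
    """
    par1_genes = [g for g in genes if g.region_class == "PAR1"]
    site_gene = map_sites_to_genes(table, par1_genes)
    maternal_is_ref = {g.site_id: g.maternal_allele == g.ref for g in genotypes if g.phased}
    n_unphased = sum(1 for g in genotypes if not g.phased)
    if n_unphased:
        logger.info("assign_par_reads: skipped %d unphased sites", n_unphased)
    t = table.assign(gene_id=table["site_id"].map(site_gene))
    n_outside = int(t["gene_id"].isna().sum())
    if n_outside:
        logger.info("assign_par_reads: rejected %d observations outside PAR1", n_outside)
    t = t.dropna(subset=["gene_id"])
    t = t[t["site_id"].isin(maternal_is_ref)]
    out: dict[str, list[int]] = {}
    for _, row in t.iterrows():
        x = row["ref_count"] if maternal_is_ref[row["site_id"]] else row["alt_count"]
        y = row["alt_count"] if maternal_is_ref[row["site_id"]] else row["ref_count"]
        acc = out.setdefault(row["gene_id"], [0, 0])
        acc[0] += int(x)
        acc[1] += int(y)
    return [ParGeneXY(g, x, y) for g, (x, y) in sorted(out.items())]


def test_xy_equality(gene: ParGeneXY, level: float = 0.95) -> tuple[TestResult, tuple[float, float]]:
    """Two-sided exact binomial test of equal X and Y expression, plus the
    Jeffreys CI on the X read fraction."""
    n = gene.x_count + gene.y_count
    if n < 1:
        raise ValueError(f"{gene.gene_id}: zero total reads")
    result = stats_core.binom_test_exact(gene.x_count, n, 0.5, "two_sided")
    ci = stats_core.jeffreys_interval(gene.x_count, n, level)
    return result, ci


def par1_dosage_table(par_genes: list[ParGeneXY], level: float = 0.95) -> pd.DataFrame:
    """Per-gene X/Y dosage summary (fraction, CI, p-value)."""
    rows = []
    for g in par_genes:
        res, ci = test_xy_equality(g, level)
        n = g.x_count + g.y_count
        rows.append(
            {
                "gene_id": g.gene_id,
                "x_count": g.x_count,
                "y_count": g.y_count,
                "x_fraction": g.x_count / n,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
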