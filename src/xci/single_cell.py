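"""Single-cell XCI analysis: biallelic detection, cell-population
assignment (trio-phased or reference-free), Xa/Xi aggregation and escape
calling.

Every female cell expresses X-linked genes predominantly from its one
active X, so across cells the expressed alleles at fully inactivated
sites are perfectly correlated with which parental X is active. With trio
phasing the assignment of each cell to the two parental populations is a
majority vote of its expressed alleles; without it, the correlation
structure of expressed alleles across cells recovers both the bipartition
of cells and the site haplotypes (up to a global label swap). PAR1 sites
and frequently biallelic sites (escape candidates) are excluded from
phasing so escape genes do not blur the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats_core
from .io_formats import GeneModel, PhasedGenotype

logger = logging.getLogger(__name__)


@dataclass
class ScCallingConfig:
    """Filters and thresholds of the single-cell calling stages."""

    min_reads_per_site: int = 8
    biallelic_ae_thresh: float = 0.05  # minor-allele fraction
    biallelic_alpha: float = 0.05  # nominal per-cell-site level
    p0: float = 0.025  # empirical allele-miscall bound
    min_cells_per_gene: int = 5
    min_biallelic_cells: int = 2
    q_thresh: float = 0.01
    frequently_biallelic_cell_fraction: float = 0.10
    min_assignment_agreement: float = 0.8

    def __post_init__(self) -> None:
        if self.min_reads_per_site < 1 or self.min_cells_per_gene < 1:
            raise ValueError("count thresholds must be positive")
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must be in (0, 1)")


@dataclass(frozen=True)
class CellAssignment:
    cell_id: str
    population: str  # 'P1' | 'P2' | 'uninformative'
    n_supporting_sites: int
    agreement_score: float


def detect_biallelic_cells(
    matrix: pd.DataFrame,
    config: ScCallingConfig | None = None,
    site_to_gene: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag biallelically expressed (cell, site) observations.

    Only observations with at least ``min_reads_per_site`` reads are
    assessed. An observation is biallelic when the minor-allele fraction
    exceeds ``biallelic_ae_thresh`` AND a one-sided binomial test finds it
    nominally (p < biallelic_alpha) above the miscall bound p0. A gene is
    flagged biallelic when at least ``min_biallelic_cells`` of its
    observations are biallelic across all cells.

    Returns (per-observation table with 'biallelic' column, per-gene flag
    series — empty when no site_to_gene map is given).
    """
    config = config or ScCallingConfig()
    m = matrix.copy()
    total = m["ref_count"] + m["alt_count"]
    m["assessed"] = total >= config.min_reads_per_site
    minor = np.minimum(m["ref_count"], m["alt_count"])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, minor / total, 0.0)
    p = sps.binom.sf(minor - 1, total.clip(lower=1), config.p0)
    m["biallelic"] = (
        m["assessed"] & (frac > config.biallelic_ae_thresh) & (p < config.biallelic_alpha)
    )
    if site_to_gene is None:
        return m, pd.Series(dtype=bool)
    m["gene_id"] = m["site_id"].map(site_to_gene)
    per_gene = (
        m.dropna(subset=["gene_id"]).groupby("gene_id")["biallelic"].sum()
        >= config.min_biallelic_cells
    )
    return m, per_gene


def identify_frequently_biallelic_sites(
    matrix: pd.DataFrame,
    config: ScCallingConfig | None = None,
    par1_sites: set[str] | None = None,
) -> set[str]:
    """Sites to exclude from phasing: all PAR1 sites plus sites biallelic
    in more than ``frequently_biallelic_cell_fraction`` of the cells in
    which they were assessed."""
    config = config or ScCallingConfig()
    flagged, _ = detect_biallelic_cells(matrix, config)
    assessed = flagged[flagged["assessed"]]
    frac = assessed.groupby("site_id")["biallelic"].mean()
    frequent = set(frac[frac > config.frequently_biallelic_cell_fraction].index)
    return frequent | (par1_sites or set())


def par1_site_ids(matrix: pd.DataFrame, genes: list[GeneModel]) -> set[str]:
    """Site ids falling inside PAR1 gene models."""
    par1 = [g for g in genes if g.region_class == "PAR1"]
    sites = matrix[["site_id", "chrom", "pos"]].drop_duplicates("site_id")
    out = set()
    for _, row in sites.iterrows():
        if any(g.contains(row["chrom"], row["pos"]) for g in par1):
            out.add(row["site_id"])
    return out


def _expressed_allele_signs(
    matrix: pd.DataFrame, exclusions: set[str]
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per (cell, site) majority expressed allele encoded +1 (ref) / -1
    (alt); balanced observations are dropped as uninformative."""
    m = matrix[~matrix["site_id"].isin(exclusions)].copy()
    m = m[(m["ref_count"] + m["alt_count"]) > 0]
    m["sign"] = np.sign(m["ref_count"] - m["alt_count"]).astype(int)
    m = m[m["sign"] != 0]
    cells = sorted(m["cell_id"].unique()) if "cell_id" in m else sorted(m["unit_id"].unique())
    sites = sorted(m["site_id"].unique())
    return m, cells, sites


def _unit_col(matrix: pd.DataFrame) -> str:
    return "cell_id" if "cell_id" in matrix.columns else "unit_id"


def assign_cells_with_parental_phase(
    matrix: pd.DataFrame,
    genotypes: list[PhasedGenotype],
    exclusions: set[str] | None = None,
) -> list[CellAssignment]:
    """Assign each cell to the maternal-active (P1) or paternal-active (P2)
    population by majority vote over its expressed alleles at phased,
    non-excluded sites. Cells without informative sites, or with an exact
    50:50 split of site support, are uninformative.

    P1 means the maternal X (haplotype A of the trio-phased genotypes) is
    the active X in that cell.
    """
    exclusions = exclusions or set()
    unit = _unit_col(matrix)
    maternal_is_ref = {
        g.site_id: g.maternal_allele == g.ref for g in genotypes if g.phased
    }
    m, _, _ = _expressed_allele_signs(matrix.rename(columns={unit: "cell_id"}), exclusions)
    m = m[m["site_id"].isin(maternal_is_ref)]
    out: list[CellAssignment] = []
    for cell in sorted(matrix[unit].unique()):
        sub = m[m["cell_id"] == cell]
        if not len(sub):
            out.append(CellAssignment(cell, "uninformative", 0, 0.0))
            continue
        mat_sign = np.where(sub["site_id"].map(maternal_is_ref), 1, -1)
        support_m = int((sub["sign"] == mat_sign).sum())
        support_p = len(sub) - support_m
        if support_m == support_p:
            out.append(CellAssignment(cell, "uninformative", len(sub), 0.5))
            continue
        pop = "P1" if support_m > support_p else "P2"
        score = max(support_m, support_p) / len(sub)
        out.append(CellAssignment(cell, pop, len(sub), score))
    return out


def infer_partition_unphased(
    matrix: pd.DataFrame,
    exclusions: set[str] | None = None,
    seed: int | None = None,
    config: ScCallingConfig | None = None,
    max_iter: int = 50,
) -> tuple[list[CellAssignment], pd.Series]:
    """Reference-free bipartition of cells into the two X-active
    populations, plus the inferred site haplotype phase.

    Cells are nodes of an agreement graph: for every pair, shared
    non-excluded sites contribute +1 when the majority expressed allele
    matches and -1 when it differs. The sign of the leading eigenvector of
    the agreement matrix gives an initial split, refined by iterating
    between (a) the consensus haplotype of population P1 (P2 expresses the
    complementary allele at every heterozygous site) and (b) reassigning
    each cell to the population its expressed alleles agree with, until a
    fixpoint. Output is invariant, up to the global P1/P2 swap, to cell
    order; cells with agreement below ``min_assignment_agreement`` are
    demoted to uninformative.

    Returns (assignments, phase) where phase maps site_id to the allele
    ('ref'/'alt') carried by the haplotype active in P1 cells. Exclusions
    apply to the partition estimation only; once cells are assigned, the
    phase is read off the population majorities at every site in the
    matrix (at fully inactivated sites the expressed allele marks the
    active haplotype; at escape sites the Xa allele still dominates).
    """
    config = config or ScCallingConfig()
    exclusions = exclusions or set()
    rng = np.random.default_rng(seed)
    unit = _unit_col(matrix)
    m, cells, sites = _expressed_allele_signs(
        matrix.rename(columns={unit: "cell_id"}), exclusions
    )
    if not cells:
        raise ValueError("no informative observations to phase")
    cell_ix = {c: i for i, c in enumerate(cells)}
    site_ix = {s: j for j, s in enumerate(sites)}
    S = np.zeros((len(cells), len(sites)))
    S[m["cell_id"].map(cell_ix), m["site_id"].map(site_ix)] = m["sign"]

    A = S @ S.T  # agreement counts; diagonal is per-cell site count
    np.fill_diagonal(A, 0.0)
    if not np.any(A):
        raise ValueError("no overlapping sites between any two cells: cannot phase")
    # leading eigenvector of the symmetric agreement matrix
    vals, vecs = np.linalg.eigh(A)
    v = vecs[:, np.argmax(vals)]
    assign = np.where(v >= 0, 1, -1)

    for _ in range(max_iter):
        h = np.sign(assign @ S)  # consensus allele per site for P1
        zero = h == 0
        if zero.any():
            h[zero] = rng.choice([-1, 1], int(zero.sum()))
        score = S @ h  # per-cell net agreement with P1 haplotype
        new_assign = np.where(score > 0, 1, np.where(score < 0, -1, assign))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    h = np.sign(assign @ S)
    zero = h == 0
    if zero.any():
        h[zero] = rng.choice([-1, 1], int(zero.sum()))
    informative = np.abs(S).sum(axis=1)

    out: list[CellAssignment] = []
    all_cells = sorted(matrix[unit].unique())
    agree_frac = np.zeros(len(cells))
    for i in range(len(cells)):
        covered = S[i] != 0
        n_cov = int(covered.sum())
        if n_cov:
            agree_frac[i] = float((S[i, covered] * h[covered] * assign[i] > 0).sum()) / n_cov
    for cell in all_cells:
        if cell not in cell_ix:
            out.append(CellAssignment(cell, "uninformative", 0, 0.0))
            continue
        i = cell_ix[cell]
        n_sites = int(informative[i])
        if agree_frac[i] < config.min_assignment_agreement:
            out.append(CellAssignment(cell, "uninformative", n_sites, agree_frac[i]))
            continue
        pop = "P1" if assign[i] > 0 else "P2"
        out.append(CellAssignment(cell, pop, n_sites, agree_frac[i]))
    # phase every site (including ones excluded from partition estimation)
    # from the final assignment's population majorities
    m_all, _, _ = _expressed_allele_signs(
        matrix.rename(columns={unit: "cell_id"}), set()
    )
    assign_of = {
        a.cell_id: (1 if a.population == "P1" else -1)
        for a in out
        if a.population in ("P1", "P2")
    }
    m_all = m_all[m_all["cell_id"].isin(assign_of)]
    weighted = m_all["sign"] * m_all["cell_id"].map(assign_of)
    h_all = weighted.groupby(m_all["site_id"]).sum()
    ties = h_all[h_all == 0].index
    if len(ties):
        h_all[ties] = rng.choice([-1, 1], len(ties))
    phase = pd.Series(
        np.where(h_all > 0, "ref", "alt"), index=h_all.index, name="p1_active_allele"
    )
    return out, phase


def phase_from_parental(genotypes: list[PhasedGenotype]) -> pd.Series:
    """Phase series (P1-active allele per site) from trio-phased genotypes,
    with P1 = maternal X active."""
    return pd.Series(
        {g.site_id: ("ref" if g.maternal_allele == g.ref else "alt") for g in genotypes if g.phased},
        name="p1_active_allele",
    )


def aggregate_xa_xi(
    matrix: pd.DataFrame,
    assignments: list[CellAssignment],
    phase: pd.Series,
    site_to_gene: pd.Series,
    xist_gene_id: str = "XIST",
) -> pd.DataFrame:
    """Collapse per-cell allelic counts to per-gene (xa, xi) totals.

    For a P1 cell the allele that phase marks active contributes to Xa and
    the other to Xi; P2 cells contribute with the orientation reversed.
    Counts are summed per site across cells, then per gene. XIST — by
    definition expressed from Xi — is re-anchored so its dominant allele
    maps to Xi if the aggregation left it the other way. Uninformative
    cells are excluded; reads at phased sites of informative cells are
    conserved. Genes with zero aggregate reads are omitted.
    """
    pop = {a.cell_id: a.population for a in assignments}
    unit = _unit_col(matrix)
    m = matrix.rename(columns={unit: "cell_id"}).copy()
    m["pop"] = m["cell_id"].map(pop)
    m = m[m["pop"].isin(["P1", "P2"])]
    m = m[m["site_id"].isin(phase.index)]
    p1_ref = m["site_id"].map(phase) == "ref"
    active_is_ref = np.where(m["pop"] == "P1", p1_ref, ~p1_ref)
    m["xa_count"] = np.where(active_is_ref, m["ref_count"], m["alt_count"])
    m["xi_count"] = np.where(active_is_ref, m["alt_count"], m["ref_count"])
    m["gene_id"] = m["site_id"].map(site_to_gene)
    m = m.dropna(subset=["gene_id"])
    per_gene = m.groupby("gene_id").agg(
        xa_count=("xa_count", "sum"),
        xi_count=("xi_count", "sum"),
        n_cells=("cell_id", "nunique"),
        n_sites=("site_id", "nunique"),
    )
    per_gene = per_gene[(per_gene["xa_count"] + per_gene["xi_count"]) > 0]
    if xist_gene_id in per_gene.index:
        row = per_gene.loc[xist_gene_id]
        if row["xa_count"] > row["xi_count"]:
            per_gene.loc[xist_gene_id, ["xa_count", "xi_count"]] = (
                row["xi_count"],
                row["xa_count"],
            )
    return per_gene.reset_index()


def call_xci_from_cells(
    per_gene: pd.DataFrame,
    config: ScCallingConfig | None = None,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Escape calls from aggregated Xa/Xi counts for one sample.

    Genes covered by fewer than ``min_cells_per_gene`` cells or fewer than
    ``min_reads_per_site`` aggregate reads are reported as 'not_assayed'
    (distinct from inactive). For the rest, the Xi-to-total ratio is
    tested one-sided against p0; q-values are computed within the sample;
    q < q_thresh calls the gene 'escape' (incompletely inactivated), else
    'inactive'.
    """
    config = config or ScCallingConfig()
    df = per_gene.copy()
    total = df["xa_count"] + df["xi_count"]
    df["total"] = total
    df["assayed"] = (df["n_cells"] >= config.min_cells_per_gene) & (
        total >= config.min_reads_per_site
    )
    df["p"] = np.nan
    assayed = df["assayed"]
    df.loc[assayed, "p"] = sps.binom.sf(
        df.loc[assayed, "xi_count"] - 1, df.loc[assayed, "total"], config.p0
    )
    df["q"] = np.nan
    if assayed.any():
        df.loc[assayed, "q"] = stats_core.fdr_qvalues(df.loc[assayed, "p"]).q_values
    df["status"] = "not_assayed"
    df.loc[assayed, "status"] = np.where(
        df.loc[assayed, "q"] < config.q_thresh, "escape", "inactive"
    )
    df["sample_id"] = sample_id
    return df


def combine_sample_calls(calls: list[pd.DataFrame]) -> pd.DataFrame:
    """Across samples: a gene significant in at least one sample is
    partially inactivated; assayed nowhere -> not_assayed."""
    allc = pd.concat(calls, ignore_index=True)
    rows = []
    for gene, sub in allc.groupby("gene_id"):
        assayed = sub[sub["assayed"]]
        if not len(assayed):
            status = "not_assayed"
        elif (assayed["status"] == "escape").any():
            status = "escape"
        else:
            status = "inactive"
        rows.append({"gene_id": gene, "status": status, "n_samples_assayed": len(assayed)})
    return pd.DataFrame(rows)


def xi_xa_ratio(xi_count: int, xa_count: int, level: float = 0.95) -> dict:
    """Xi/Xa expression ratio with a Jeffreys CI transformed from the
    Xi-fraction scale (f -> f/(1-f)). xa = 0 (the XIST-like orientation)
    is reported as an inverted special case with an infinite ratio."""
    if xa_count == 0:
        return {"ratio": np.inf, "ci_lo": np.nan, "ci_hi": np.nan, "inverted": True}
    n = xi_count + xa_count
    lo, hi = stats_core.jeffreys_interval(xi_count, n, level)
    to_ratio = lambda f: f / (1.0 - f) if f < 1.0 else np.inf
    return {
        "ratio": xi_count / xa_count,
        "ci_lo": to_ratio(lo),
        "ci_hi": to_ratio(hi),
        "inverted": False,
    }


def skew_from_cell_counts(n_pop1: int, n_pop2: int) -> tuple[int, int]:
    """Rounded percent split of informative cells between the two
    populations, e.g. (373, 315) -> (54, 46)."""
    if n_pop1 < 0 or n_pop2 < 0 or n_pop1 + n_pop2 < 1:
        raise ValueError("need at least one informative cell")
    p1 = round(100 * n_pop1 / (n_pop1 + n_pop2))
    return int(p1), int(100 - p1)
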