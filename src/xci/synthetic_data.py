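"""Synthetic generators for every input the XCI pipeline consumes.

The generators emulate the three study designs the analysis is built
around:

* a female donor with fully skewed XCI assayed by bulk RNA-seq across
  many tissues, where ~23% of X genes escape inactivation and Xi output
  at escape genes averages ~33% of Xa;
* single-cell RNA-seq of female cells where each cell has one parental X
  active (random choice per cell), monoallelic expression at inactive
  genes, per-allele dropout and a small allele-miscall rate (~2.5%, the
  empirical error bound used by the calling stages);
* population male/female expression matrices where escape produces
  female-biased expression and PAR1 genes (Xi/Xa near 0.80) come out
  male-biased, plus per-gene chromatin-state coverage matrices.

Ground truth is always returned alongside the data; calling stages must
never read it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GeneModel, PhasedGenotype, classify_region, ParConfig

_BASES = np.array(["A", "C", "G", "T"])

XIST_ID = "XIST"
# hg19 locus of XIST; the lncRNA expressed exclusively from Xi
_XIST_INTERVAL = (73_040_486, 73_072_588)


@dataclass
class SimConfig:
    """Parameters of the synthetic study designs.

    Defaults are the generative targets of the emulated designs: 23% of
    assessed X genes escaping (5.8 points of which escape in a single
    tissue only), mean Xi/Xa expression ratio 0.33 at nonPAR escape genes
    and 0.80 in PAR1, and a 2.5% allele-miscall rate.
    """

    n_genes: int = 500
    n_sites: int | None = None  # single-cell: exact site-count override
    escape_fraction: float = 0.23  # total incompletely inactivated fraction
    tissue_specific_escape_fraction: float = 0.058  # subset of the above
    xi_to_xa_mean: float = 0.33
    xi_concentration: float = 15.0  # Beta concentration on the Xi-fraction scale
    par1_xi_to_xa_mean: float = 0.80
    miscall_rate: float = 0.025
    n_tissues: int = 16
    n_cells: int = 200
    skew: float = 0.5  # fraction of cells with haplotype A active
    dropout_rate: float = 0.5  # per-allele, per cell-site
    depth_mean: float = 100.0  # bulk per-site per-tissue mean coverage
    depth_overdispersion: float = 10.0  # negative-binomial size
    cell_depth_mean: float = 30.0
    cell_depth_overdispersion: float = 2.0
    n_par1_genes: int = 15  # PAR1 genes assessed in the emulated design
    sites_per_gene_mean: float = 2.0  # Poisson, truncated >= 1
    include_xist: bool = True
    n_samples_per_sex: int = 80
    sex_noise_sd: float = 0.35  # log2 residual SD of expression
    n_states: int = 15
    n_escape_chromatin: int = 86
    n_inactive_chromatin: int = 399
    chromatin_shift_states: tuple[int, ...] = ()
    chromatin_shift_strength: float = 0.0  # multiplicative alpha boost
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "escape_fraction",
            "tissue_specific_escape_fraction",
            "miscall_rate",
            "skew",
            "dropout_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tissue_specific_escape_fraction > self.escape_fraction:
            raise ValueError("tissue_specific_escape_fraction exceeds escape_fraction")
        for name in ("n_genes", "n_tissues", "n_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed the way the pipeline
    reports results. Consumed only by tests and scoring, never by calls."""

    gene_status: dict[str, str] = field(default_factory=dict)
    xi_fraction: dict[str, float] = field(default_factory=dict)  # xi/(xi+xa)
    escape_tissue: dict[str, str] = field(default_factory=dict)
    site_gene: dict[str, str] = field(default_factory=dict)
    site_hap_a_allele: dict[str, str] = field(default_factory=dict)  # 'ref'|'alt'
    xi_haplotype: str = "B"  # skewed donor: which haplotype is inactive
    cell_active_hap: dict[str, str] = field(default_factory=dict)

    def xi_fraction_in(self, gene_id: str, tissue: str) -> float:
        """Planted Xi read fraction of a gene in one tissue."""
        status = self.gene_status.get(gene_id, "inactive")
        if status == "tissue_specific_escape":
            return self.xi_fraction[gene_id] if self.escape_tissue[gene_id] == tissue else 0.0
        if status in ("escape", "par1_escape", "xist"):
            return self.xi_fraction[gene_id]
        return 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1."""
    draws = rng.poisson(mean, size)
    while (zero := draws == 0).any():
        draws[zero] = rng.poisson(mean, int(zero.sum()))
    return draws


def _negbin(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, n)


def _xi_fraction_from_ratio_mean(
    rng: np.random.Generator, ratio_mean: float, concentration: float, n: int
) -> np.ndarray:
    """Draw per-gene Xi fractions from a Beta re-parameterized by the mean
    Xi/Xa ratio; bounded support matches the wide gene-to-gene variability
    in the degree of escape."""
    mean_frac = ratio_mean / (1.0 + ratio_mean)
    a = mean_frac * concentration
    b = (1.0 - mean_frac) * concentration
    return rng.beta(a, b, n)


def _build_genes(
    cfg: SimConfig, rng: np.random.Generator, par: ParConfig
) -> tuple[list[GeneModel], GroundTruth, dict[str, list[tuple[str, int]]]]:
    """Lay out genes on chrX, assign statuses and Xi fractions, and place
    heterozygous sites (truncated-Poisson count per gene)."""
    truth = GroundTruth()
    genes: list[GeneModel] = []
    gene_sites: dict[str, list[tuple[str, int]]] = {}

    n_par1 = min(cfg.n_par1_genes, cfg.n_genes)
    n_nonpar = cfg.n_genes - n_par1
    n_ts = int(round(cfg.tissue_specific_escape_fraction * n_nonpar))
    n_escape = int(round(cfg.escape_fraction * n_nonpar)) - n_ts
    statuses = (
        ["escape"] * n_escape
        + ["tissue_specific_escape"] * n_ts
        + ["inactive"] * (n_nonpar - n_escape - n_ts)
    )
    rng.shuffle(statuses)

    # nonPAR gene intervals spread over the X-specific region, avoiding the
    # XIST locus which is added explicitly
    span = 20_000
    starts = np.sort(
        rng.choice(
            np.arange(3_000_000, 154_000_000, 100_000), size=n_nonpar, replace=False
        )
    )
    par1_starts = np.sort(
        rng.choice(np.arange(par.par1[0] + 1000, par.par1[1] - span, 40_000), n_par1, replace=False)
    )

    frac_nonpar = _xi_fraction_from_ratio_mean(
        rng, cfg.xi_to_xa_mean, cfg.xi_concentration, n_nonpar
    )
    frac_par1 = _xi_fraction_from_ratio_mean(
        rng, cfg.par1_xi_to_xa_mean, cfg.xi_concentration, n_par1
    )
    tissues = [f"tissue_{t:02d}" for t in range(cfg.n_tissues)]

    def add_gene(gene_id: str, name: str, start: int, status: str, frac: float) -> None:
        gm = GeneModel(
            gene_id=gene_id,
            gene_name=name,
            chrom="X",
            start=int(start),
            end=int(start) + span,
            region_class=classify_region("X", int(start), int(start) + span, par),
        )
        genes.append(gm)
        truth.gene_status[gene_id] = status
        truth.xi_fraction[gene_id] = float(frac) if status != "inactive" else 0.0
        if status == "tissue_specific_escape":
            truth.escape_tissue[gene_id] = tissues[int(rng.integers(cfg.n_tissues))]

    for i in range(n_par1):
        add_gene(f"PARG{i:04d}", f"PARG{i:04d}", par1_starts[i], "par1_escape", frac_par1[i])
    for i in range(n_nonpar):
        add_gene(f"G{i:04d}", f"G{i:04d}", starts[i], statuses[i], frac_nonpar[i])
    if cfg.include_xist:
        gm = GeneModel(
            gene_id=XIST_ID,
            gene_name=XIST_ID,
            chrom="X",
            start=_XIST_INTERVAL[0],
            end=_XIST_INTERVAL[1],
            region_class="nonPAR_Xq",
        )
        genes.append(gm)
        truth.gene_status[XIST_ID] = "xist"
        truth.xi_fraction[XIST_ID] = 1.0

    n_sites_per_gene = _truncated_poisson(rng, cfg.sites_per_gene_mean, len(genes))
    budget = cfg.n_sites
    for gm, k in zip(genes, n_sites_per_gene):
        if budget is not None:
            k = min(int(k), budget)
            if k == 0:
                break
            budget -= k
        offsets = np.sort(rng.choice(np.arange(10, gm.end - gm.start), int(k), replace=False))
        sites = []
        for off in offsets:
            pos = gm.start + int(off)
            sid = f"{gm.chrom}:{pos}"
            sites.append((sid, pos))
            truth.site_gene[sid] = gm.gene_id
            truth.site_hap_a_allele[sid] = "ref" if rng.random() < 0.5 else "alt"
        gene_sites[gm.gene_id] = sites
    return genes, truth, gene_sites


def _genotypes_for(
    truth: GroundTruth,
    gene_sites: dict[str, list[tuple[str, int]]],
    rng: np.random.Generator,
    parental: bool,
) -> list[PhasedGenotype]:
    out = []
    for sites in gene_sites.values():
        for sid, pos in sites:
            ref, alt = rng.choice(_BASES, 2, replace=False)
            hap_a = ref if truth.site_hap_a_allele[sid] == "ref" else alt
            hap_b = alt if hap_a == ref else ref
            out.append(
                PhasedGenotype(
                    site_id=sid,
                    chrom="X",
                    pos=pos,
                    ref=str(ref),
                    alt=str(alt),
                    hap_a=str(hap_a),
                    hap_b=str(hap_b),
                    phased=True,
                    parental_origin_known=parental,
                )
            )
    return out


def _effective_xi_prob(f: float, miscall: float) -> float:
    # each read independently miscalled to the opposite allele
    return f * (1 - miscall) + (1 - f) * miscall


def simulate_skewed_donor(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, list[PhasedGenotype], list[GeneModel], GroundTruth]:
    """Bulk multi-tissue allelic counts for a fully skewed donor.

    Haplotype A is active (Xa) in every cell of every tissue; haplotype B
    is Xi. Inactive genes emit Xi-allele reads only through the miscall
    rate; escape genes emit Xi reads at their drawn per-gene fraction
    (tissue-specific escapers in exactly one tissue); XIST emits from Xi
    only.
    """
    rng = np.random.default_rng(cfg.seed)
    par = ParConfig.grch37()
    genes, truth, gene_sites = _build_genes(cfg, rng, par)
    truth.xi_haplotype = "B"
    genotypes = _genotypes_for(truth, gene_sites, rng, parental=False)
    allele_of = {g.site_id: g for g in genotypes}
    tissues = [f"tissue_{t:02d}" for t in range(cfg.n_tissues)]

    rows = []
    for gm in genes:
        for sid, pos in gene_sites.get(gm.gene_id, []):
            g = allele_of[sid]
            xi_allele = g.hap_b  # haplotype B carries Xi
            for tissue in tissues:
                f = truth.xi_fraction_in(gm.gene_id, tissue)
                total = int(_negbin(rng, cfg.depth_mean, cfg.depth_overdispersion, 1)[0])
                if total == 0:
                    continue
                xi_reads = int(rng.binomial(total, _effective_xi_prob(f, cfg.miscall_rate)))
                ref_count = xi_reads if xi_allele == g.ref else total - xi_reads
                rows.append(
                    {
                        "chrom": "X",
                        "pos": pos,
                        "site_id": sid,
                        "ref_allele": g.ref,
                        "alt_allele": g.alt,
                        "unit_id": tissue,
                        "ref_count": ref_count,
                        "alt_count": total - ref_count,
                    }
                )
    counts = pd.DataFrame(rows)
    counts["other_bases"] = False
    return counts, genotypes, genes, truth


def simulate_single_cells(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, list[PhasedGenotype], list[GeneModel], GroundTruth]:
    """Per-cell allelic counts with random XCI choice per cell.

    Each cell activates haplotype A with probability ``skew``. At inactive
    genes only the active-haplotype allele is transcribed; escape genes
    transcribe both with the gene's Xi fraction; XIST transcribes the
    inactive haplotype. Per-allele dropout then removes each allele's
    transcripts independently, and each surviving read is miscalled to the
    opposite allele with probability ``miscall_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    par = ParConfig.grch37()
    genes, truth, gene_sites = _build_genes(cfg, rng, par)
    genotypes = _genotypes_for(truth, gene_sites, rng, parental=True)
    allele_of = {g.site_id: g for g in genotypes}

    cells = [f"cell_{c:04d}" for c in range(cfg.n_cells)]
    active = np.where(rng.random(cfg.n_cells) < cfg.skew, "A", "B")
    truth.cell_active_hap = dict(zip(cells, (str(a) for a in active)))

    rows = []
    for ci, cell in enumerate(cells):
        act = active[ci]
        for gm in genes:
            for sid, pos in gene_sites.get(gm.gene_id, []):
                g = allele_of[sid]
                total = int(
                    _negbin(rng, cfg.cell_depth_mean, cfg.cell_depth_overdispersion, 1)[0]
                )
                if total == 0:
                    continue
                f = truth.xi_fraction.get(gm.gene_id, 0.0)
                if truth.gene_status[gm.gene_id] == "tissue_specific_escape":
                    # single-cell samples are one tissue context; treat the
                    # gene as escaping so that its Xi signal is present
                    f = truth.xi_fraction[gm.gene_id]
                xi_raw = int(rng.binomial(total, f))
                xa_raw = total - xi_raw
                if rng.random() < cfg.dropout_rate:
                    xa_raw = 0
                if rng.random() < cfg.dropout_rate:
                    xi_raw = 0
                if xa_raw + xi_raw == 0:
                    continue
                # miscalls flip reads between alleles
                xa_flip = int(rng.binomial(xa_raw, cfg.miscall_rate))
                xi_flip = int(rng.binomial(xi_raw, cfg.miscall_rate))
                xa_reads = xa_raw - xa_flip + xi_flip
                xi_reads = xi_raw - xi_flip + xa_flip
                # the active haplotype of this cell carries Xa reads
                act_allele = g.hap_a if act == "A" else g.hap_b
                ref_count = xa_reads if act_allele == g.ref else xi_reads
                alt_count = xi_reads if act_allele == g.ref else xa_reads
                rows.append(
                    {
                        "chrom": "X",
                        "pos": pos,
                        "site_id": sid,
                        "ref_allele": g.ref,
                        "alt_allele": g.alt,
                        "unit_id": cell,
                        "ref_count": ref_count,
                        "alt_count": alt_count,
                    }
                )
    counts = pd.DataFrame(rows)
    if len(counts):
        counts["other_bases"] = False
    return counts, genotypes, genes, truth


def simulate_sex_expression(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[GeneModel], GroundTruth]:
    """Male/female expression matrices with escape-driven sex bias.

    Expected female:male ratios — nonPAR escape: 1 + Xi/Xa ratio (two
    expressing X copies vs one); PAR1: (1 + Xi/Xa)/2 relative to the male
    X+Y output, hence male-biased when escape is partial; inactive: 1.
    Log-normal residual noise on the log2 scale.

    Returns (expression matrix genes x samples, sample sheet, per-gene
    true log2 female:male ratio per tissue, gene models, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    par = ParConfig.grch37()
    genes, truth, _ = _build_genes(cfg, rng, par)
    tissues = [f"tissue_{t:02d}" for t in range(cfg.n_tissues)]

    samples, sexes, tissue_col = [], [], []
    for t in tissues:
        for i in range(cfg.n_samples_per_sex):
            samples.append(f"{t}_F{i:03d}")
            sexes.append("female")
            tissue_col.append(t)
        for i in range(cfg.n_samples_per_sex):
            samples.append(f"{t}_M{i:03d}")
            sexes.append("male")
            tissue_col.append(t)
    sheet = pd.DataFrame({"sample": samples, "sex": sexes, "tissue": tissue_col})

    gene_ids = [g.gene_id for g in genes]
    base = rng.uniform(3.0, 8.0, len(genes))  # log2 baseline expression
    effect = np.zeros((len(genes), cfg.n_tissues))
    for gi, gm in enumerate(genes):
        status = truth.gene_status[gm.gene_id]
        frac = truth.xi_fraction[gm.gene_id]
        ratio = frac / (1.0 - frac) if frac < 1 else np.inf
        for ti, t in enumerate(tissues):
            if status in ("escape", "xist"):
                r = 1.0 + (ratio if np.isfinite(ratio) else 1.0)
            elif status == "tissue_specific_escape":
                r = 1.0 + ratio if truth.escape_tissue[gm.gene_id] == t else 1.0
            elif status == "par1_escape":
                r = (1.0 + ratio) / 2.0
            else:
                r = 1.0
            effect[gi, ti] = np.log2(r)

    female = np.array([s == "female" for s in sexes])
    t_index = np.array([tissues.index(t) for t in tissue_col])
    log2_expr = (
        base[:, None]
        + effect[:, t_index] * female[None, :]
        + rng.normal(0.0, cfg.sex_noise_sd, (len(genes), len(samples)))
    )
    expr = pd.DataFrame(2.0**log2_expr, index=gene_ids, columns=samples)
    true_effect = pd.DataFrame(effect, index=gene_ids, columns=tissues)
    return expr, sheet, true_effect, genes, truth


def simulate_chromatin_coverage(cfg: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene chromatin-state coverage fractions (rows sum to 1) for an
    escape and an inactive gene set, with an optional planted shift of a
    subset of states in the escape class."""
    rng = np.random.default_rng(cfg.seed)
    base_alpha = rng.uniform(0.5, 3.0, cfg.n_states)
    alpha_escape = base_alpha.copy()
    for s in cfg.chromatin_shift_states:
        alpha_escape[s] *= 1.0 + cfg.chromatin_shift_strength
    n_e, n_i = cfg.n_escape_chromatin, cfg.n_inactive_chromatin
    cov = np.vstack(
        [rng.dirichlet(alpha_escape, n_e), rng.dirichlet(base_alpha, n_i)]
    )
    gene_ids = [f"E{i:04d}" for i in range(n_e)] + [f"I{i:04d}" for i in range(n_i)]
    labels = pd.Series(["escape"] * n_e + ["inactive"] * n_i, index=gene_ids, name="status")
    df = pd.DataFrame(cov, index=gene_ids, columns=[f"state_{s + 1}" for s in range(cfg.n_states)])
    return df, labels
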