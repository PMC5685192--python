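"""Readers and writers for the external formats the pipeline consumes.

Coordinate conventions: VCF and allelic-count tables are 1-based; BED is
ingested as 0-based half-open and converted to 1-based inclusive on read.
Allele-count dialects are declared, never sniffed — silently misparsing a
count column is the worst failure mode for an allelic-imbalance analysis.
Indels are always excluded: the analysis is restricted to biallelic SNPs
because of mapping bias against indels in RNA-seq.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

RegionClass = Literal["PAR1", "PAR2", "nonPAR_Xp", "nonPAR_Xq", "autosome", "chrY"]

#: canonical column order of an AlleleCountTable
ALLELE_COUNT_COLUMNS = [
    "chrom",
    "pos",
    "site_id",
    "ref_allele",
    "alt_allele",
    "unit_id",
    "ref_count",
    "alt_count",
]

_BASES = {"A", "C", "G", "T"}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class ParConfig:
    """PAR1/PAR2 boundaries plus the Xp/Xq split (1-based inclusive)."""

    par1: tuple[int, int]
    par2: tuple[int, int]
    xp_xq_boundary: int
    chrom: str = "X"

    @classmethod
    def grch37(cls) -> "ParConfig":
        with resources.files("xci.data").joinpath("par_grch37.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls(
            par1=(raw["PAR1"]["start"], raw["PAR1"]["end"]),
            par2=(raw["PAR2"]["start"], raw["PAR2"]["end"]),
            xp_xq_boundary=raw["xp_xq_boundary"],
            chrom=str(raw["PAR1"]["chrom"]),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            par1=(raw["PAR1"]["start"], raw["PAR1"]["end"]),
            par2=(raw["PAR2"]["start"], raw["PAR2"]["end"]),
            xp_xq_boundary=raw["xp_xq_boundary"],
            chrom=str(raw["PAR1"].get("chrom", "X")),
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with its X-chromosome region class."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    region_class: RegionClass

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class PhasedGenotype:
    """One biallelic heterozygous SNP with its two haplotype alleles.

    ``hap_a``/``hap_b`` are the first/second haplotype in the VCF GT field.
    When the genotype comes from trio phasing, haplotype A is the maternal
    (transmitted-from-mother) allele by the usual convention.
    """

    site_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hap_a: str
    hap_b: str
    phased: bool
    parental_origin_known: bool = False

    def __post_init__(self) -> None:
        alleles = {self.ref, self.alt}
        if self.hap_a not in alleles or self.hap_b not in alleles:
            raise ValueError(f"{self.site_id}: haplotype alleles must be ref or alt")
        if self.hap_a == self.hap_b:
            raise ValueError(f"{self.site_id}: not heterozygous")

    @property
    def maternal_allele(self) -> str:
        return self.hap_a

    @property
    def paternal_allele(self) -> str:
        return self.hap_b


@dataclass
class SiteFilterConfig:
    """Conservative site/observation filters applied before any calling."""

    blacklist: set = field(default_factory=set)
    min_total_reads: int = 0
    exclude_indels: bool = True

    def __post_init__(self) -> None:
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be >= 0")


def classify_region(chrom: str, start: int, end: int, par: ParConfig | None = None) -> RegionClass:
    """Assign a gene interval to PAR1/PAR2/nonPAR_Xp/nonPAR_Xq/autosome/chrY.

    A gene is pseudoautosomal when it lies wholly within a PAR interval;
    Xp vs Xq is split at the configured centromere boundary.
    """
    par = par or ParConfig.grch37()
    c = chrom.removeprefix("chr")
    if c == "Y":
        return "chrY"
    if c != par.chrom:
        return "autosome"
    if par.par1[0] <= start and end <= par.par1[1]:
        return "PAR1"
    if par.par2[0] <= start and end <= par.par2[1]:
        return "PAR2"
    return "nonPAR_Xp" if end < par.xp_xq_boundary else "nonPAR_Xq"


def validate_allele_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Check AlleleCountTable invariants; returns the table for chaining."""
    missing = [c for c in ALLELE_COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(table):
        if (table["ref_count"] < 0).any() or (table["alt_count"] < 0).any():
            raise ValueError("negative read counts")
        dup = table.duplicated(subset=["site_id", "unit_id"])
        if dup.any():
            raise ValueError(f"duplicate (site_id, unit_id) rows: {table.loc[dup, 'site_id'].head().tolist()}")
        bad = ~(table["ref_allele"].isin(_BASES) & table["alt_allele"].isin(_BASES))
        if bad.any():
            raise ValueError("non-SNP alleles present (biallelic SNPs only)")
    return table


def read_allele_counts(
    path: str | Path,
    dialect: Literal["asereadcounter_tsv", "generic_tsv"],
    unit_id: str | None = None,
) -> pd.DataFrame:
    """Read per-site allelic read counts into an AlleleCountTable.

    ``asereadcounter_tsv`` is the GATK ASEReadCounter layout (contig,
    position, variantID, refAllele, altAllele, refCount, altCount,
    totalCount, ...); it carries one observation unit per file, so
    ``unit_id`` names that tissue sample or cell. ``generic_tsv`` is this
    package's long layout with an explicit unit_id column.

    Rows whose totalCount exceeds refCount + altCount (reads supporting
    other bases) are kept with their ref/alt counts and flagged in the
    ``other_bases`` column.
    """
    path = Path(path)
    if dialect == "asereadcounter_tsv":
        if unit_id is None:
            raise ValueError("asereadcounter_tsv carries one unit per file: pass unit_id")
        required = [
            "contig",
            "position",
            "variantID",
            "refAllele",
            "altAllele",
            "refCount",
            "altCount",
            "totalCount",
        ]
        try:
            raw = pd.read_csv(path, sep="\t", dtype={"contig": str})
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{path}: {exc}") from exc
        missing = [c for c in required if c not in raw.columns]
        if missing:
            raise ParseError(f"{path}: missing ASEReadCounter columns {missing}")
        _check_integer_columns(raw, ["position", "refCount", "altCount", "totalCount"], path)
        table = pd.DataFrame(
            {
                "chrom": raw["contig"].astype(str),
                "pos": raw["position"].astype(int),
                "site_id": raw["variantID"].astype(str),
                "ref_allele": raw["refAllele"].astype(str),
                "alt_allele": raw["altAllele"].astype(str),
                "unit_id": unit_id,
                "ref_count": raw["refCount"].astype(int),
                "alt_count": raw["altCount"].astype(int),
            }
        )
        table["other_bases"] = (
            raw["totalCount"].astype(int) > table["ref_count"] + table["alt_count"]
        )
    elif dialect == "generic_tsv":
        try:
            raw = pd.read_csv(path, sep="\t", dtype={"chrom": str, "unit_id": str, "site_id": str})
        except Exception as exc:  # pragma: no cover
            raise ParseError(f"{path}: {exc}") from exc
        missing = [c for c in ALLELE_COUNT_COLUMNS if c not in raw.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        _check_integer_columns(raw, ["pos", "ref_count", "alt_count"], path)
        table = raw.copy()
        table["pos"] = table["pos"].astype(int)
        table["ref_count"] = table["ref_count"].astype(int)
        table["alt_count"] = table["alt_count"].astype(int)
        if "other_bases" not in table.columns:
            table["other_bases"] = False
    else:
        raise ValueError(f"unknown dialect {dialect!r} (dialects are never sniffed)")
    # empty-with-header files produce an empty, valid table
    if (table["ref_count"] < 0).any() or (table["alt_count"] < 0).any():
        bad = table[(table["ref_count"] < 0) | (table["alt_count"] < 0)].index[0]
        raise ValueError(f"{path}: negative read count at data row {bad + 1}")
    return validate_allele_counts(table[ALLELE_COUNT_COLUMNS + ["other_bases"]])


def _check_integer_columns(raw: pd.DataFrame, cols: list[str], path: Path) -> None:
    for col in cols:
        if len(raw) and not pd.api.types.is_integer_dtype(raw[col]):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise ParseError(f"{path}: malformed {col!r} at line {line}")
            raw[col] = coerced.astype(int)


def write_allele_counts(table: pd.DataFrame, path: str | Path) -> None:
    """Write an AlleleCountTable in the generic long TSV dialect (1-based)."""
    cols = ALLELE_COUNT_COLUMNS + (["other_bases"] if "other_bases" in table.columns else [])
    table[cols].to_csv(path, sep="\t", index=False)


def read_phased_vcf(path: str | Path, sample: str) -> list[PhasedGenotype]:
    """Extract biallelic heterozygous SNP genotypes for one sample.

    Multiallelic sites and indels are skipped with a log message; the phase
    flag is read from the VCF phase separator ('|' vs '/').
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise ValueError(f"sample {sample!r} not in VCF (has {vcf.samples})")
    si = vcf.samples.index(sample)
    out: list[PhasedGenotype] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        g = var.genotypes[si]  # [allele_a, allele_b, phased]
        a, b, phased = g[0], g[1], bool(g[2])
        if a < 0 or b < 0 or a == b:  # missing or homozygous
            continue
        alleles = [var.REF, var.ALT[0]]
        out.append(
            PhasedGenotype(
                site_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref=var.REF,
                alt=var.ALT[0],
                hap_a=alleles[a],
                hap_b=alleles[b],
                phased=phased,
            )
        )
    if n_skipped:
        logger.info("read_phased_vcf: skipped %d multiallelic/indel sites", n_skipped)
    return out


def write_vcf(genotypes: Iterable[PhasedGenotype], path: str | Path, sample: str) -> None:
    """Write a minimal single-sample VCF 4.2 with phased GT fields."""
    gts = sorted(genotypes, key=lambda g: (g.chrom, g.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({g.chrom for g in gts})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for g in gts:
            a = 0 if g.hap_a == g.ref else 1
            b = 0 if g.hap_b == g.ref else 1
            sep = "|" if g.phased else "/"
            fh.write(
                f"{g.chrom}\t{g.pos}\t{g.site_id}\t{g.ref}\t{g.alt}\t.\tPASS\t.\tGT\t{a}{sep}{b}\n"
            )


def read_gene_models_bed(path: str | Path, par: ParConfig | None = None) -> list[GeneModel]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)
    and classify each into a chrX region class. Column 4 is the gene_id;
    an optional column 7 supplies a distinct gene_name."""
    par = par or ParConfig.grch37()
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >= 4 columns")
            chrom, start0, end0, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start = int(start0) + 1
                end = int(end0)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            gene_name = parts[6] if len(parts) >= 7 and parts[6] else name
            genes.append(
                GeneModel(
                    gene_id=name,
                    gene_name=gene_name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    region_class=classify_region(chrom, start, end, par),
                )
            )
    return genes


def write_gene_models_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 + gene_name (1-based inclusive -> 0-based)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t+\t{g.gene_name}\n")


def apply_site_filters(table: pd.DataFrame, config: SiteFilterConfig) -> pd.DataFrame:
    """Remove blacklisted sites, low-coverage observations and (by default)
    indels. Idempotent; row counts are logged at each step."""
    validate_allele_counts(table)
    n0 = len(table)
    out = table[~table["site_id"].isin(config.blacklist)]
    n1 = len(out)
    total = out["ref_count"] + out["alt_count"]
    out = out[total >= config.min_total_reads]
    n2 = len(out)
    if config.exclude_indels:
        out = out[
            (out["ref_allele"].str.len() == 1) & (out["alt_allele"].str.len() == 1)
        ]
    logger.info(
        "apply_site_filters: %d rows -> %d after blacklist -> %d after coverage -> %d final",
        n0,
        n1,
        n2,
        len(out),
    )
    return out.reset_index(drop=True)


def map_sites_to_genes(table: pd.DataFrame, genes: Iterable[GeneModel]) -> pd.Series:
    """Map each site_id to the gene whose interval contains it.

    Returns a Series indexed by site_id; sites in no gene are absent. When
    gene intervals overlap the gene starting first wins (deterministic).
    """
    sites = table[["site_id", "chrom", "pos"]].drop_duplicates("site_id")
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start))
    mapping: dict[str, str] = {}
    for _, row in sites.iterrows():
        for g in ordered:
            if g.contains(row["chrom"], row["pos"]):
                mapping[row["site_id"]] = g.gene_id
                break
    return pd.Series(mapping, name="gene_id")


def read_catalog_csv(path: str | Path) -> pd.DataFrame:
    """Read a prior XCI-status catalogue (gene_id, gene_name, status, source)."""
    df = pd.read_csv(path)
    required = {"gene_id", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing catalogue columns {sorted(missing)}")
    if "gene_name" not in df.columns:
        df["gene_name"] = df["gene_id"]
    if "source" not in df.columns:
        df["source"] = str(path)
    return df[["gene_id", "gene_name", "status", "source"]]


def write_catalog_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
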