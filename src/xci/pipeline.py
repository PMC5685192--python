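"""End-to-end orchestration: simulate inputs, run the calling stages, and
write a manifest recording inputs, config, seed and output hashes so a
rerun with the same seed is verifiably identical."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__, single_cell, skewed_donor
from .io_formats import write_allele_counts, write_gene_models_bed, write_vcf
from .synthetic_data import (
    SimConfig,
    simulate_single_cells,
    simulate_skewed_donor,
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_demo(out_dir: str | Path, seed: int = 0, n_genes: int = 120, n_cells: int = 80) -> dict:
    """One-command synthetic demo: generate a skewed-donor and a
    single-cell data set, run both calling pipelines, and write all
    outputs plus a manifest. Returns the manifest dict."""
    out = Path(out_dir)
    data_dir = out / "data"
    truth_dir = out / "ground_truth"  # pipelines must never read from here
    results_dir = out / "results"
    for d in (data_dir, truth_dir, results_dir):
        d.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"tool": "xci", "version": __version__, "seed": seed, "outputs": {}}

    donor_cfg = SimConfig(n_genes=n_genes, seed=seed)
    counts, genotypes, genes, truth = simulate_skewed_donor(donor_cfg)
    write_allele_counts(counts, data_dir / "donor_ase.tsv")
    write_gene_models_bed(genes, data_dir / "genes.bed")
    write_vcf(genotypes, data_dir / "donor.vcf", sample="DONOR")
    truth.to_json(truth_dir / "donor_truth.json")

    calls, classification = skewed_donor.run_donor_pipeline(counts, genes)
    calls.to_csv(results_dir / "donor_per_tissue_calls.tsv", sep="\t", index=False)
    classification.to_csv(results_dir / "donor_gene_status.tsv", sep="\t", index=False)

    sc_cfg = SimConfig(n_genes=n_genes, n_cells=n_cells, skew=0.5, seed=seed + 1)
    sc_counts, sc_genotypes, sc_genes, sc_truth = simulate_single_cells(sc_cfg)
    write_allele_counts(sc_counts, data_dir / "cells_ase.tsv")
    write_vcf(sc_genotypes, data_dir / "trio_phased.vcf", sample="PROBAND")
    sc_truth.to_json(truth_dir / "cells_truth.json")

    cfg = single_cell.ScCallingConfig()
    par1 = single_cell.par1_site_ids(sc_counts, sc_genes)
    xist_sites = {
        s for s, g in sc_truth.site_gene.items() if g == "XIST"
    }
    exclusions = (
        single_cell.identify_frequently_biallelic_sites(sc_counts, cfg, par1) | xist_sites
    )
    assignments, phase = single_cell.infer_partition_unphased(sc_counts, exclusions, seed=seed)
    site_to_gene = pd.Series(sc_truth.site_gene)
    per_gene = single_cell.aggregate_xa_xi(sc_counts, assignments, phase, site_to_gene)
    sc_calls = single_cell.call_xci_from_cells(per_gene, cfg, sample_id="demo")
    pd.DataFrame([asdict(a) for a in assignments]).to_csv(
        results_dir / "cell_assignments.tsv", sep="\t", index=False
    )
    sc_calls.to_csv(results_dir / "sc_gene_status.tsv", sep="\t", index=False)

    manifest["config"] = {"donor": asdict(donor_cfg), "cells": asdict(sc_cfg)}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
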