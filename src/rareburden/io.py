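"""File formats, configuration and pipeline orchestration.

Tables are tab-separated UTF-8 with a header row; genotypes travel as
minimal VCF 4.2 (GT only, missing as "./."); truth/provenance metadata as
JSON.  Multi-allelic VCF records are decomposed into bi-allelic records on
read, one per alternate allele.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .classify import classify_variants, clinvar_triage
from .errors import ConfigurationError
from .sampleqc import QCThresholds, run_qc_cascade
from .simulate import (CohortDesign, OutlierSpec, PhenotypeModel,
                       make_reference_pcs, simulate_annotations,
                       simulate_case_control, simulate_haplotype_pool,
                       simulate_qc_metrics, simulate_reference_panels)
from .tiers import (AnalysisDataset, default_gene_tiers, run_gene_tests,
                    run_tier_tests, summarize)

logger = logging.getLogger(__name__)

__all__ = ["read_vcf", "write_vcf", "PipelineConfig", "run_pipeline",
           "generate_dataset", "write_dataset", "read_tsv", "write_tsv"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def read_vcf(path):
    """Read a VCF with GT fields into (variants DataFrame, dosage matrix,
    sample ids).

    Multi-allelic sites become one bi-allelic record per alternate allele
    (records share the position); dosages are 0/1/2 with NaN for missing.
    """
    path = str(path)
    vf = pysam.VariantFile(path)
    sample_ids = list(vf.header.samples)
    rows, dosages = [], []
    for rec in vf:
        if "GT" not in rec.format:
            raise ValueError(f"record at {rec.chrom}:{rec.pos} has no GT field")
        alts = rec.alts or ()
        gts = [rec.samples[s].get("GT") for s in sample_ids]
        for ai, alt in enumerate(alts, start=1):
            dose = np.full(len(sample_ids), np.nan)
            for si, gt in enumerate(gts):
                if gt is None or any(a is None for a in gt):
                    continue
                dose[si] = sum(1 for a in gt if a == ai)
            rows.append({"chrom": rec.chrom, "pos": rec.pos,
                         "id": rec.id or ".", "ref": rec.ref, "alt": alt})
            dosages.append(dose)
    vf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    G = np.array(dosages).T if dosages else np.empty((len(sample_ids), 0))
    return variants, G, sample_ids


def write_vcf(path, variants: pd.DataFrame, G: np.ndarray, sample_ids):
    """Write a minimal VCF 4.2 (GT only; missing as "./.")."""
    G = np.asarray(G, dtype=float)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, (_, v) in enumerate(variants.iterrows()):
            gts = [gt_map.get(G[i, j], "./.") if np.isfinite(G[i, j]) else "./."
                   for i in range(len(sample_ids))]
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v.get('id', '.')}\t"
                     f"{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# synthetic dataset bundle
# ---------------------------------------------------------------------------

def generate_dataset(seed: int, n_genes: int = 8, n_cases_ts: int = 120,
                     n_cases_wes: int = 60, n_controls: int = 120,
                     n_haplotypes: int = 2000, region_per_gene: int = 3000,
                     causal_fraction: float = 0.0,
                     baseline_prevalence: float = 0.05,
                     outlier_spec: OutlierSpec | None = None) -> dict:
    """Generate a complete, coherent synthetic input bundle in memory.

    The gene map chops the simulated region into ``n_genes`` contiguous
    blocks, assigned round-robin to the six tiers.  Returns a dict with the
    pool, genotypes, sample/annotation/panel/QC/IBD tables and the truth
    record.
    """
    rng = np.random.default_rng(seed)
    region = n_genes * region_per_gene
    pool = simulate_haplotype_pool(n_haplotypes, region,
                                   seed=int(rng.integers(2**31)))
    tiers = default_gene_tiers()
    gene_names = tiers["gene"].sample(
        n=n_genes, random_state=int(rng.integers(2**31))).tolist()
    gene_of_site = np.minimum(
        (pool.site_positions - 1) // region_per_gene, n_genes - 1)

    model = PhenotypeModel(baseline_prevalence=baseline_prevalence,
                           causal_fraction=causal_fraction)
    design = CohortDesign(n_cases_ts=n_cases_ts, n_cases_wes=n_cases_wes,
                          n_controls=n_controls)
    G, samples, truth = simulate_case_control(
        pool, model, design, seed=int(rng.integers(2**31)))

    variants = pd.DataFrame({
        "chrom": "1", "pos": pool.site_positions,
        "ref": pool.site_ref, "alt": pool.site_alt,
        "gene": [gene_names[g] for g in gene_of_site],
        "site_index": np.arange(pool.n_sites),
        "g_index": np.arange(pool.n_sites),
    })
    annotations = simulate_annotations(variants,
                                       seed=int(rng.integers(2**31)))
    panels = simulate_reference_panels(pool, seed=int(rng.integers(2**31)))
    qc, ibd, qc_truth = simulate_qc_metrics(
        samples["sample_id"], outlier_spec or OutlierSpec(),
        seed=int(rng.integers(2**31)))
    qc = qc.merge(samples, on="sample_id")
    gene_tiers = tiers[tiers["gene"].isin(gene_names)].reset_index(drop=True)
    truth["qc"] = qc_truth
    return {"pool": pool, "genotypes": G, "samples": samples,
            "variants": variants, "annotations": annotations,
            "panels": panels, "qc": qc, "ibd": ibd,
            "gene_tiers": gene_tiers, "truth": truth}


def write_dataset(bundle: dict, outdir, seed: int | None = None):
    """Write a generated bundle to disk (VCF + TSVs + truth JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    v = bundle["variants"].assign(id=".")
    write_vcf(out / "genotypes.vcf", v, bundle["genotypes"],
              bundle["samples"]["sample_id"].tolist())
    write_tsv(bundle["annotations"], out / "annotations.tsv")
    write_tsv(bundle["panels"], out / "panels.tsv")
    write_tsv(bundle["qc"], out / "qc.tsv")
    write_tsv(bundle["ibd"], out / "ibd.tsv")
    write_tsv(bundle["gene_tiers"], out / "gene_tiers.tsv")
    truth = dict(bundle["truth"])
    if seed is not None:
        truth["seed"] = seed
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    vcf: str = ""
    annotations: str = ""
    panels: str = ""
    qc: str = ""
    ibd: str = ""
    gene_tiers: str = ""
    outdir: str = "results"
    seed: int = 0
    known_genes: list = field(default_factory=list)
    freemix_threshold: float = 0.03
    ibd_threshold: float = 0.1875
    ancestry_k_sd: float = 6.0
    pooled_rule: str = "allele_counts"
    run_triage: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """classify -> qc -> association -> tiers, with stage-count logging.

    All input paths are validated before any stage runs.  Writes the
    classification, QC-exclusion and report tables under ``config.outdir``
    and returns them in a dict.
    """
    paths = {k: getattr(config, k)
             for k in ("vcf", "annotations", "panels", "qc", "ibd", "gene_tiers")}
    missing = [k for k, p in paths.items() if not p or not Path(p).exists()]
    if missing:
        raise ConfigurationError(f"missing input files: {missing}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    variants, G, sample_ids = read_vcf(config.vcf)
    annotations = read_tsv(config.annotations)
    panels = read_tsv(config.panels)
    qc = read_tsv(config.qc)
    ibd = read_tsv(config.ibd)
    gene_tiers = read_tsv(config.gene_tiers)
    logger.info("loaded %d variants x %d samples", len(variants), len(sample_ids))

    classified = classify_variants(annotations, panels,
                                   known_genes=config.known_genes,
                                   pooled_rule=config.pooled_rule)
    classified["g_index"] = np.arange(len(classified))
    write_tsv(classified, out / "classified_variants.tsv")

    thr = QCThresholds(freemix=config.freemix_threshold,
                       ibd=config.ibd_threshold,
                       ancestry_k_sd=config.ancestry_k_sd)
    qc_res = run_qc_cascade(qc, ibd, make_reference_pcs(seed=config.seed),
                            thresholds=thr)
    write_tsv(qc_res.exclusions, out / "qc_exclusions.tsv")
    for stage, n in qc_res.stage_counts.items():
        logger.info("stage %-12s: %d", stage, n)

    order = [i for i, sid in enumerate(sample_ids)
             if sid in qc_res.retained]
    retained_ids = [sample_ids[i] for i in order]
    samples = qc.set_index("sample_id").loc[retained_ids].reset_index()
    dataset = AnalysisDataset(genotypes=G[order], samples=samples,
                              variants=classified)

    rows = []
    for gene, sub in gene_tiers.groupby("gene", sort=True):
        rows += run_gene_tests(dataset, gene, tier=sub["tier"].iloc[0])
    rows += run_tier_tests(dataset, gene_tiers)
    table1, fig5 = summarize(rows)
    write_tsv(table1, out / "table1_report.tsv")
    write_tsv(fig5, out / "scenario_report.tsv")

    result = {"classified": classified, "qc": qc_res, "table1": table1,
              "fig5": fig5, "stage_counts": qc_res.stage_counts}
    if config.run_triage:
        triaged = clinvar_triage(classified)
        write_tsv(triaged, out / "triage.tsv")
        result["triage"] = triaged
    return result
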