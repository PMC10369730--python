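"""End-to-end per-disease orchestration.

One run chains: GWAS SNP assembly (significance + LD-proxy filters) ->
motif preparation (pseudocounts, entropy trimming, per-motif null-scale
calibration on a null SNP panel) -> differential-binding scan (rSNP calls)
-> regulatory-element overlap and gene linking -> coding/non-coding
classification and per-gene statistics -> disease enrichment of the coding
genes -> co-expression partners of the non-coding genes and enrichment of
their union. Every stage writes its table under the output directory and
logs its counts.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression as cx
from . import diffbind as db
from . import enrichment as en
from . import gwas
from . import linking
from .genome import Genome
from .motifs import counts_to_pwm, read_motifs, trim_flanks

log = logging.getLogger("rsnpscan")


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run."""

    genome: str
    motifs: str
    associations: str
    proxies: str
    null_snps: str          # null SNP panel for per-motif scale estimation
    rems: str
    annotation: str
    expression: str
    disease_catalog: str
    out_dir: str = "results"
    diseases: list[str] = field(default_factory=list)

    gwas_alpha: float = 1e-5
    r2_min: float = 0.75
    window: int = 500_000
    entropy_trim: float = 1.9
    pseudocount: float = 0.25
    p_bind_max: float = 0.5
    p_diff_max: float = 0.001
    k_coexpr: int = 10
    fdr: float = 0.05
    min_query: int = 30
    n_null_scale: int = 200_000   # panel cap; desk-scale files are smaller
    seed: int = 123
    motif_dialect: str = "transfac"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class DiseaseResult:
    """Per-disease output bundle (tables of every pipeline stage)."""

    disease: str
    input_snps: pd.DataFrame
    scan_results: pd.DataFrame
    rsnp_ids: list[str]
    links: pd.DataFrame
    gene_stats: pd.DataFrame
    category_counts: dict[str, int]
    coding_enrichment: en.EnrichmentOutcome
    coexpr_partners: pd.DataFrame
    coexpr_union: set[str]
    coexpr_enrichment: en.EnrichmentOutcome


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def prepare_motifs(cfg: PipelineConfig, genome: Genome
                   ) -> tuple[list, dict[str, db.MotifNullModel]]:
    """Read, trim and calibrate motifs; uncalibrated motifs are excluded."""
    counts = read_motifs(cfg.motifs, dialect=cfg.motif_dialect)
    pwms = []
    for m in counts:
        pwm = trim_flanks(counts_to_pwm(m, pseudocount=cfg.pseudocount),
                          threshold=cfg.entropy_trim)
        if len(pwm) == 0:
            log.warning("motif %s fully trimmed, excluded", m.id)
            continue
        pwms.append(pwm)
    panel = gwas.snps_from_frame(
        gwas.read_snps_tsv(cfg.null_snps).head(cfg.n_null_scale))
    models: dict[str, db.MotifNullModel] = {}
    kept = []
    for pwm in pwms:
        model = db.estimate_scale(pwm, genome, panel)
        if model.calibrated:
            models[pwm.id] = model
            kept.append(pwm)
        else:
            log.warning("motif %s uncalibrated, excluded from scanning",
                        pwm.id)
    log.info("motifs: %d read, %d calibrated", len(counts), len(kept))
    return kept, models


def run_disease(cfg: PipelineConfig, disease: str,
                genome: Genome | None = None,
                pwms=None, null_models=None) -> DiseaseResult:
    """Run the full pipeline for one disease and write its tables."""
    out = Path(cfg.out_dir) / disease.replace(" ", "_")
    out.mkdir(parents=True, exist_ok=True)
    if genome is None:
        genome = Genome(cfg.genome)
    if pwms is None or null_models is None:
        pwms, null_models = prepare_motifs(cfg, genome)

    # stage 1: GWAS SNP assembly
    assoc = gwas.read_associations(cfg.associations)
    assoc = assoc[assoc["disease"] == disease]
    leads = gwas.filter_significant(assoc, alpha=cfg.gwas_alpha)
    proxies = gwas.read_proxies(cfg.proxies)
    snp_table = gwas.merge_proxies(leads, proxies, r2_min=cfg.r2_min,
                                   window=cfg.window)
    snp_table.to_csv(out / "input_snps.tsv", sep="\t", index=False)
    log.info("%s: %d leads, %d input SNPs", disease, len(leads),
             len(snp_table))

    # stage 2: differential-binding scan
    snps = gwas.snps_from_frame(snp_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = db.scan_snps(snps, pwms, genome, null_models,
                               p_bind_max=cfg.p_bind_max,
                               p_diff_max=cfg.p_diff_max)
    scan_df = db.results_to_frame(results)
    scan_df.to_csv(out / "scan_results.tsv", sep="\t", index=False)
    rsnp_ids = sorted(scan_df["snp_id"].unique()) if not scan_df.empty else []
    log.info("%s: %d rSNPs from %d emitted pairs", disease, len(rsnp_ids),
             len(scan_df))

    # stage 3: gene linking
    rems = linking.read_rem_catalog(cfg.rems)
    rsnp_rows = snp_table[snp_table["rsid"].isin(rsnp_ids)]
    links = linking.overlap_snps_rems(rsnp_rows, rems)
    links.to_csv(out / "rsnp_rem_links.tsv", sep="\t", index=False)

    annotation = linking.read_annotation(cfg.annotation)
    catalog = en.read_term_catalog(cfg.disease_catalog)
    known = set(catalog["gene_id"])
    gene_stats = linking.aggregate_gene_stats(links, annotation,
                                              disease_genes=known,
                                              disease=disease)
    gene_stats.to_csv(out / "gene_associations.tsv", sep="\t", index=False)
    counts = linking.category_counts(gene_stats)
    log.info("%s: %d genes (%d coding / %d noncoding)", disease,
             len(gene_stats), counts["coding"], counts["noncoding"])

    # stage 4: enrichment of directly associated coding genes
    universe = set(annotation["gene_id"])
    coding_genes = set(
        gene_stats.loc[gene_stats["biotype_class"] == "coding", "gene_id"])
    coding_enr = en.run_set_enrichment(coding_genes, catalog, universe,
                                       min_query=cfg.min_query,
                                       fdr_threshold=cfg.fdr)
    if not coding_enr.skipped:
        coding_enr.table.to_csv(out / "coding_enrichment.tsv", sep="\t",
                                index=False)
    else:
        (out / "coding_enrichment.SKIPPED").write_text(coding_enr.reason + "\n")

    # stage 5: co-expression guilt-by-association for non-coding genes
    noncoding = sorted(
        gene_stats.loc[gene_stats["biotype_class"] == "noncoding", "gene_id"])
    expr = cx.read_expression(cfg.expression)
    coding_ids = annotation.loc[
        annotation["biotype"].isin(linking.CODING_BIOTYPES),
        "gene_id"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        union, partner_lists = cx.coexpression_gene_set(
            noncoding, expr, coding_ids, k=cfg.k_coexpr)
    partners = cx.partners_to_frame(partner_lists)
    partners.to_csv(out / "coexpression_partners.tsv", sep="\t", index=False)

    coexpr_enr = en.run_set_enrichment(union, catalog, universe,
                                       min_query=cfg.min_query,
                                       fdr_threshold=cfg.fdr)
    if not coexpr_enr.skipped:
        coexpr_enr.table.to_csv(out / "coexpression_enrichment.tsv",
                                sep="\t", index=False)
    else:
        (out / "coexpression_enrichment.SKIPPED").write_text(
            coexpr_enr.reason + "\n")

    return DiseaseResult(
        disease=disease, input_snps=snp_table, scan_results=scan_df,
        rsnp_ids=rsnp_ids, links=links, gene_stats=gene_stats,
        category_counts=counts, coding_enrichment=coding_enr,
        coexpr_partners=partners, coexpr_union=union,
        coexpr_enrichment=coexpr_enr)


def run_all(cfg: PipelineConfig) -> list[DiseaseResult]:
    """Run every configured disease, sharing the motif calibration."""
    genome = Genome(cfg.genome)
    pwms, models = prepare_motifs(cfg, genome)
    diseases = cfg.diseases
    if not diseases:
        diseases = sorted(
            gwas.read_associations(cfg.associations)["disease"].unique())
    results = [run_disease(cfg, d, genome=genome, pwms=pwms,
                           null_models=models) for d in diseases]
    out = Path(cfg.out_dir)
    summary = summarize(results)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    write_manifest(cfg, out / "run_manifest.yaml")
    return results


def summarize(results: list[DiseaseResult]) -> pd.DataFrame:
    """Per-disease counts plus a pooled distinct-rSNP row.

    Pooled rSNPs are counted as distinct SNP ids across diseases, so the
    pooled value is at most the per-disease sum.
    """
    if not results:
        raise ValueError("need at least one disease result")
    rows = []
    pooled: set[str] = set()
    for r in results:
        pooled.update(r.rsnp_ids)
        rows.append({"disease": r.disease,
                     "n_input_snps": len(r.input_snps),
                     "n_rsnps": len(r.rsnp_ids),
                     "n_coding_genes": r.category_counts["coding"],
                     "n_noncoding_genes": r.category_counts["noncoding"]})
    df = pd.DataFrame(rows)
    df.attrs["pooled_rsnps"] = len(pooled)
    total = {"disease": "ALL (distinct)",
             "n_input_snps": int(df["n_input_snps"].sum()),
             "n_rsnps": len(pooled),
             "n_coding_genes": int(df["n_coding_genes"].sum()),
             "n_noncoding_genes": int(df["n_noncoding_genes"].sum())}
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def write_manifest(cfg: PipelineConfig, path: str | Path) -> None:
    """Run manifest: full configuration plus input checksums."""
    manifest = {"config": asdict(cfg), "input_checksums": {}}
    for key in ("genome", "motifs", "associations", "proxies", "null_snps",
                "rems", "annotation", "expression", "disease_catalog"):
        p = getattr(cfg, key)
        if p and Path(p).exists():
            manifest["input_checksums"][key] = _checksum(p)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
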