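"""Assembly of per-disease GWAS SNP input sets.

Lead SNPs are the genome-wide associations passing the significance filter
(p < 1e-5, strict); proxy SNPs in linkage disequilibrium with a lead
(R^2 >= 0.75, within +/-500 kb of the lead, both bounds inclusive) are
merged in. LD values are consumed from a precomputed proxy table — the
package never queries an LD service.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ASSOC_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "pvalue", "disease"]
PROXY_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "lead_rsid", "r2"]
SNP_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "gwas_p", "role",
               "lead_rsid", "r2", "disease"]


@dataclass
class SnpRecord:
    """One SNP in a disease input set (lead or LD proxy)."""

    rsid: str
    chrom: str
    pos: int            # 1-based
    ref: str
    alt: str
    gwas_p: float | None = None
    role: str = "lead"
    lead_rsid: str | None = None
    r2: float = 1.0
    disease: str | None = None

    def __post_init__(self) -> None:
        if self.role == "lead" and self.gwas_p is None:
            raise ValueError(f"{self.rsid}: lead SNP without a GWAS p-value")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"{self.rsid}: r2 {self.r2} outside [0, 1]")
        if self.lead_rsid is None:
            self.lead_rsid = self.rsid


def read_associations(path: str | Path) -> pd.DataFrame:
    """Read a GWAS association table (TSV with ASSOC_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    return df


def read_proxies(path: str | Path) -> pd.DataFrame:
    """Read an LD-proxy table (TSV with PROXY_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PROXY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"proxy table missing columns: {sorted(missing)}")
    return df


def filter_significant(associations: pd.DataFrame,
                       alpha: float = 1e-5) -> pd.DataFrame:
    """Keep associations with p strictly below ``alpha``.

    Rows without a p-value are dropped with a warning; duplicate rsids
    within a disease keep the record with the smallest p.
    """
    df = associations.copy()
    n_missing = df["pvalue"].isna().sum()
    if n_missing:
        warnings.warn(f"{n_missing} association rows without p-value dropped")
        df = df.dropna(subset=["pvalue"])
    bad = (df["pvalue"] < 0) | (df["pvalue"] > 1)
    if bad.any():
        raise ValueError("p-values outside [0, 1] in association table")
    df = df[df["pvalue"] < alpha]
    df = (df.sort_values(["disease", "rsid", "pvalue"])
            .drop_duplicates(subset=["disease", "rsid"], keep="first")
            .reset_index(drop=True))
    return df


def merge_proxies(leads: pd.DataFrame, proxy_table: pd.DataFrame,
                  r2_min: float = 0.75, window: int = 500_000) -> pd.DataFrame:
    """Union of lead SNPs and their qualifying LD proxies, deduplicated.

    A proxy qualifies when r2 >= ``r2_min`` and its position is within
    ``window`` bp of its lead (inclusive at both boundaries). A SNP seen as
    both lead and proxy keeps the lead role; a proxy to several leads keeps
    the assignment with the largest r2. Output is one row per (disease,
    rsid) in SNP_COLUMNS layout.
    """
    lead_rows = leads.rename(columns={"pvalue": "gwas_p"}).copy()
    lead_rows["role"] = "lead"
    lead_rows["lead_rsid"] = lead_rows["rsid"]
    lead_rows["r2"] = 1.0

    prox = proxy_table.merge(
        leads[["rsid", "pos", "disease"]].rename(
            columns={"rsid": "lead_rsid", "pos": "lead_pos"}),
        on="lead_rsid", how="left")
    unknown = prox["lead_pos"].isna()
    if unknown.any():
        warnings.warn(f"{int(unknown.sum())} proxies referencing unknown "
                      "leads dropped")
        prox = prox[~unknown]
    prox = prox[(prox["r2"] >= r2_min)
                & ((prox["pos"] - prox["lead_pos"]).abs() <= window)].copy()
    prox["gwas_p"] = float("nan")
    prox["role"] = "proxy"
    # a proxy linked to several leads appears once, at its max r2
    prox = (prox.sort_values(["disease", "rsid", "r2"],
                             ascending=[True, True, False])
                .drop_duplicates(subset=["disease", "rsid"], keep="first"))

    combined = pd.concat([lead_rows[SNP_COLUMNS], prox[SNP_COLUMNS]],
                         ignore_index=True)
    # lead role wins when the same rsid appears in both sets
    combined["_role_rank"] = (combined["role"] != "lead").astype(int)
    combined = (combined.sort_values(["disease", "rsid", "_role_rank"])
                        .drop_duplicates(subset=["disease", "rsid"],
                                         keep="first")
                        .drop(columns="_role_rank")
                        .reset_index(drop=True))
    return combined


def snps_from_frame(df: pd.DataFrame) -> list[SnpRecord]:
    """Materialize SnpRecord objects from a SNP table."""
    out = []
    for row in df.itertuples(index=False):
        gwas_p = getattr(row, "gwas_p", None)
        if gwas_p is not None and pd.isna(gwas_p):
            gwas_p = None
        role = getattr(row, "role", None)
        if role is None:
            # plain SNP panels (e.g. null SNPs for calibration) carry
            # neither role nor p-value
            role = "lead" if gwas_p is not None else "panel"
        out.append(SnpRecord(
            rsid=row.rsid, chrom=str(row.chrom), pos=int(row.pos),
            ref=row.ref, alt=row.alt, gwas_p=gwas_p,
            role=role,
            lead_rsid=getattr(row, "lead_rsid", None),
            r2=float(getattr(row, "r2", 1.0)),
            disease=getattr(row, "disease", None)))
    return out


def read_snps_tsv(path: str | Path) -> pd.DataFrame:
    """Read a SNP table in SNP_COLUMNS layout (extra columns preserved)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"rsid", "chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    return df


def read_snps_vcf(path: str | Path) -> pd.DataFrame:
    """Read SNPs from a VCF 4.x file; multi-allelic rows are expanded."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                rows.append({
                    "rsid": rec.id or f"{rec.chrom}:{rec.pos}",
                    "chrom": rec.chrom, "pos": rec.pos,
                    "ref": rec.ref, "alt": alt,
                })
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ref", "alt"])
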