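"""Linking regulatory SNPs to target genes through a regulatory-element map.

Regulatory elements (REMs) are genomic intervals statistically linked to a
target gene. An rSNP falling inside a REM makes that REM's gene a candidate
disease gene. Genes are classified as coding or non-coding from their
annotation biotype: non-coding means any biotype other than protein_coding
or TEC. Per gene we count the distinct rSNPs across all its REMs and the
number of its REMs containing at least one rSNP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

CODING_BIOTYPES = {"protein_coding", "TEC"}

REM_COLUMNS = ["rem_id", "chrom", "start", "end", "gene_id", "gene_name",
               "model_score"]


@dataclass
class REM:
    """Regulatory element: 0-based half-open interval linked to a gene."""

    rem_id: str
    chrom: str
    start: int
    end: int
    gene_id: str
    gene_name: str
    model_score: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.rem_id}: start {self.start} >= end {self.end}")


class RemIndex:
    """Per-chromosome interval index over a REM catalogue."""

    def __init__(self, rems: list[REM]):
        self.rems = rems
        self._trees: dict[str, IntervalTree] = {}
        for rem in rems:
            self._trees.setdefault(rem.chrom, IntervalTree()).addi(
                rem.start, rem.end, rem)

    def overlapping(self, chrom: str, pos0: int) -> list[REM]:
        """REMs whose half-open interval contains the 0-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos0)),
                      key=lambda r: r.rem_id)


def read_rem_catalog(path: str | Path,
                     column_map: dict[str, str] | None = None) -> list[REM]:
    """Read a REM catalogue CSV (gzip or plain); invalid rows are dropped.

    ``column_map`` renames file columns onto the canonical REM_COLUMNS
    schema for catalogues with a different header.
    """
    df = pd.read_csv(path, dtype={"chrom": str})  # pandas infers gzip
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(REM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"REM catalogue missing columns: {sorted(missing)}")
    rems: list[REM] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        if row.start >= row.end:
            n_bad += 1
            continue
        rems.append(REM(rem_id=str(row.rem_id), chrom=str(row.chrom),
                        start=int(row.start), end=int(row.end),
                        gene_id=str(row.gene_id), gene_name=str(row.gene_name),
                        model_score=float(row.model_score)))
    if n_bad:
        warnings.warn(f"{n_bad} REM rows with start >= end rejected")
    return rems


def rems_to_frame(rems: list[REM]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rems], columns=REM_COLUMNS)


def overlap_snps_rems(rsnps: pd.DataFrame,
                      rems: list[REM] | RemIndex) -> pd.DataFrame:
    """All (rSNP, REM) pairs where the SNP lies inside the REM interval.

    SNP positions are 1-based; a SNP at position p overlaps a REM iff
    start <= p-1 < end.
    """
    index = rems if isinstance(rems, RemIndex) else RemIndex(rems)
    rows = []
    for snp in rsnps.itertuples(index=False):
        pos0 = int(snp.pos) - 1
        for rem in index.overlapping(str(snp.chrom), pos0):
            rows.append({"rsid": snp.rsid, "chrom": rem.chrom,
                         "pos": int(snp.pos), "rem_id": rem.rem_id,
                         "gene_id": rem.gene_id, "gene_name": rem.gene_name,
                         "model_score": rem.model_score})
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "rem_id",
                                       "gene_id", "gene_name", "model_score"])


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (TSV: gene_id, gene_name, biotype)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "gene_name", "biotype"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return df


def classify_biotype(gene_id: str, annotation: pd.DataFrame) -> str:
    """'coding' for protein_coding/TEC biotypes, else 'noncoding'.

    Genes absent from the annotation classify as 'unknown' (with a warning)
    and are excluded from category counts.
    """
    hit = annotation.loc[annotation["gene_id"] == gene_id, "biotype"]
    if hit.empty:
        warnings.warn(f"gene {gene_id} absent from annotation, "
                      "classified unknown")
        return "unknown"
    return "coding" if hit.iloc[0] in CODING_BIOTYPES else "noncoding"


def aggregate_gene_stats(links: pd.DataFrame, annotation: pd.DataFrame,
                         disease_genes: set[str] | None = None,
                         disease: str | None = None) -> pd.DataFrame:
    """Per-gene association statistics from (rSNP, REM) link pairs.

    For each gene: n_rsnps = distinct rSNP ids over all the gene's REMs;
    n_rems_hit = distinct REMs containing >= 1 rSNP; biotype class; whether
    the gene is already listed for the disease in the catalogue.
    """
    cols = ["gene_id", "gene_name", "biotype_class", "disease",
            "n_rsnps", "n_rems_hit", "known_disease_gene"]
    if links.empty:
        return pd.DataFrame(columns=cols)
    biotype_map = annotation.set_index("gene_id")["biotype"].to_dict()
    known = disease_genes or set()
    grouped = links.groupby("gene_id", sort=True)
    rows = []
    for gene_id, sub in grouped:
        biotype = biotype_map.get(gene_id)
        if biotype is None:
            warnings.warn(f"gene {gene_id} absent from annotation, "
                          "excluded from category counts")
            bclass = "unknown"
        else:
            bclass = "coding" if biotype in CODING_BIOTYPES else "noncoding"
        rows.append({
            "gene_id": gene_id,
            "gene_name": sub["gene_name"].iloc[0],
            "biotype_class": bclass,
            "disease": disease,
            "n_rsnps": sub["rsid"].nunique(),
            "n_rems_hit": sub["rem_id"].nunique(),
            "known_disease_gene": gene_id in known,
        })
    return pd.DataFrame(rows, columns=cols)


def category_counts(gene_stats: pd.DataFrame) -> dict[str, int]:
    """Distinct associated genes per biotype category (unknowns excluded)."""
    counted = gene_stats[gene_stats["biotype_class"] != "unknown"]
    return {
        "coding": int((counted["biotype_class"] == "coding").sum()),
        "noncoding": int((counted["biotype_class"] == "noncoding").sum()),
    }
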