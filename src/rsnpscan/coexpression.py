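"""Guilt-by-association through co-expression.

Each candidate non-coding gene is correlated (Spearman) against every
protein-coding gene across expression samples; its top-k partners
(default k = 10, ranked by signed rho descending) suggest the pathways the
non-coding gene participates in. The union of partner sets over all
non-coding genes of a disease feeds the disease-enrichment analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class CoexpressionPartnerList:
    """Ranked co-expression partners of one non-coding gene."""

    ncrna: str
    partners: list[tuple[str, float]]  # (coding gene id, rho), rho descending
    k: int
    skipped: bool = False
    reason: str | None = None


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression matrix TSV: first column gene_id, rest samples."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average-ranked values.

    Pairs with a missing value in either vector are dropped; a constant
    vector yields NaN (undefined, excluded from ranking).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, mat)


def top_k_partners(ncrna: str, expr: pd.DataFrame, coding_ids: list[str],
                   k: int = 10) -> CoexpressionPartnerList:
    """Top-k protein-coding co-expression partners of one non-coding gene.

    Ranking is by signed rho descending; ties break lexicographically by
    gene id. Coding genes with zero variance are excluded (their count is
    logged); a non-coding gene absent from the matrix yields a skipped
    marker.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if ncrna not in expr.index:
        warnings.warn(f"{ncrna} absent from expression matrix, skipped")
        return CoexpressionPartnerList(ncrna=ncrna, partners=[], k=k,
                                       skipped=True,
                                       reason="absent from expression matrix")
    coding = [g for g in coding_ids if g in expr.index and g != ncrna]
    x = expr.loc[ncrna].to_numpy(dtype=float)
    rx = rankdata(x)
    if rx.std() == 0:
        warnings.warn(f"{ncrna} has zero expression variance, skipped")
        return CoexpressionPartnerList(ncrna=ncrna, partners=[], k=k,
                                       skipped=True, reason="zero variance")
    mat = expr.loc[coding].to_numpy(dtype=float)
    ranks = _rank_rows(mat)
    sds = ranks.std(axis=1)
    n_const = int((sds == 0).sum())
    if n_const:
        warnings.warn(f"{n_const} zero-variance coding genes excluded from "
                      f"ranking against {ncrna}")
    rxc = rx - rx.mean()
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ rxc) / (np.linalg.norm(rc, axis=1) * np.linalg.norm(rxc))
    pairs = [(g, float(r)) for g, r, sd in zip(coding, rho, sds) if sd > 0]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return CoexpressionPartnerList(ncrna=ncrna, partners=pairs[:k], k=k)


def coexpression_gene_set(ncrnas: list[str], expr: pd.DataFrame,
                          coding_ids: list[str], k: int = 10
                          ) -> tuple[set[str], list[CoexpressionPartnerList]]:
    """Union of top-k partner gene ids over all non-coding genes."""
    lists = [top_k_partners(nc, expr, coding_ids, k=k) for nc in ncrnas]
    union: set[str] = set()
    for pl in lists:
        union.update(g for g, _ in pl.partners)
    return union, lists


def partners_to_frame(lists: list[CoexpressionPartnerList]) -> pd.DataFrame:
    """Tabulate partner lists, one row per (ncRNA, rank, partner)."""
    rows = []
    for pl in lists:
        for rank, (gene, rho) in enumerate(pl.partners, start=1):
            rows.append({"ncrna": pl.ncrna, "rank": rank,
                         "partner": gene, "rho": rho})
    return pd.DataFrame(rows, columns=["ncrna", "rank", "partner", "rho"])
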