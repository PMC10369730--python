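"""Gene-set over-representation against a disease (or any term) catalogue.

One-sided Fisher exact tests (upper-tail hypergeometric) per term, with
Benjamini-Hochberg control of the false discovery rate across terms.
Queries smaller than ``min_query`` genes (default 30) are skipped as
statistically underpowered rather than tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ["term_id", "term_name", "universe_size", "term_size",
                  "query_size", "overlap", "odds_ratio", "p", "fdr",
                  "significant"]


@dataclass
class EnrichmentOutcome:
    """Either a full enrichment table or an explicit skipped marker."""

    skipped: bool
    reason: str | None = None
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))


def read_term_catalog(path: str | Path) -> pd.DataFrame:
    """Read a term->gene catalogue TSV (term_id, term_name, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"term_id", "term_name", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"term catalogue missing columns: {sorted(missing)}")
    return df


def catalog_to_sets(catalog: pd.DataFrame) -> dict[str, tuple[str, set[str]]]:
    """term_id -> (term_name, gene set)."""
    out: dict[str, tuple[str, set[str]]] = {}
    for (tid, tname), sub in catalog.groupby(["term_id", "term_name"]):
        out[tid] = (tname, set(sub["gene_id"]))
    return out


def _odds_ratio(k: int, n: int, K: int, N: int) -> tuple[float, bool]:
    """Odds ratio of the 2x2 table; 0.5 continuity only on a zero cell."""
    a, b, c, d = k, n - k, K - k, N - K - n + k
    corrected = False
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    return (a * d) / (b * c), corrected


def fisher_enrichment(query: set[str],
                      term_sets: dict[str, tuple[str, set[str]]],
                      universe: set[str],
                      fdr_threshold: float = 0.05) -> pd.DataFrame:
    """One-sided over-representation of ``query`` in each term set.

    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|term|, n=|query|).
    Genes outside the universe are dropped with a warning; term sets are
    intersected with the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    dropped = query - universe
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside universe dropped")
    q = query & universe
    if not q:
        raise ValueError("empty query after universe intersection")
    N, n = len(universe), len(q)
    rows = []
    for tid, (tname, genes) in sorted(term_sets.items()):
        term = genes & universe
        K = len(term)
        k = len(q & term)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(p, 1.0)
        orat, _ = _odds_ratio(k, n, K, N) if K else (float("nan"), False)
        rows.append({"term_id": tid, "term_name": tname, "universe_size": N,
                     "term_size": K, "query_size": n, "overlap": k,
                     "odds_ratio": orat, "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].tolist())
    df["significant"] = df["fdr"] <= fdr_threshold
    return df.sort_values(["fdr", "p", "term_id"]).reset_index(drop=True)


def bh_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    if not pvalues:
        return []
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return list(q)


def run_set_enrichment(genes: set[str], catalog: pd.DataFrame,
                       universe: set[str], min_query: int = 30,
                       fdr_threshold: float = 0.05) -> EnrichmentOutcome:
    """Enrichment of a gene set, or a skipped marker for small queries.

    Queries with fewer than ``min_query`` genes in the universe are not
    tested: with so few genes the test is underpowered and a marker is
    returned instead of a table.
    """
    effective = genes & universe
    if len(effective) < min_query:
        return EnrichmentOutcome(
            skipped=True,
            reason=f"query has {len(effective)} genes in universe "
                   f"(< {min_query}); enrichment omitted")
    table = fisher_enrichment(effective, catalog_to_sets(catalog), universe,
                              fdr_threshold=fdr_threshold)
    return EnrichmentOutcome(skipped=False, table=table)
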