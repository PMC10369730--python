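"""Bundled reference tables.

The package ships a curated shortlist of candidate non-coding RNA genes
associated with cardiovascular diseases (pseudogenes, lncRNAs, antisense
RNAs and small RNAs selected for their regulatory-SNP load). It is used as
a worked example and as a fixture for the table readers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_ncrna_candidates() -> pd.DataFrame:
    """The bundled CVD ncRNA candidate shortlist (gene_id, gene_name,
    disease)."""
    ref = resources.files("rsnpscan.data").joinpath("ncrna_candidates.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def candidate_disease_counts(table: pd.DataFrame | None = None
                             ) -> dict[str, int]:
    """Candidates per disease; a gene listed for several diseases counts
    under its first-listed (primary) disease."""
    df = load_ncrna_candidates() if table is None else table
    primary = df["disease"].str.split("&").str[0].str.strip()
    return primary.value_counts().to_dict()
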