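"""Cross-omics joins: transcript-protein concordance and metabolite-gene links.

The proteomic fold changes arrive as an external table (iTRAQ study,
24 h / 48 h, possibly missing at one time point).  Every consistently
induced gene is assigned exactly one concordance class:

    both_up     protein fold change >= threshold at >= 1 reported time point
    protein_down  protein fold change <= -threshold at >= 1 time point and
                  never >= +threshold
    unchanged   everything else, including genes with no detected protein
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .transcriptomics import InducedGeneSet

__all__ = ["ConcordanceTable", "build_concordance", "link_metabolites_to_genes"]

CLASSES = ("both_up", "protein_down", "unchanged")


@dataclass
class ConcordanceTable:
    """Per-induced-gene concordance class plus the class size summary."""

    table: pd.DataFrame  # indexed by gene id, column 'class' among others
    counts: dict[str, int]

    def genes_in_class(self, cls: str) -> list[str]:
        if cls not in CLASSES:
            raise ValueError(f"unknown concordance class {cls!r}")
        return sorted(self.table.index[self.table["class"] == cls])


def build_concordance(
    induced: InducedGeneSet,
    protein_fc: pd.DataFrame,
    threshold: float = 1.5,
) -> ConcordanceTable:
    """Classify every induced gene against the proteomic fold-change table.

    ``protein_fc`` is indexed by gene id with one column per proteomic time
    point; missing measurements are NaN.  Genes absent from the table are
    classed unchanged.
    """
    rows = []
    for gene in induced.genes:
        if gene in protein_fc.index:
            vals = protein_fc.loc[gene].dropna()
        else:
            vals = pd.Series(dtype=float)
        if len(vals) and (vals >= threshold).any():
            cls = "both_up"
        elif len(vals) and (vals <= -threshold).any():
            cls = "protein_down"
        else:
            cls = "unchanged"
        row = {"class": cls}
        for col in protein_fc.columns:
            row[f"protein_{col}"] = (
                protein_fc.loc[gene, col] if gene in protein_fc.index else float("nan")
            )
        rows.append(pd.Series(row, name=gene))
    table = (
        pd.DataFrame(rows)
        if rows
        else pd.DataFrame(columns=["class"])
    )
    counts = {cls: int((table.get("class", pd.Series(dtype=object)) == cls).sum()) for cls in CLASSES}
    return ConcordanceTable(table=table, counts=counts)


def link_metabolites_to_genes(
    qualified_metabolites: list[str] | pd.Index,
    induced_genes: list[str] | InducedGeneSet,
    link_table: pd.DataFrame,
) -> pd.DataFrame:
    """Join qualified metabolites to induced genes through a curated map.

    ``link_table`` needs columns ``metabolite`` and ``gene_id`` (extra
    columns pass through).  A row is reported only when both the metabolite
    qualified and the linked gene passed the induction filter; rows naming
    ids unknown on either side are skipped.  Purely a join — no inference.
    """
    required = {"metabolite", "gene_id"}
    if not required.issubset(link_table.columns):
        raise ValueError(f"link table must have columns {sorted(required)}")
    mets = set(qualified_metabolites)
    genes = set(
        induced_genes.genes
        if isinstance(induced_genes, InducedGeneSet)
        else induced_genes
    )
    mask = link_table["metabolite"].isin(mets) & link_table["gene_id"].isin(genes)
    return link_table.loc[mask].reset_index(drop=True)
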