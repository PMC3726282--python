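"""RNA-seq read accounting, RPKM expression, and the consistent-induction filter.

The transcriptomic layer consumes a gene x sample count matrix (with gene
lengths and per-sample mapped-read totals), converts it to RPKM, forms
per-time-point treated/control fold changes under the shared signed
convention, and retains as induced the genes whose fold change clears a
threshold (default 1.5) at every sampled time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratios import to_signed

__all__ = [
    "SampleReadStats",
    "summarize_read_stats",
    "compute_rpkm",
    "rpkm_to_counts",
    "compute_fold_changes",
    "filter_consistent_induction",
    "replicate_correlation",
]


@dataclass(frozen=True)
class SampleReadStats:
    """Per-sample read accounting: raw, quality/ncRNA-filtered, genome-mapped.

    The mapping ratio is the fraction of qualified reads that align to the
    genome (mapped / qualified).
    """

    sample_id: str
    raw_reads: int
    qualified_reads: int
    mapped_reads: int

    def __post_init__(self) -> None:
        if not (self.raw_reads >= self.qualified_reads >= self.mapped_reads >= 0):
            raise ValueError(
                f"{self.sample_id}: require raw >= qualified >= mapped >= 0, got "
                f"{self.raw_reads} / {self.qualified_reads} / {self.mapped_reads}"
            )

    @property
    def mapping_ratio(self) -> float:
        if self.qualified_reads == 0:
            raise ZeroDivisionError(
                f"{self.sample_id}: mapping ratio undefined with 0 qualified reads"
            )
        return self.mapped_reads / self.qualified_reads


def summarize_read_stats(rows: Sequence[SampleReadStats]) -> dict:
    """Per-sample mapping percentages plus aggregate read-accounting totals.

    Per-sample percentages are rounded to 2 decimals; the mean mapping ratio
    is the unweighted mean of the per-sample percentages, rounded to 1
    decimal.  Totals are exact integer sums.
    """
    if not rows:
        raise ValueError("no read-stats rows supplied")
    per_sample = {r.sample_id: round(100.0 * r.mapping_ratio, 2) for r in rows}
    ratios = list(per_sample.values())
    return {
        "per_sample_mapping_pct": per_sample,
        "total_raw": sum(r.raw_reads for r in rows),
        "mean_raw": sum(r.raw_reads for r in rows) / len(rows),
        "total_qualified": sum(r.qualified_reads for r in rows),
        "mean_mapping_ratio_pct": round(float(np.mean(ratios)), 1),
    }


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM values together with what is needed to invert them."""

    rpkm: pd.DataFrame  # genes x samples
    gene_lengths: pd.Series  # bp, indexed like rpkm
    mapped_totals: pd.Series  # per-sample mapped reads, indexed like columns

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rpkm.columns)


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    mapped_totals: pd.Series,
) -> ExpressionMatrix:
    """Reads per kilobase of gene per million mapped reads.

    RPKM[g, s] = count[g, s] * 1e9 / (length[g] * mapped_total[s]).
    """
    lengths = lengths.reindex(counts.index)
    mapped_totals = mapped_totals.reindex(counts.columns)
    bad_len = lengths[(lengths.isna()) | (lengths <= 0)]
    if len(bad_len):
        raise ValueError(f"non-positive or missing gene length for {list(bad_len.index)}")
    bad_tot = mapped_totals[(mapped_totals.isna()) | (mapped_totals <= 0)]
    if len(bad_tot):
        raise ValueError(f"non-positive or missing mapped total for {list(bad_tot.index)}")
    rpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(mapped_totals, axis=1)
    return ExpressionMatrix(rpkm=rpkm, gene_lengths=lengths, mapped_totals=mapped_totals)


def rpkm_to_counts(expr: ExpressionMatrix) -> pd.DataFrame:
    """Invert the RPKM formula back to the read counts that produced it."""
    return (
        expr.rpkm.mul(expr.gene_lengths, axis=0)
        .mul(expr.mapped_totals, axis=1)
        .div(1e9)
    )


@dataclass
class FoldChangeTable:
    """Gene x time-point signed fold changes (treated vs control)."""

    fc: pd.DataFrame  # genes x time points (hours)
    time_points: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.time_points:
            self.time_points = tuple(int(t) for t in self.fc.columns)


def _choose_pseudocount(rpkm: pd.DataFrame) -> float:
    nz = rpkm.values[rpkm.values > 0]
    if nz.size == 0:
        raise ValueError("expression matrix is identically zero")
    return float(nz.min()) / 2.0


def compute_fold_changes(
    expr: ExpressionMatrix,
    manifest: pd.DataFrame,
    *,
    treated: str = "butanol",
    control: str = "control",
    pseudocount: float | None = None,
) -> FoldChangeTable:
    """Per-time-point treated/control fold change of replicate-averaged RPKM.

    ``manifest`` needs columns ``sample_id``, ``condition``, ``time_h``.
    Replicates are averaged arithmetically before the ratio is formed; the
    ratio is then expressed in the signed convention.  Zeros in either mean
    are shifted by a pseudocount (default: half the smallest nonzero RPKM)
    only when zeros are actually present.
    """
    required = {"sample_id", "condition", "time_h"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    times = sorted(manifest["time_h"].unique())
    fc = pd.DataFrame(index=expr.rpkm.index, columns=times, dtype=float)
    for t in times:
        sub = manifest[manifest["time_h"] == t]
        t_samples = sub.loc[sub["condition"] == treated, "sample_id"].tolist()
        c_samples = sub.loc[sub["condition"] == control, "sample_id"].tolist()
        if not t_samples or not c_samples:
            raise ValueError(
                f"time point {t} h lacks a '{treated}' or '{control}' sample"
            )
        t_mean = expr.rpkm[t_samples].mean(axis=1)
        c_mean = expr.rpkm[c_samples].mean(axis=1)
        if ((t_mean == 0) | (c_mean == 0)).any():
            pc = pseudocount if pseudocount is not None else _choose_pseudocount(expr.rpkm)
            t_mean = t_mean + pc
            c_mean = c_mean + pc
        ratio = t_mean / c_mean
        fc[t] = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return FoldChangeTable(fc=fc)


@dataclass
class InducedGeneSet:
    """Genes whose fold change clears ``threshold`` at every time point."""

    threshold: float
    genes: list[str]
    per_gene_fc: pd.DataFrame

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def filter_consistent_induction(
    fc_table: FoldChangeTable, threshold: float = 1.5
) -> InducedGeneSet:
    """Retain genes induced at least ``threshold``-fold at ALL time points.

    The comparison is inclusive (fc >= threshold), so a gene printed at
    exactly the threshold passes.  Output is sorted by gene id.
    """
    fc = fc_table.fc
    keep = (fc >= threshold).all(axis=1)
    genes = sorted(fc.index[keep])
    return InducedGeneSet(
        threshold=threshold, genes=genes, per_gene_fc=fc.loc[genes]
    )


def filter_consistent_repression(
    fc_table: FoldChangeTable, threshold: float = 1.5
) -> InducedGeneSet:
    """Mirror of the induction filter for consistently down-regulated genes."""
    fc = fc_table.fc
    keep = (fc <= -threshold).all(axis=1)
    genes = sorted(fc.index[keep])
    return InducedGeneSet(
        threshold=-threshold, genes=genes, per_gene_fc=fc.loc[genes]
    )


def replicate_correlation(
    expr_a: pd.Series | np.ndarray,
    expr_b: pd.Series | np.ndarray,
    *,
    pseudocount: float | None = None,
) -> float:
    """Pearson correlation of two replicate RPKM profiles on the log scale.

    A pseudocount (default: half the smallest nonzero value across both
    vectors) is added before the log so genes undetected in one replicate
    do not produce -inf.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("replicate vectors must be equal-length 1-D")
    if a.size < 3:
        raise ValueError("need at least 3 genes for a replicate correlation")
    if pseudocount is None:
        nz = np.concatenate([a[a > 0], b[b > 0]])
        if nz.size == 0:
            raise ValueError("both vectors are identically zero")
        pseudocount = float(nz.min()) / 2.0
    la, lb = np.log(a + pseudocount), np.log(b + pseudocount)
    if np.allclose(la, la[0]) or np.allclose(lb, lb[0]):
        raise ValueError("zero-variance vector: correlation undefined")
    r, _ = stats.pearsonr(la, lb)
    return float(r)
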