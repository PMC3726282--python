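"""End-to-end orchestration: simulation output, file-based runs, and the
packaged-fixture summary.

``run_pipeline`` drives the full analysis over on-disk inputs (typically
written by ``write_simulation``): read accounting, RPKM, fold changes and
the induction filter; metabolite normalization, replicate-ratio scoring,
clustering and PCA; qPCR standard-curve quantification and RNA-seq sign
concordance; and, when a proteomic table is supplied, the cross-omics
concordance classes.  ``reference_summary`` recomputes every number the
packaged reference tables support, from scratch, through the same public
functions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from . import metabolomics as mb
from . import qpcr as qp
from . import transcriptomics as tr
from .integration import build_concordance, link_metabolites_to_genes
from .synthetic import SimConfig, gen_metabolome, gen_qpcr, gen_transcriptome

__all__ = ["PipelineConfig", "run_pipeline", "write_simulation", "reference_summary"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Optional stages (qPCR, proteomics, links) are skipped when their input
    path is None.
    """

    counts: str | None = None
    read_stats: str | None = None
    manifest: str | None = None
    metabolites: str | None = None
    cell_counts: str | None = None
    metabolome_manifest: str | None = None
    qpcr: str | None = None
    protein_fc: str | None = None
    link_table: str | None = None
    outdir: str | None = None
    fc_threshold: float = 1.5
    ratio_threshold: float = 1.5
    min_changed: int = 5
    time_points: tuple[int, ...] = (24, 48, 72)
    pseudocount: float | None = None
    pca_unit_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1 or self.ratio_threshold <= 1:
            raise ValueError("thresholds must exceed 1")
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ValueError("time_points must be strictly increasing")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["time_points"] = list(self.time_points)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "time_points" in d:
            d["time_points"] = tuple(d["time_points"])
        return cls(**d)


def write_simulation(sim: SimConfig, outdir: str | Path) -> PipelineConfig:
    """Generate all three synthetic datasets and write them as text tables.

    Returns a :class:`PipelineConfig` pointing at the written files; the
    planted ground truth goes to ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, lengths, stats, t_truth = gen_transcriptome(sim)
    bio.write_counts_tsv(outdir / "counts.tsv", counts, lengths)
    bio.write_read_stats(outdir / "read_stats.tsv", stats)
    t_truth.manifest_frame().to_csv(outdir / "manifest_transcriptome.csv", index=False)

    raw, cells, m_truth = gen_metabolome(sim)
    raw.index.name = "metabolite"
    raw.to_csv(outdir / "metabolites.csv", float_format=bio.FLOAT_FORMAT)
    cells.rename_axis("sample_id").reset_index().to_csv(
        outdir / "cell_counts.csv", index=False
    )
    m_truth.manifest_frame().to_csv(outdir / "manifest_metabolome.csv", index=False)

    qpcr_df, q_truth = gen_qpcr(sim)
    qpcr_df.to_csv(outdir / "qpcr.csv", index=False)

    truth = {
        "induced_genes": t_truth.induced_genes,
        "metabolite_patterns": {
            m: {"cluster": lab, "signs": signs}
            for m, (lab, signs) in m_truth.metabolite_patterns.items()
        },
        "qpcr_true_ratios": q_truth.induced_genes,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))

    return PipelineConfig(
        counts=str(outdir / "counts.tsv"),
        read_stats=str(outdir / "read_stats.tsv"),
        manifest=str(outdir / "manifest_transcriptome.csv"),
        metabolites=str(outdir / "metabolites.csv"),
        cell_counts=str(outdir / "cell_counts.csv"),
        metabolome_manifest=str(outdir / "manifest_metabolome.csv"),
        qpcr=str(outdir / "qpcr.csv"),
        outdir=str(outdir),
        seed=sim.seed,
    )


def _fit_qpcr(df: pd.DataFrame, ratio_threshold: float) -> dict:
    standards = df[df["role"] == "standard"]
    curve = qp.fit_standard_curve(
        list(zip(standards["known_quantity"], standards["ct"]))
    )
    # technical replicates averaged before interpolation
    mean_ct = (
        df[df["role"] != "standard"]
        .groupby(["gene_id", "sample_id", "role"])["ct"]
        .mean()
        .reset_index()
    )
    ref = mean_ct[mean_ct["role"] == "reference"].set_index("sample_id")["ct"]
    ratios = {}
    for gid, sub in mean_ct[mean_ct["role"] == "target"].groupby("gene_id"):
        q = {
            r.sample_id: qp.quantify(r.ct, curve) for r in sub.itertuples()
        }
        ratios[gid] = qp.expression_ratio(
            q["butanol"], q["control"],
            qp.quantify(ref["butanol"], curve), qp.quantify(ref["control"], curve),
        )
    return {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "efficiency": curve.efficiency,
        "expression_ratios": ratios,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and return the result bundle.

    The bundle maps stage names to their in-memory results plus a
    ``summary`` of headline numbers; when ``config.outdir`` is set the
    stage tables and the summary JSON are also written there.
    """
    bundle: dict = {}
    summary: dict = {"thresholds": {
        "fc_threshold": config.fc_threshold,
        "ratio_threshold": config.ratio_threshold,
        "min_changed": config.min_changed,
    }}

    if config.counts and config.read_stats and config.manifest:
        counts, lengths = bio.read_counts_tsv(config.counts)
        stats = bio.read_read_stats(config.read_stats)
        manifest = bio.read_manifest(config.manifest)
        stats_summary = tr.summarize_read_stats(stats)
        mapped = pd.Series({s.sample_id: s.mapped_reads for s in stats})
        expr = tr.compute_rpkm(counts, lengths, mapped)
        fc = tr.compute_fold_changes(expr, manifest, pseudocount=config.pseudocount)
        induced = tr.filter_consistent_induction(fc, config.fc_threshold)
        bundle["transcriptome"] = {
            "read_stats": stats_summary,
            "expression": expr,
            "fold_changes": fc,
            "induced": induced,
        }
        summary["read_stats"] = stats_summary
        summary["n_induced_genes"] = len(induced)

    if config.metabolites and config.cell_counts and config.metabolome_manifest:
        raw, is_peaks, = bio.read_metabolite_csv(config.metabolites)
        cells = bio.read_cell_counts(config.cell_counts)
        m_manifest = bio.read_manifest(config.metabolome_manifest)
        table = mb.normalize_abundances(raw, is_peaks, cells)
        cube = mb.build_ratio_cube(table, m_manifest)
        scores = mb.score_and_qualify(
            cube, threshold=config.ratio_threshold, k_min=config.min_changed
        )
        qualified = scores.qualified_ids
        assignment = mb.assign_cluster(scores.scores.loc[qualified])
        pca_scores, evr = mb.pca_profiles(
            table, m_manifest, unit_scale=config.pca_unit_scale
        )
        bundle["metabolome"] = {
            "abundances": table,
            "scores": scores,
            "clusters": assignment,
            "pca": (pca_scores, evr),
        }
        summary["n_qualified_metabolites"] = len(qualified)
        summary["qualified_per_time"] = {
            str(t): int((scores.changed_counts[t] >= config.min_changed).sum())
            for t in scores.changed_counts.columns
        }
        summary["cluster_sizes"] = mb.cluster_sizes(assignment)

    if config.qpcr:
        qdf = bio.read_qpcr_csv(config.qpcr)
        qres = _fit_qpcr(qdf, config.ratio_threshold)
        bundle["qpcr"] = qres
        summary["qpcr"] = {
            "efficiency": qres["efficiency"],
            "r_squared": qres["r_squared"],
        }

    if config.protein_fc and "transcriptome" in bundle:
        prot = pd.read_csv(config.protein_fc, sep="\t").set_index("gene_id")
        conc = build_concordance(
            bundle["transcriptome"]["induced"], prot, config.fc_threshold
        )
        bundle["concordance"] = conc
        summary["concordance"] = conc.counts

    if (
        config.link_table
        and "transcriptome" in bundle
        and "metabolome" in bundle
    ):
        links = pd.read_csv(config.link_table)
        joined = link_metabolites_to_genes(
            bundle["metabolome"]["scores"].qualified_ids,
            bundle["transcriptome"]["induced"],
            links,
        )
        bundle["links"] = joined
        summary["n_metabolite_gene_links"] = int(len(joined))

    bundle["summary"] = summary
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        if "transcriptome" in bundle:
            t = bundle["transcriptome"]
            t["expression"].rpkm.rename_axis("gene_id").to_csv(
                out / "rpkm.tsv", sep="\t", float_format=bio.FLOAT_FORMAT
            )
            t["fold_changes"].fc.rename_axis("gene_id").to_csv(
                out / "fold_changes.tsv", sep="\t", float_format=bio.FLOAT_FORMAT
            )
            t["induced"].per_gene_fc.rename_axis("gene_id").to_csv(
                out / "induced_genes.tsv", sep="\t", float_format=bio.FLOAT_FORMAT
            )
        if "metabolome" in bundle:
            m = bundle["metabolome"]
            m["scores"].scores.rename_axis("metabolite").to_csv(
                out / "metabolite_scores.tsv", sep="\t"
            )
            m["clusters"].rename_axis("metabolite").to_csv(
                out / "metabolite_clusters.tsv", sep="\t"
            )
            m["pca"][0].rename_axis("sample_id").to_csv(
                out / "pca_scores.csv", float_format=bio.FLOAT_FORMAT
            )
        if "concordance" in bundle:
            bundle["concordance"].table.rename_axis("gene_id").to_csv(
                out / "concordance.tsv", sep="\t", float_format=bio.FLOAT_FORMAT
            )
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return bundle


def reference_summary() -> dict:
    """Recompute every packaged-reference-table statistic from scratch.

    Runs the public analysis functions over the packaged fixtures: read
    accounting, the all-time-points induction filter, metabolite
    qualification / per-time detection / cluster assignment, qPCR-RNA-seq
    sign concordance, and the transcript-protein concordance classes.
    """
    stats = tr.summarize_read_stats(bio.load_fixture("table1"))

    t2 = bio.load_fixture("table2_fc")
    fc2 = t2[["fc_24h", "fc_48h", "fc_72h"]].set_axis([24, 48, 72], axis=1)
    induced2 = tr.filter_consistent_induction(tr.FoldChangeTable(fc=fc2))

    t4 = bio.load_fixture("table4")
    fc4 = t4[["transcript_fc_24h", "transcript_fc_48h", "transcript_fc_72h"]].set_axis(
        [24, 48, 72], axis=1
    )
    combined = pd.concat([fc2, fc4[~fc4.index.isin(fc2.index)]])
    induced_all = tr.filter_consistent_induction(tr.FoldChangeTable(fc=combined))
    prot = t4[["protein_fc_24h", "protein_fc_48h"]].set_axis([24, 48], axis=1)
    concordance = build_concordance(induced_all, prot)

    t5 = bio.load_fixture("table5_scores")
    scores = t5[["s24", "s48", "s72"]].set_axis([24, 48, 72], axis=1)
    qualified = mb.qualify_from_scores(scores)
    assignment = mb.assign_cluster(scores)
    nonzero = (scores != 0).sum(axis=0)

    t3 = bio.load_fixture("table3_pairs")
    n_conc, frac = qp.sign_concordance(
        list(zip(t3["qpcr_ratio"], t3["rnaseq_ratio"]))
    )

    links = link_metabolites_to_genes(
        list(scores.index[qualified]), induced_all, bio.load_fixture("link_table")
    )

    return {
        "read_stats": stats,
        "table2_n_induced": len(induced2),
        "table5_n_qualified": int(qualified.sum()),
        "table5_nonzero_per_time": {int(t): int(nonzero[t]) for t in nonzero.index},
        "table5_cluster_sizes": mb.cluster_sizes(assignment),
        "table4_concordance": concordance.counts,
        "table3_concordant": n_conc,
        "table3_concordant_fraction": frac,
        "n_metabolite_gene_links": int(len(links)),
    }
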