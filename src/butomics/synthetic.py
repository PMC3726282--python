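"""Synthetic transcriptome / metabolome / qPCR data with planted ground truth.

The generator emulates the study design the analysis assumes: two
conditions (control vs 0.2% v/v butanol) sampled at 24, 48 and 72 h, with
three biological replicates per condition for GC-MS metabolomics and
single RNA-seq samples per condition except a duplicated butanol sample at
72 h.  Induced genes are planted with treated/control RPKM ratios >= 1.5
at every time point; planted metabolites follow the canonical time-course
sign patterns of clusters I-VI.

All randomness flows from ``SimConfig.seed`` through fixed per-assay
stream ids (0 transcriptome, 1 metabolome, 2 qPCR), so each generator is
independently reproducible.  At ``noise_cv=0`` each generator emits the
exact mean-parameterized values (counts may then be non-integer), making
the noiseless-limit recovery properties exact; with ``noise_cv>0`` counts
are drawn from an overdispersed Poisson-gamma model and abundances from a
multiplicative log-normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .qpcr import slope_for_efficiency
from .transcriptomics import SampleReadStats

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PLANT_PATTERNS",
    "gen_transcriptome",
    "gen_metabolome",
    "gen_qpcr",
]

#: sign pattern planted per cluster label; VI has no canonical pattern in the
#: assignment rule (catch-all), so its plants use (-,-,-), which no other
#: cluster claims.
PLANT_PATTERNS: dict[str, tuple[int, int, int]] = {
    "I": (1, 1, 1),
    "II": (0, 1, 1),
    "III": (1, -1, -1),
    "IV": (1, -1, 1),
    "V": (1, 1, 0),
    "VI": (-1, -1, -1),
}

_STREAM = {"transcriptome": 0, "metabolome": 1, "qpcr": 2}


def _default_cluster_plan() -> dict[str, int]:
    # mirrors the observed differential-metabolite class sizes (46 of 73)
    return {"I": 7, "II": 7, "III": 4, "IV": 5, "V": 3, "VI": 20}


def _default_treated_reps() -> dict[int, int]:
    return {24: 1, 48: 1, 72: 2}


@dataclass
class SimConfig:
    """Study-design and noise parameters for all three generators."""

    seed: int = 0
    n_genes: int = 500
    n_metabolites: int = 73
    time_points: tuple[int, ...] = (24, 48, 72)
    reps_per_condition_metabolome: int = 3
    reps_per_condition_transcriptome: Mapping[int, int] = field(
        default_factory=_default_treated_reps
    )
    induced_gene_fraction: float = 0.1
    induced_fc_range: tuple[float, float] = (1.5, 6.0)
    metabolite_cluster_plan: Mapping[str, int] = field(
        default_factory=_default_cluster_plan
    )
    metabolite_effect_size: float = 3.0
    noise_cv: float = 0.1
    library_size_range: tuple[int, int] = (2_000_000, 6_000_000)
    gene_length_range: tuple[int, int] = (200, 3000)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_metabolites", "reps_per_condition_metabolome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be a positive count")
        if not self.time_points or list(self.time_points) != sorted(
            set(self.time_points)
        ):
            raise ValueError("SimConfig.time_points must be strictly increasing")
        if not 0 <= self.induced_gene_fraction <= 1:
            raise ValueError("SimConfig.induced_gene_fraction must be in [0, 1]")
        lo, hi = self.induced_fc_range
        if lo < 1.5 or hi < lo:
            raise ValueError(
                "SimConfig.induced_fc_range must satisfy 1.5 <= low <= high"
            )
        unknown = set(self.metabolite_cluster_plan) - set(PLANT_PATTERNS)
        if unknown:
            raise ValueError(
                f"SimConfig.metabolite_cluster_plan has unknown labels {sorted(unknown)}"
            )
        if sum(self.metabolite_cluster_plan.values()) > self.n_metabolites:
            raise ValueError(
                "SimConfig.metabolite_cluster_plan plants more metabolites than "
                "n_metabolites"
            )
        if self.metabolite_effect_size <= 1:
            raise ValueError("SimConfig.metabolite_effect_size must exceed 1")
        if self.noise_cv < 0:
            raise ValueError("SimConfig.noise_cv must be non-negative")
        for name in ("library_size_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"SimConfig.{name} must satisfy 0 < low <= high")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one assay, derived from the one seed."""
        return np.random.default_rng([_STREAM[stream], self.seed])


@dataclass
class GroundTruth:
    """Planted effects and the sample manifest behind one simulated dataset."""

    induced_genes: dict[str, dict[int, float]] = field(default_factory=dict)
    metabolite_patterns: dict[str, tuple[str, dict[int, int]]] = field(
        default_factory=dict
    )
    sample_manifest: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def manifest_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "condition": c, "time_h": t, "replicate": r}
            for s, (c, t, r) in self.sample_manifest.items()
        ]
        return pd.DataFrame(rows)


def _noisy(mean: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal noise with the given CV; exact mean at cv=0."""
    if cv == 0:
        return mean.copy()
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return mean * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=mean.shape)


def gen_transcriptome(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, list[SampleReadStats], GroundTruth]:
    """Simulate a count matrix, gene lengths, read stats and ground truth.

    Expression is parameterized in RPKM space so planted treated/control
    RPKM ratios equal the planted fold changes exactly at the mean; counts
    are recovered via the inverse RPKM formula and, when ``noise_cv > 0``,
    drawn from a Poisson-gamma (negative-binomial-like) model around those
    means.
    """
    rng = config.rng("transcriptome")
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    lengths = pd.Series(
        rng.integers(
            config.gene_length_range[0],
            config.gene_length_range[1] + 1,
            config.n_genes,
        ),
        index=genes,
        name="length_bp",
    )
    base_rpkm = pd.Series(rng.lognormal(mean=3.0, sigma=1.2, size=config.n_genes),
                          index=genes)

    n_induced = round(config.n_genes * config.induced_gene_fraction)
    induced = sorted(rng.choice(genes, size=n_induced, replace=False))
    truth = GroundTruth()
    lo, hi = config.induced_fc_range
    for g in induced:
        truth.induced_genes[g] = {
            int(t): float(rng.uniform(lo, hi)) for t in config.time_points
        }

    # sample plan: control single per time point; treated per the replicate map
    plan: list[tuple[str, int, int]] = []
    for t in config.time_points:
        plan.append(("control", int(t), 1))
        for r in range(1, int(config.reps_per_condition_transcriptome.get(t, 1)) + 1):
            plan.append(("butanol", int(t), r))

    counts = {}
    read_stats = []
    for cond, t, rep in plan:
        sid = f"{'B' if cond == 'butanol' else 'C'}{t}R{rep}"
        truth.sample_manifest[sid] = (cond, t, rep)
        fc = pd.Series(1.0, index=genes)
        if cond == "butanol":
            for g, per_t in truth.induced_genes.items():
                fc[g] = per_t[t]
        rpkm_mean = base_rpkm * fc
        mapped = int(rng.integers(*config.library_size_range))
        mean_counts = (rpkm_mean * lengths * mapped / 1e9).to_numpy()
        if config.noise_cv == 0:
            sample_counts = mean_counts
        else:
            shape = 1.0 / config.noise_cv**2
            mult = rng.gamma(shape, 1.0 / shape, size=mean_counts.shape)
            sample_counts = rng.poisson(mean_counts * mult).astype(float)
        counts[sid] = sample_counts
        mapping_ratio = rng.uniform(0.55, 0.82)
        qualified = math.ceil(mapped / mapping_ratio)
        raw = math.ceil(qualified / rng.uniform(0.28, 0.40))
        read_stats.append(
            SampleReadStats(
                sample_id=sid,
                raw_reads=raw,
                qualified_reads=qualified,
                mapped_reads=mapped,
            )
        )
    counts_df = pd.DataFrame(counts, index=genes)
    return counts_df, lengths, read_stats, truth


def gen_metabolome(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate raw GC-MS peak areas (with an ``IS`` row) plus cell counts.

    Planted metabolites multiply their control mean by the effect size in
    the planted direction at pattern-positive/negative time points and
    leave it unchanged at pattern-zero time points.  The internal-standard
    row and the per-sample cell counts carry their own small variation so
    normalization is exercised non-trivially; both are inverted exactly by
    the normalization step.
    """
    rng = config.rng("metabolome")
    mets = [f"met{i:03d}" for i in range(1, config.n_metabolites + 1)]
    base = pd.Series(rng.lognormal(mean=0.0, sigma=1.0, size=config.n_metabolites),
                     index=mets)

    truth = GroundTruth()
    planted_order = [
        lab for lab in ("I", "II", "III", "IV", "V", "VI")
        if lab in config.metabolite_cluster_plan
    ]
    pool = list(rng.permutation(mets))
    for lab in planted_order:
        pattern = PLANT_PATTERNS[lab]
        for _ in range(int(config.metabolite_cluster_plan[lab])):
            m = pool.pop()
            truth.metabolite_patterns[m] = (
                lab,
                {int(t): pattern[i] for i, t in enumerate(config.time_points)},
            )

    scale = 1e8
    is_base, is_cv = 5e5, 0.05
    samples, raw_cols, is_vals, cell_vals = [], {}, {}, {}
    for t in config.time_points:
        for cond in ("control", "butanol"):
            for rep in range(1, config.reps_per_condition_metabolome + 1):
                sid = f"{'B' if cond == 'butanol' else 'C'}{t}R{rep}"
                truth.sample_manifest[sid] = (cond, int(t), rep)
                mean = base.copy()
                if cond == "butanol":
                    for m, (_, signs) in truth.metabolite_patterns.items():
                        s = signs[int(t)]
                        if s:
                            mean[m] = mean[m] * config.metabolite_effect_size**s
                abundance = _noisy(mean.to_numpy(), config.noise_cv, rng)
                is_peak = float(is_base * rng.lognormal(-is_cv**2 / 2, is_cv))
                cells = float(1e8 * rng.lognormal(0.0, 0.1))
                raw_cols[sid] = abundance * is_peak * cells / scale
                is_vals[sid] = is_peak
                cell_vals[sid] = cells
                samples.append(sid)
    raw = pd.DataFrame(raw_cols, index=mets)
    raw.loc["IS"] = [is_vals[s] for s in samples]
    cell_counts = pd.Series(cell_vals, name="cell_count")
    return raw, cell_counts, truth


def gen_qpcr(
    config: SimConfig,
    efficiency: float = 0.95,
    *,
    noise_sd: float = 0.1,
    n_genes: int = 10,
    intercept: float = 34.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a dilution series and per-gene target/reference Ct values.

    Ct follows Ct = intercept + slope * log10(quantity) with
    slope = -1/log10(1 + efficiency), plus Gaussian noise of sd
    ``noise_sd``.  The reference gene (rnpB) has equal template in both
    conditions; target genes carry planted signed expression ratios stored
    in the ground truth.  Technical triplicates per measurement.
    """
    if efficiency <= 0:
        raise ValueError(f"efficiency must be positive, got {efficiency}")
    slope = slope_for_efficiency(efficiency)
    rng = config.rng("qpcr")
    truth = GroundTruth()
    rows = []

    def ct_of(quantity: float) -> float:
        ct = intercept + slope * math.log10(quantity)
        if noise_sd > 0:
            ct += float(rng.normal(0.0, noise_sd))
        return ct

    for q in (1e2, 1e1, 1e0, 1e-1, 1e-2):
        for _ in range(3):
            rows.append(
                {"gene_id": "standard", "sample_id": f"std_{q:g}", "role": "standard",
                 "known_quantity": q, "ct": ct_of(q)}
            )

    ref_q = 0.5
    for cond in ("control", "butanol"):
        for _ in range(3):
            rows.append(
                {"gene_id": "rnpB", "sample_id": cond, "role": "reference",
                 "known_quantity": float("nan"), "ct": ct_of(ref_q)}
            )

    for i in range(1, n_genes + 1):
        gid = f"q{i:03d}"
        plain_ratio = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
        truth.induced_genes[gid] = {48: plain_ratio}
        q_control = float(rng.lognormal(mean=math.log(0.1), sigma=0.5))
        q_treated = q_control * plain_ratio
        for cond, q in (("control", q_control), ("butanol", q_treated)):
            for _ in range(3):
                rows.append(
                    {"gene_id": gid, "sample_id": cond, "role": "target",
                     "known_quantity": float("nan"), "ct": ct_of(q)}
                )
    return pd.DataFrame(rows), truth
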