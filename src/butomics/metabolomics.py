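"""GC-MS metabolomics: normalization, replicate-ratio scoring, clustering, PCA.

The differential statistic works on all treated x control replicate pairs at
each time point (3 x 3 replicates -> 9 signed ratios).  Each ratio is coded
+1 / 0 / -1 by a strict +-1.5 cutoff; the sign-sum score (range -9..+9) and
the count of nonzero codes summarize one metabolite at one time point.  A
metabolite qualifies as differentially regulated when at least 5 of the 9
ratios are changed at some time point, and qualified metabolites are
classified into time-course clusters by the signs of their three scores:

    I   (+, +, +)   up at all three time points
    II  (0, +, +)   up only at the two later time points
    III (+, -, -)   up early, down later
    IV  (+, -, +)   up / down / up
    V   (+, +, 0)   up early, back to baseline at the last time point
    VI  anything else (catch-all)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .ratios import signed_ratio, sign, ternary_code

__all__ = [
    "AbundanceTable",
    "RatioCube",
    "ScoreMatrix",
    "CANONICAL_PATTERNS",
    "normalize_abundances",
    "build_ratio_cube",
    "score_and_qualify",
    "assign_cluster",
    "qualify_from_scores",
    "pca_profiles",
]

#: canonical score-sign patterns for clusters I-V; VI is the catch-all
CANONICAL_PATTERNS: dict[tuple[int, int, int], str] = {
    (1, 1, 1): "I",
    (0, 1, 1): "II",
    (1, -1, -1): "III",
    (1, -1, 1): "IV",
    (1, 1, 0): "V",
}

CLUSTER_LABELS = ("I", "II", "III", "IV", "V", "VI")


@dataclass
class AbundanceTable:
    """Metabolite x sample normalized abundances with detection flags."""

    values: pd.DataFrame  # metabolites x samples, >= 0
    detected: pd.DataFrame  # boolean, same shape

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_abundances(
    raw_peaks: pd.DataFrame,
    is_peaks: pd.Series,
    cell_counts: pd.Series,
    *,
    scale: float = 1e8,
) -> AbundanceTable:
    """Normalize raw peak areas by the internal standard and cell counts.

    value = raw / IS_peak / cell_count * scale.  The default scale of 1e8
    (a typical per-sample cell count) keeps magnitudes O(1).  A raw peak of
    0 is kept as 0 and flagged not-detected.
    """
    is_peaks = is_peaks.reindex(raw_peaks.columns)
    cell_counts = cell_counts.reindex(raw_peaks.columns)
    for name, series in (("internal standard", is_peaks), ("cell count", cell_counts)):
        bad = series[(series.isna()) | (series <= 0)]
        if len(bad):
            raise ValueError(f"zero/missing {name} for sample(s) {list(bad.index)}")
    if (raw_peaks.values < 0).any():
        raise ValueError("raw peak areas must be non-negative")
    values = raw_peaks.div(is_peaks, axis=1).div(cell_counts, axis=1) * scale
    return AbundanceTable(values=values, detected=raw_peaks > 0)


@dataclass
class RatioCube:
    """All treated x control replicate ratios per metabolite and time point."""

    ratios: np.ndarray  # (n_metabolites, n_times, n_treated * n_control)
    metabolite_ids: list[str]
    time_points: tuple[int, ...]


def build_ratio_cube(
    table: AbundanceTable,
    manifest: pd.DataFrame,
    *,
    treated: str = "butanol",
    control: str = "control",
) -> RatioCube:
    """Signed ratios for every treated-replicate x control-replicate pair.

    With the default 3 + 3 replicates this generates 9 ratios per
    metabolite per time point.  ``manifest`` needs columns ``sample_id``,
    ``condition``, ``time_h``, ``replicate``; replicate order is fixed by
    sorting so the cube is deterministic.
    """
    required = {"sample_id", "condition", "time_h", "replicate"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    times = tuple(sorted(manifest["time_h"].unique()))
    mets = table.metabolite_ids
    n_pairs = None
    blocks = []
    for t in times:
        sub = manifest[manifest["time_h"] == t].sort_values("replicate")
        t_samples = sub.loc[sub["condition"] == treated, "sample_id"].tolist()
        c_samples = sub.loc[sub["condition"] == control, "sample_id"].tolist()
        if not t_samples or not c_samples:
            raise ValueError(f"time point {t} h lacks treated or control replicates")
        if n_pairs is None:
            n_pairs = len(t_samples) * len(c_samples)
        elif n_pairs != len(t_samples) * len(c_samples):
            raise ValueError("unbalanced replicate design across time points")
        tv = table.values[t_samples].to_numpy()  # (n_met, n_t)
        cv = table.values[c_samples].to_numpy()  # (n_met, n_c)
        block = np.empty((len(mets), n_pairs))
        k = 0
        for i in range(tv.shape[1]):
            for j in range(cv.shape[1]):
                block[:, k] = [signed_ratio(a, b) for a, b in zip(tv[:, i], cv[:, j])]
                k += 1
        blocks.append(block)
    cube = np.stack(blocks, axis=1)  # (n_met, n_times, n_pairs)
    return RatioCube(ratios=cube, metabolite_ids=list(mets), time_points=times)


@dataclass
class ScoreMatrix:
    """Sign-sum scores, changed counts and the qualification verdict."""

    scores: pd.DataFrame  # metabolites x time points, ints in [-n, n]
    changed_counts: pd.DataFrame  # metabolites x time points, ints in [0, n]
    qualified: pd.Series  # boolean per metabolite
    n_ratios: int
    threshold: float
    k_min: int

    @property
    def qualified_ids(self) -> list[str]:
        return list(self.qualified.index[self.qualified])


def score_and_qualify(
    cube: RatioCube, *, threshold: float = 1.5, k_min: int = 5
) -> ScoreMatrix:
    """Ternary-code the ratio cube and apply the >= k_min-of-n change rule.

    score = sum of the ternary codes; changed_count = number of nonzero
    codes.  A metabolite qualifies as differentially regulated when its
    changed_count reaches ``k_min`` at at least one time point.
    """
    n_pairs = cube.ratios.shape[2]
    codes = np.vectorize(lambda r: ternary_code(r, threshold), otypes=[int])(
        cube.ratios
    )
    scores = codes.sum(axis=2)
    changed = (codes != 0).sum(axis=2)
    scores_df = pd.DataFrame(
        scores, index=cube.metabolite_ids, columns=list(cube.time_points)
    )
    changed_df = pd.DataFrame(
        changed, index=cube.metabolite_ids, columns=list(cube.time_points)
    )
    qualified = pd.Series(
        changed.max(axis=1) >= k_min, index=cube.metabolite_ids
    )
    return ScoreMatrix(
        scores=scores_df,
        changed_counts=changed_df,
        qualified=qualified,
        n_ratios=n_pairs,
        threshold=threshold,
        k_min=k_min,
    )


def qualify_from_scores(scores: pd.DataFrame, k_min: int = 5) -> pd.Series:
    """Qualification re-derived from sign-sum scores alone.

    |score| is a lower bound on the changed count (every unit of |score|
    needs at least one nonzero code), so max_t |s| >= k_min is a
    conservative sufficient condition used when only the published score
    matrix — not the underlying ratios — is available.
    """
    return scores.abs().max(axis=1) >= k_min


def assign_cluster(
    scores: pd.DataFrame,
    *,
    patterns: Mapping[tuple[int, int, int], str] = CANONICAL_PATTERNS,
) -> pd.DataFrame:
    """Classify metabolites by the sign pattern of their three scores.

    Returns a frame with the per-time-point signs and the cluster label;
    any pattern not in ``patterns`` falls into the catch-all cluster VI.
    """
    if scores.shape[1] != 3:
        raise ValueError(
            f"cluster assignment expects 3 time points, got {scores.shape[1]}"
        )
    signs = scores.apply(lambda col: col.map(sign))
    labels = [
        patterns.get(tuple(int(s) for s in row), "VI")
        for row in signs.to_numpy()
    ]
    out = signs.copy()
    out.columns = [f"sign_{c}" for c in scores.columns]
    out["cluster"] = labels
    return out


def cluster_sizes(assignment: pd.DataFrame) -> dict[str, int]:
    """Number of metabolites per cluster label, including empty clusters."""
    counts = assignment["cluster"].value_counts().to_dict()
    return {lab: int(counts.get(lab, 0)) for lab in CLUSTER_LABELS}


def pca_profiles(
    table: AbundanceTable,
    manifest: pd.DataFrame | None = None,
    *,
    n_components: int | None = None,
    unit_scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the per-sample metabolite profiles.

    Samples are observations, metabolites features.  Profiles are centered
    (and optionally unit-scaled); component signs follow the convention
    that the largest-magnitude loading of each component is positive.
    Returns (scores frame with manifest annotations if given,
    explained-variance fractions).
    """
    X = table.values.to_numpy().T  # samples x metabolites
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 metabolites")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate input: all metabolites have zero variance")
    Xc = X - X.mean(axis=0)
    if unit_scale:
        sd = X.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    k = n_components or min(Xc.shape)
    pca = PCA(n_components=min(k, min(Xc.shape)))
    scores = pca.fit_transform(Xc)
    # deterministic sign: flip components whose extreme loading is negative
    for i, comp in enumerate(pca.components_):
        j = np.argmax(np.abs(comp))
        if comp[j] < 0:
            pca.components_[i] = -comp
            scores[:, i] = -scores[:, i]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    out = pd.DataFrame(scores, index=table.sample_ids, columns=cols)
    if manifest is not None:
        ann = manifest.set_index("sample_id").reindex(out.index)
        out = pd.concat([out, ann], axis=1)
    return out, pca.explained_variance_ratio_
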