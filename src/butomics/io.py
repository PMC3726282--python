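"""Plain-text table I/O and the packaged reference fixtures.

All interchange formats are TSV/CSV with documented schemas:

- counts TSV: ``gene_id``, ``length_bp``, then one column per sample
- read-stats TSV: ``sample_id``, ``raw_reads``, ``qualified_reads``,
  ``mapped_reads``
- sample manifest CSV: ``sample_id``, ``condition``, ``time_h``,
  ``replicate``
- metabolite CSV: first column ``metabolite``, one column per sample; the
  reserved row id ``IS`` holds the internal-standard peak areas
- cell-count CSV: ``sample_id``, ``cell_count``
- qPCR CSV: ``gene_id``, ``sample_id``, ``role`` (target | reference |
  standard), ``known_quantity``, ``ct``

Readers validate the owning type's invariants and reject offending rows
rather than coercing silently.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .transcriptomics import SampleReadStats

__all__ = [
    "FIXTURE_NAMES",
    "load_fixture",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_read_stats",
    "write_read_stats",
    "read_manifest",
    "read_metabolite_csv",
    "read_cell_counts",
    "read_qpcr_csv",
]

_FIXTURE_FILES = {
    "table1": "table1_read_stats.tsv",
    "table2_fc": "table2_induced_fc.tsv",
    "table3_pairs": "table3_qpcr_pairs.tsv",
    "table4": "table4_proteome.tsv",
    "table5_scores": "table5_metabolite_scores.tsv",
    "link_table": "metabolite_gene_links.csv",
}
FIXTURE_NAMES = tuple(_FIXTURE_FILES)

FLOAT_FORMAT = "%.6g"


def _fixture_path(filename: str):
    return resources.files("butomics.fixtures").joinpath(filename)


def load_fixture(name: str):
    """Load one packaged reference table, validated on load.

    ``table1`` returns a list of :class:`SampleReadStats`; the remaining
    names return DataFrames (``table2_fc``, ``table4`` and
    ``table5_scores`` indexed by id).
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    path = _fixture_path(_FIXTURE_FILES[name])
    sep = "," if path.name.endswith(".csv") else "\t"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep=sep)

    if name == "table1":
        return [
            SampleReadStats(
                sample_id=r.sample_id,
                raw_reads=int(r.raw_reads),
                qualified_reads=int(r.qualified_reads),
                mapped_reads=int(r.mapped_reads),
            )
            for r in df.itertuples()
        ]
    if name == "table2_fc":
        df = df.set_index("gene_id")
        fc = df[["fc_24h", "fc_48h", "fc_72h"]]
        bad = fc.index[(fc.abs() < 1).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"table2_fc: signed fold changes inside (-1, 1) for {list(bad)}"
            )
        return df
    if name == "table3_pairs":
        bad = df.index[
            (df[["qpcr_ratio", "rnaseq_ratio"]].abs() < 1).any(axis=1)
        ]
        if len(bad):
            raise ValueError(f"table3_pairs: ratios inside (-1, 1) at rows {list(bad)}")
        return df
    if name == "table4":
        return df.set_index("gene_id")
    if name == "table5_scores":
        df = df.set_index("metabolite")
        s = df[["s24", "s48", "s72"]]
        bad = s.index[(s.abs() > 9).any(axis=1) | (s != s.round()).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"table5_scores: scores must be integers in [-9, 9]; bad rows {list(bad)}"
            )
        return df
    return df  # link_table


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV, returning (gene x sample counts, gene lengths)."""
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    if "length_bp" not in df.columns:
        raise ValueError(f"{path}: counts TSV lacks a length_bp column")
    lengths = df.pop("length_bp")
    if (lengths <= 0).any():
        raise ValueError(f"{path}: non-positive gene lengths present")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts present")
    return df, lengths


def write_counts_tsv(path: str | Path, counts: pd.DataFrame, lengths: pd.Series) -> None:
    out = pd.concat([lengths.rename("length_bp"), counts], axis=1)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_read_stats(path: str | Path) -> list[SampleReadStats]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleReadStats(
            sample_id=str(r.sample_id),
            raw_reads=int(r.raw_reads),
            qualified_reads=int(r.qualified_reads),
            mapped_reads=int(r.mapped_reads),
        )
        for r in df.itertuples()
    ]


def write_read_stats(path: str | Path, rows: list[SampleReadStats]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "raw_reads": r.raw_reads,
                "qualified_reads": r.qualified_reads,
                "mapped_reads": r.mapped_reads,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "condition", "time_h", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest lacks columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in manifest")
    return df


def read_metabolite_csv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a metabolite CSV, splitting off the reserved ``IS`` row."""
    df = pd.read_csv(path).set_index("metabolite")
    if "IS" not in df.index:
        raise ValueError(f"{path}: metabolite CSV lacks the reserved 'IS' row")
    is_peaks = df.loc["IS"]
    raw = df.drop(index="IS")
    if (raw.values < 0).any() or (is_peaks <= 0).any():
        raise ValueError(f"{path}: peak areas must be non-negative (IS positive)")
    return raw, is_peaks


def read_cell_counts(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    if not {"sample_id", "cell_count"}.issubset(df.columns):
        raise ValueError(f"{path}: cell-count CSV needs sample_id and cell_count")
    s = df.set_index("sample_id")["cell_count"]
    if (s <= 0).any():
        raise ValueError(f"{path}: cell counts must be positive")
    return s


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"gene_id", "sample_id", "role", "known_quantity", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: qPCR CSV lacks columns {sorted(missing)}")
    bad_role = set(df["role"]) - {"target", "reference", "standard"}
    if bad_role:
        raise ValueError(f"{path}: unknown qPCR roles {sorted(bad_role)}")
    return df
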