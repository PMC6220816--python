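"""Gene-evidence tables: positive association reports per clinical setting.

The input is a four-column TSV (gene, ncbi, setting, reference) in which
each row records one published positive association of a gene variant with
the phenotype in one clinical setting.  A (gene, setting) pair is counted
at most once, so a gene's score is the number of *distinct* settings with
a positive report, not the number of publications.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Default controlled vocabulary of clinical settings for persisting pain.
DEFAULT_SETTINGS = (
    "back",
    "inflammatory",
    "musculoskeletal",
    "neuropathic",
    "visceral",
    "widespread",
    "idiopathic",
    "miscellaneous",
)


@dataclass(frozen=True)
class EvidenceRecord:
    gene: str
    ncbi: int | None
    setting: str
    reference: str


@dataclass
class EvidenceTable:
    """Deduplicated (gene, setting) positive reports with provenance."""

    records: list[EvidenceRecord]
    settings: tuple[str, ...]
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.records)

    def ncbi_id(self, gene: str) -> int | None:
        for r in self.records:
            if r.gene == gene:
                return r.ncbi
        raise KeyError(gene)


def _read_rows(stream) -> pd.DataFrame:
    df = pd.read_csv(
        stream,
        sep="\t",
        comment="#",
        dtype={"gene": str, "setting": str, "reference": str},
    )
    required = {"gene", "ncbi", "setting", "reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    return df


def parse_evidence(
    stream, settings_vocabulary: Iterable[str] = DEFAULT_SETTINGS
) -> EvidenceTable:
    """Parse an evidence TSV into a deduplicated :class:`EvidenceTable`.

    Duplicate (gene, setting) rows collapse to the first occurrence.
    Setting labels outside the controlled vocabulary are a hard error, as
    is a gene symbol carrying two different NCBI ids.
    """
    df = _read_rows(stream)
    if df.empty:
        raise ValueError("evidence table is empty")

    vocab = list(settings_vocabulary)
    df["setting"] = df["setting"].str.strip().str.lower()
    unknown = sorted(set(df["setting"]) - set(vocab))
    if unknown:
        raise ValueError(f"unknown setting labels: {unknown} (allowed: {vocab})")

    ncbi_counts = df.groupby("gene")["ncbi"].nunique()
    conflicted = ncbi_counts[ncbi_counts > 1]
    if not conflicted.empty:
        raise ValueError(
            f"conflicting NCBI ids for gene(s): {sorted(conflicted.index)}"
        )

    dedup = df.drop_duplicates(subset=["gene", "setting"], keep="first")
    records = [
        EvidenceRecord(
            gene=row.gene,
            ncbi=int(row.ncbi) if pd.notna(row.ncbi) else None,
            setting=row.setting,
            reference=row.reference,
        )
        for row in dedup.itertuples()
    ]
    genes = tuple(sorted(dedup["gene"].unique()))
    present = tuple(s for s in vocab if s in set(dedup["setting"]))
    return EvidenceTable(records=records, settings=present, genes=genes)


@dataclass
class SettingsMatrix:
    """Binary clinical-settings (rows) x genes (columns) matrix.

    The column sums — the number of distinct settings per gene — are the
    positive scores submitted to computed ABC analysis.
    """

    frame: pd.DataFrame  # settings x genes, 0/1

    @property
    def settings(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def column_sums(self) -> pd.Series:
        return self.frame.sum(axis=0).astype(int)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def settings_matrix(table: EvidenceTable) -> SettingsMatrix:
    """Build the binary settings x genes matrix from an evidence table."""
    frame = pd.DataFrame(
        np.zeros((len(table.settings), len(table.genes)), dtype=int),
        index=list(table.settings),
        columns=list(table.genes),
    )
    for rec in table.records:
        frame.loc[rec.setting, rec.gene] = 1
    return SettingsMatrix(frame=frame)


def genes_in_all_settings(matrix: SettingsMatrix) -> set[str]:
    """Genes reported in every clinical setting (often empty)."""
    sums = matrix.column_sums
    return set(sums.index[sums == len(matrix.settings)])


def intersect_gene_list(genes: Iterable[str], list_stream) -> list[str]:
    """Case-insensitive intersection with a flat one-symbol-per-line list.

    Preserves the order of ``genes``.  An empty list file is a hard error.
    """
    if isinstance(list_stream, (str, Path)):
        text = Path(list_stream).read_text()
    else:
        text = list_stream.read()
    wanted = {
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.strip().startswith("#")
    }
    if not wanted:
        raise ValueError("gene list is empty")
    return [g for g in genes if g.lower() in wanted]
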