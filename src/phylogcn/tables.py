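"""Tab-separated trait and abundance tables.

Trait tables map tip labels to 16S gene copy numbers (GCNs, positive
integers) with ``NA`` marking tips whose genome has not been sequenced.
Abundance tables hold non-negative integer read counts per (OTU, sample),
with an optional group label per sample.  All files are UTF-8 TSV with a
header row; lines starting with '#' are ignored on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tree import PhyloTree


class TableFormatError(ValueError):
    """Malformed TSV content (message carries the offending line number)."""


@dataclass
class TraitTable:
    """Mapping tip label -> GCN (int >= 1) or None for missing."""

    values: dict[str, int | None]

    def __post_init__(self):
        for k, v in self.values.items():
            if v is not None and (int(v) != v or v < 1):
                raise TableFormatError(
                    f"GCN for {k!r} must be a positive integer, got {v!r}"
                )

    @property
    def known(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.values.items() if v is not None}

    @property
    def known_tips(self) -> list[str]:
        return [k for k, v in self.values.items() if v is not None]

    def __len__(self) -> int:
        return len(self.values)

    def validate_against(self, tree: PhyloTree) -> None:
        missing = [k for k in self.values if k not in tree.tip_index]
        if missing:
            raise TableFormatError(
                f"{len(missing)} trait labels are not tips of the tree "
                f"(first: {missing[:3]})"
            )

    def mask(self, keep: set[str]) -> "TraitTable":
        """Copy with entries outside ``keep`` set to missing."""
        return TraitTable(
            {k: (v if k in keep else None) for k, v in self.values.items()}
        )


@dataclass
class AbundanceTable:
    """Read counts as a (OTU x sample) integer DataFrame plus sample groups."""

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise TableFormatError("duplicate OTU or sample labels")
        if (self.counts.to_numpy() < 0).any():
            raise TableFormatError("negative read counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.index)

    def sample_counts(self, sample: str) -> pd.Series:
        return self.counts[sample]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise TableFormatError(str(exc)) from None


def read_trait_table(path) -> TraitTable:
    """Read a (tip_id, gcn) TSV; 'NA' marks a missing GCN."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise TableFormatError("trait table needs at least 2 columns (tip_id, gcn)")
    values: dict[str, int | None] = {}
    for lineno, (tip, raw) in enumerate(
        zip(df.iloc[:, 0], df.iloc[:, 1]), start=2
    ):
        raw = "NA" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw)
        if raw.strip().upper() == "NA":
            values[str(tip)] = None
            continue
        try:
            x = float(raw)
            if x != int(x):
                raise ValueError
            values[str(tip)] = int(x)
        except ValueError:
            raise TableFormatError(
                f"line {lineno}: non-numeric GCN {raw!r} (use 'NA' for missing)"
            ) from None
    return TraitTable(values)


def write_trait_table(trait: TraitTable, path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write("tip_id\tgcn\n")
        for k, v in trait.values.items():
            fh.write(f"{k}\t{'NA' if v is None else int(v)}\n")


def read_abundance_table(path, groups: Mapping[str, str] | None = None) -> AbundanceTable:
    """Read an (OTU x samples) count TSV: first column OTU id, rest samples."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise TableFormatError("abundance table needs an OTU column and >=1 sample")
    otus = df.iloc[:, 0].astype(str)
    body = df.iloc[:, 1:]
    try:
        counts = body.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric count: {exc}") from None
    if (counts.to_numpy() % 1 != 0).any():
        raise TableFormatError("read counts must be integers")
    counts = counts.astype(np.int64)
    counts.index = pd.Index(otus, name="otu_id")
    return AbundanceTable(counts, dict(groups or {}))


def write_abundance_table(table: AbundanceTable, path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        buf = io.StringIO()
        table.counts.rename_axis("otu_id").to_csv(buf, sep="\t")
        fh.write(buf.getvalue())


def write_table(df: pd.DataFrame, path, header: str | None = None, index: bool = False) -> None:
    """Write a generic results DataFrame as TSV (reals at 12 significant digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=index, float_format="%.12g")
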