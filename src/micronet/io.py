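"""Readers and writers for the flat formats the pipeline exchanges.

All tabular files are tab-separated UTF-8 without quoting; sequence files
are plain FASTA. Readers validate loudly — a malformed cell raises with its
coordinates instead of being coerced. Writers are deterministic byte-for-byte
for identical inputs. All coordinates in reports are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CountMatrix",
    "SequenceRecord",
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_fasta",
    "write_fasta",
    "utr_gene_id",
    "write_edges",
    "read_edges",
]

VALID_LAYERS = ("mRNA", "miRNA")


class SequenceRecord(NamedTuple):
    """A named nucleotide sequence over the alphabet {A,C,G,T,U,N}."""

    id: str
    seq: str


@dataclass
class CountMatrix:
    """Integer expression counts, features in rows, samples in columns.

    ``counts`` is a pandas DataFrame with unique feature ids as index and
    unique sample ids as columns; every cell is a non-negative integer.
    ``layer`` tags the matrix as mRNA or miRNA so downstream thresholds
    (fold-change cutoffs) can be chosen per layer.
    """

    counts: pd.DataFrame
    layer: str = "mRNA"

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"layer must be one of {VALID_LAYERS}, got {self.layer!r}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise ValueError("counts must be integral; read_counts reports the offending cell")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at feature {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_counts(path: str | Path, layer: str = "mRNA") -> CountMatrix:
    """Read a feature x sample count TSV (first column = feature ids).

    Non-integer or negative cells raise with the feature/sample coordinates
    of the first offending cell; duplicate ids raise. Row and column order
    are preserved from the file.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round()) | (converted < 0)
        if bad.any():
            feature = raw.index[bad.to_numpy().nonzero()[0][0]]
            value = raw.loc[feature, col]
            raise ValueError(
                f"{path}: count for feature {feature!r}, sample {col!r} is {value!r}; "
                "expected a non-negative integer"
            )
        out[col] = converted.astype(np.int64)
    return CountMatrix(out, layer=layer)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, group, sex, batch).

    Returns a DataFrame indexed by sample_id. Groups must be drawn from
    {H, L}; both groups must be non-empty for any differential contrast,
    which is enforced at test time, not here (a metadata file may describe
    a single group).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "sex", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    bad_group = set(df["group"]) - {"H", "L"}
    if bad_group:
        raise ValueError(f"{path}: group labels must be H or L, got {sorted(bad_group)}")
    return df.set_index("sample_id")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    df = samples.reset_index() if samples.index.name == "sample_id" else samples
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; ids are the header up to the first whitespace.

    Sequences are uppercased on load (so U/T and case handling happen in
    exactly one place). Empty records and duplicate ids raise.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for start in range(0, len(rec.seq), width):
                fh.write(rec.seq[start : start + width] + "\n")


_ISOFORM_SUFFIX = re.compile(r"\.\d+$")


def utr_gene_id(utr_id: str) -> str:
    """Map a UTR record id to its parent gene id.

    Multi-isoform UTRs use a trailing ``.N`` suffix (``GENE.1``, ``GENE.2``);
    ids without the suffix are themselves gene ids.
    """
    return _ISOFORM_SUFFIX.sub("", utr_id)


EDGE_COLUMNS = ["source", "target", "edge_type", "r"]


def write_edges(edges: "pd.DataFrame | object", path: str | Path) -> None:
    """Write a regulatory network edge table deterministically.

    Accepts either an edge DataFrame (source, target, edge_type, r) or a
    :class:`micronet.network.RegulatoryNetwork`. Rows are ordered by
    (edge_type, source, target) lexicographically and r is printed with six
    decimals, so identical networks produce byte-identical files.
    """
    df = getattr(edges, "edges", edges)
    df = pd.DataFrame(df, columns=EDGE_COLUMNS)
    df = df.sort_values(["edge_type", "source", "target"], kind="mergesort")
    df["r"] = df["r"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str, "edge_type": str})
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["r"] = df["r"].astype(float)
    return df
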