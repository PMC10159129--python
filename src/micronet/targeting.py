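"""7mer-m8 seed extraction and exact-match interrogation of 3'UTRs.

The seed site of a mature miRNA is taken from its 5' end: nucleotides 2-8
(1-based, seven bases), converted to the DNA alphabet (U -> T) and
reverse-complemented. That DNA string is searched, exactly and on the given
strand only, along each 3'UTR; every (possibly overlapping) occurrence is a
putative binding site. Matching is binary at the gene level — a gene counts
as targeted if any of its UTR isoforms carries at least one site. No G:U
wobble, no mismatches, and no other site classes (6mer, 8mer) are
considered. Offsets are 0-based.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io import SequenceRecord, utr_gene_id

__all__ = [
    "extract_seed_site",
    "scan_utrs",
    "scan_all",
    "group_mirnas_by_seed",
    "targeted_fraction",
]

SEED_LEN = 7
_ALPHABET = set("ACGTU")


def extract_seed_site(mature: SequenceRecord) -> str:
    """DNA search site for a mature miRNA: reverse complement of seed nt 2-8.

    The mature sequence may be in RNA (ACGU) or DNA (ACGT) alphabet and must
    be at least 8 nt long.
    """
    seq = mature.seq.upper()
    if len(seq) < 8:
        raise ValueError(f"mature miRNA {mature.id!r} is {len(seq)} nt; need >= 8 for a 7mer-m8 seed")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"mature miRNA {mature.id!r} contains non-ACGTU characters: {sorted(bad)}")
    seed = seq[1:8].replace("U", "T")
    return str(Seq(seed).reverse_complement())


def _find_overlapping(haystack: str, needle: str) -> list[int]:
    """All (overlapping) exact occurrences of ``needle``; N never matches."""
    offsets = []
    start = haystack.find(needle)
    while start != -1:
        offsets.append(start)
        start = haystack.find(needle, start + 1)
    return offsets


def scan_utrs(mirna_id: str, site: str, utrs: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Scan one miRNA's site along a UTR collection.

    UTR isoform ids with a trailing ``.N`` suffix are pooled to their parent
    gene; a gene's offsets are the sorted union over isoforms. Genes without
    a match are absent from the table.

    Returns a DataFrame with columns mirna_id, seed7, gene_id, n_sites,
    offsets (comma-joined string of 0-based starts).
    """
    if len(site) != SEED_LEN:
        raise ValueError(f"site must be {SEED_LEN} nt, got {len(site)}")
    per_gene: dict[str, set[int]] = {}
    for rec in utrs:
        offsets = _find_overlapping(rec.seq.upper().replace("U", "T"), site)
        if offsets:
            per_gene.setdefault(utr_gene_id(rec.id), set()).update(offsets)
    rows = [
        {
            "mirna_id": mirna_id,
            "seed7": site,
            "gene_id": gene,
            "n_sites": len(offs),
            "offsets": ",".join(str(o) for o in sorted(offs)),
        }
        for gene, offs in sorted(per_gene.items())
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "seed7", "gene_id", "n_sites", "offsets"])


def scan_all(mirnas: Sequence[SequenceRecord], utrs: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Seed-match table for every miRNA in a collection against the UTRs."""
    tables = [scan_utrs(rec.id, extract_seed_site(rec), utrs) for rec in mirnas]
    if not tables:
        return pd.DataFrame(columns=["mirna_id", "seed7", "gene_id", "n_sites", "offsets"])
    return pd.concat(tables, ignore_index=True)


def group_mirnas_by_seed(mirnas: Sequence[SequenceRecord]) -> dict[str, list[str]]:
    """Group miRNA ids sharing an identical 7mer-m8 site (site -> sorted ids).

    Distinct mature miRNAs can carry the same seed and are then
    indistinguishable to the scan, so targeting summaries pool them.
    """
    groups: dict[str, list[str]] = {}
    for rec in mirnas:
        groups.setdefault(extract_seed_site(rec), []).append(rec.id)
    return {site: sorted(ids) for site, ids in groups.items()}


def _pct(count: int, total: int) -> float:
    """Percentage with round-half-up to 2 decimals (so 28.935 -> 28.94)."""
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def targeted_fraction(
    matches: pd.DataFrame,
    de_genes: Iterable[str],
    de_mirna_groups: Mapping[str, Sequence[str]] | Sequence[str],
) -> pd.DataFrame:
    """Per-miRNA-group counts and percentages of targeted DE genes.

    Parameters
    ----------
    matches
        Seed-match table (``scan_all`` output).
    de_genes
        The differentially expressed genes; percentages are over this set.
    de_mirna_groups
        Either a mapping group label -> member miRNA ids (seed-sharing
        miRNAs pooled under one label) or a flat sequence of DE miRNA ids,
        in which case each id is its own group.

    Returns
    -------
    DataFrame with columns mirna_group, n_targeted_degs, pct_of_degs; one
    row per group plus a final ``all_de_mirnas`` union row.
    """
    de_genes = set(de_genes)
    if not de_genes:
        raise ValueError("de_genes must be non-empty")
    if not isinstance(de_mirna_groups, Mapping):
        de_mirna_groups = {m: [m] for m in de_mirna_groups}

    hits = matches[matches["n_sites"] >= 1]
    targets_by_mirna: dict[str, set[str]] = {
        m: set(sub["gene_id"]) & de_genes for m, sub in hits.groupby("mirna_id")
    }

    rows = []
    union: set[str] = set()
    for label in sorted(de_mirna_groups):
        members = de_mirna_groups[label]
        targeted = set().union(*(targets_by_mirna.get(m, set()) for m in members))
        union |= targeted
        rows.append(
            {
                "mirna_group": label,
                "n_targeted_degs": len(targeted),
                "pct_of_degs": _pct(len(targeted), len(de_genes)),
            }
        )
    rows.append(
        {
            "mirna_group": "all_de_mirnas",
            "n_targeted_degs": len(union),
            "pct_of_degs": _pct(len(union), len(de_genes)),
        }
    )
    return pd.DataFrame(rows, columns=["mirna_group", "n_targeted_degs", "pct_of_degs"])
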