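"""Assembly of the final miRNA-mRNA regulatory network.

Two typed edge sets are combined into one table:

* ``miRNA_mRNA`` — directed, repressive. A miRNA m and gene g are linked
  iff both are differentially expressed (their own layer's thresholds),
  their expression correlation is r < -0.50, the edge survives the PCIT
  filter (optional via ``require_pcit``), and g's 3'UTR carries at least
  one exact 7mer-m8 site for m's seed.
* ``mRNA_mRNA`` — undirected co-expression between a targeted gene and any
  other DE gene at |r| > 0.7 (plus PCIT), stored with lexicographically
  ordered endpoints. The stricter cutoff reflects that mRNA-mRNA
  expression correlations typically run higher in magnitude than
  miRNA-mRNA ones.

All threshold comparisons are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .pcit import PcitEdgeSet

__all__ = ["RegulatoryNetwork", "mirna_mrna_edges", "mrna_mrna_edges", "assemble_network"]

EDGE_MIRNA = "miRNA_mRNA"
EDGE_MRNA = "mRNA_mRNA"


@dataclass
class RegulatoryNetwork:
    """Typed edge list: columns source, target, edge_type, r."""

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["source", "target", "edge_type", "r"])
    )

    def __post_init__(self) -> None:
        self.edges = pd.DataFrame(self.edges, columns=["source", "target", "edge_type", "r"])
        if self.edges.duplicated(["source", "target", "edge_type"]).any():
            raise ValueError("duplicate edges in network")

    @property
    def mirna_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["edge_type"] == EDGE_MIRNA]

    @property
    def mrna_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["edge_type"] == EDGE_MRNA]


def _r_lookup(pcit: PcitEdgeSet, a: str, b: str) -> float:
    missing = a if a not in pcit.r.index else (b if b not in pcit.r.index else None)
    if missing is not None:
        raise KeyError(
            f"node {missing!r} missing from the PCIT edge set; "
            "PCIT must be computed on the union of DE miRNAs and DE mRNAs"
        )
    return float(pcit.r.at[a, b])


def mirna_mrna_edges(
    de_mirnas: Iterable[str],
    de_mrnas: Iterable[str],
    pcit: PcitEdgeSet,
    matches: pd.DataFrame,
    r_max: float = -0.50,
    require_pcit: bool = True,
) -> pd.DataFrame:
    """Directed repressive miRNA -> mRNA edges.

    ``matches`` is a seed-match table; a pair qualifies only with
    n_sites >= 1 recorded there. ``r_max`` is the strict upper bound on the
    (negative) correlation.
    """
    de_mirnas, de_mrnas = set(de_mirnas), set(de_mrnas)
    matched_pairs = {
        (m, g)
        for m, g, n in matches[["mirna_id", "gene_id", "n_sites"]].itertuples(index=False)
        if n >= 1
    }
    rows = []
    for m in sorted(de_mirnas):
        for g in sorted(de_mrnas):
            if (m, g) not in matched_pairs:
                continue
            r = _r_lookup(pcit, m, g)
            if r < r_max and (not require_pcit or bool(pcit.significant.at[m, g])):
                rows.append({"source": m, "target": g, "edge_type": EDGE_MIRNA, "r": r})
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "r"])


def mrna_mrna_edges(
    targeted_genes: Iterable[str],
    de_mrnas: Iterable[str],
    pcit: PcitEdgeSet,
    r_min_abs: float = 0.7,
    require_pcit: bool = True,
) -> pd.DataFrame:
    """Undirected co-expression edges between targeted genes and other DE genes.

    Endpoints are stored lexicographically ordered; no self loops; each
    unordered pair appears at most once.
    """
    targeted, de_mrnas = set(targeted_genes), set(de_mrnas)
    if not targeted <= de_mrnas:
        raise ValueError("targeted_genes must be a subset of the DE mRNAs")
    seen: set[tuple[str, str]] = set()
    rows = []
    for g1 in sorted(targeted):
        for g2 in sorted(de_mrnas):
            if g1 == g2:
                continue
            pair = tuple(sorted((g1, g2)))
            if pair in seen:
                continue
            r = _r_lookup(pcit, g1, g2)
            if abs(r) > r_min_abs and (not require_pcit or bool(pcit.significant.at[g1, g2])):
                seen.add(pair)
                rows.append({"source": pair[0], "target": pair[1], "edge_type": EDGE_MRNA, "r": r})
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "r"])


def assemble_network(
    de_mirnas: Iterable[str],
    de_mrnas: Iterable[str],
    pcit: PcitEdgeSet,
    matches: pd.DataFrame,
    r_max: float = -0.50,
    r_min_abs: float = 0.7,
    require_pcit: bool = True,
) -> RegulatoryNetwork:
    """Full network: repressive miRNA->mRNA edges plus the co-expression shell
    around the targeted genes."""
    mi = mirna_mrna_edges(de_mirnas, de_mrnas, pcit, matches, r_max, require_pcit)
    targeted = sorted(set(mi["target"]))
    mm = mrna_mrna_edges(targeted, de_mrnas, pcit, r_min_abs, require_pcit)
    parts = [df for df in (mi, mm) if not df.empty]
    if not parts:
        return RegulatoryNetwork()
    edges = pd.concat(parts, ignore_index=True)
    edges = edges.sort_values(["edge_type", "source", "target"], kind="mergesort").reset_index(drop=True)
    return RegulatoryNetwork(edges)
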