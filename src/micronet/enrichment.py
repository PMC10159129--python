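"""One-sided hypergeometric over-representation with BH FDR control.

For a term annotating K genes in a universe of N, with n selected genes of
which k are annotated, the enrichment p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n). The universe is the set of expressed
genes (post count filter), not the whole annotation, matching standard
practice for expression studies. Terms annotating fewer than ``min_term``
universe genes are skipped as degenerate. Benjamini-Hochberg adjustment is
applied across the tested terms.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_enrich", "read_annotation"]

RESULT_COLUMNS = ["term_id", "universe_size", "annotated", "selected", "overlap", "p_value", "p_adj"]


def read_annotation(path) -> pd.DataFrame:
    """Two-column gene -> term TSV (header gene_id, term_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "term_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def hypergeom_enrich(
    selected: Iterable[str],
    annotation: pd.DataFrame | Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    min_term: int = 3,
) -> pd.DataFrame:
    """Test every annotation term for over-representation in ``selected``.

    Parameters
    ----------
    selected
        Gene set of interest (e.g. the DE genes); must be a subset of
        ``universe``.
    annotation
        Either a DataFrame with gene_id/term_id columns or a mapping
        gene -> iterable of terms. Restricted to the universe before
        testing.
    universe
        Background gene set (the expressed genes).
    alpha
        FDR level recorded in the ``enriched`` call column.
    min_term
        Minimum number of universe genes a term must annotate to be tested.

    Returns
    -------
    DataFrame with one row per tested term, sorted by (p_adj, term_id).
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not selected:
        raise ValueError("selected gene set must be non-empty")
    if not selected <= universe:
        extra = sorted(selected - universe)[:5]
        raise ValueError(f"selected genes outside the universe, e.g. {extra}")

    if isinstance(annotation, pd.DataFrame):
        pairs = annotation[["gene_id", "term_id"]].itertuples(index=False)
    else:
        pairs = ((g, t) for g, terms in annotation.items() for t in terms)
    term_genes: dict[str, set[str]] = {}
    for gene, term in pairs:
        if gene in universe:
            term_genes.setdefault(term, set()).add(gene)

    N, n = len(universe), len(selected)
    skipped = [t for t, genes in term_genes.items() if len(genes) < min_term]
    if skipped:
        logger.info("skipping %d term(s) annotating < %d universe genes", len(skipped), min_term)

    rows = []
    for term, genes in term_genes.items():
        K = len(genes)
        if K < min_term:
            continue
        k = len(genes & selected)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "universe_size": N,
                "annotated": K,
                "selected": n,
                "overlap": k,
                "p_value": min(1.0, p),
            }
        )
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(result):
        result["p_adj"] = multipletests(result["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        result["p_adj"] = pd.Series(dtype=float)
    result["enriched"] = result["p_adj"] < alpha
    return result.sort_values(["p_adj", "term_id"], kind="mergesort").reset_index(drop=True)
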