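"""Local hypergeometric gene-set enrichment and multi-term intersection.

For a query gene set of size q drawn from a universe of N genes of which K
carry a term, the enrichment p-value is the upper-tail hypergeometric
probability of observing ≥ m overlapping genes.  P-values are adjusted by
Benjamini–Hochberg within each namespace (BP, CC, MF, pathway) so that GO
branches and pathway collections are corrected as separate families.

``intersect_terms`` reproduces the final nomination step: the genes present
in *every* selected GO term and in at least ``pathway_min`` of the selected
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import AnnotationSet

__all__ = ["EnrichmentResult", "IntersectionReport", "hypergeom_enrich", "intersect_terms"]

RESULT_COLUMNS = [
    "term_id", "term_name", "namespace", "overlap", "term_size",
    "query_size", "universe_size", "p_value", "adjusted_p", "genes",
]


@dataclass
class EnrichmentResult:
    """Tidy per-term enrichment table (one row per annotated term)."""

    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adjusted_p"] <= alpha]

    def overlap_genes(self, term_id: str) -> set[str]:
        row = self.table[self.table["term_id"] == term_id]
        if row.empty:
            raise KeyError(f"unknown term id {term_id!r}")
        g = row["genes"].iloc[0]
        return set(g.split(",")) if g else set()


@dataclass
class IntersectionReport:
    selected_go_terms: list[str]
    selected_pathways: list[str]
    pathway_min: int
    gene_term_counts: pd.DataFrame  # gene × (n_go_terms, n_pathways)
    final_genes: list[str]


def hypergeom_enrich(
    query: set[str],
    annotation: AnnotationSet,
    universe: set[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test per term.

    The annotation is intersected with the universe first; query genes
    outside the universe are dropped.  Rows are sorted by p-value (ties by
    term id); BH adjustment is applied within each namespace.
    """
    if not universe:
        raise ValueError("universe is empty")
    q_set = set(query) & set(universe)
    if not q_set:
        raise ValueError("query is empty (or disjoint from the universe)")
    ann = annotation.restrict(set(universe))
    n_univ = len(universe)
    rows = []
    for tid in sorted(ann.terms):
        t = ann.terms[tid]
        overlap = sorted(t.genes & q_set)
        m, big_k, q = len(overlap), len(t.genes), len(q_set)
        p = float(hypergeom.sf(m - 1, n_univ, big_k, q))
        rows.append(
            {
                "term_id": tid,
                "term_name": t.name,
                "namespace": t.namespace,
                "overlap": m,
                "term_size": big_k,
                "query_size": q,
                "universe_size": n_univ,
                "p_value": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = 1.0
    for ns, idx in table.groupby("namespace").groups.items():
        adj = multipletests(table.loc[idx, "p_value"], method="fdr_bh")[1]
        table.loc[idx, "adjusted_p"] = adj
    table = table.sort_values(
        ["p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return EnrichmentResult(table[RESULT_COLUMNS])


def intersect_terms(
    results: EnrichmentResult,
    selected_go_terms: list[str],
    selected_pathways: list[str],
    pathway_min: int = 3,
) -> IntersectionReport:
    """Genes present in all selected GO terms and ≥ ``pathway_min`` of the
    selected pathways (overlap-with-query genes, per the enrichment table)."""
    for tid in list(selected_go_terms) + list(selected_pathways):
        if tid not in set(results.table["term_id"]):
            raise KeyError(f"unknown term id {tid!r}")
    go_sets = [results.overlap_genes(t) for t in selected_go_terms]
    pw_sets = [results.overlap_genes(t) for t in selected_pathways]
    all_genes = sorted(set().union(*go_sets, *pw_sets)) if (go_sets or pw_sets) else []
    counts = pd.DataFrame(
        {
            "n_go_terms": [sum(g in s for s in go_sets) for g in all_genes],
            "n_pathways": [sum(g in s for s in pw_sets) for g in all_genes],
        },
        index=pd.Index(all_genes, name="gene_id"),
    )
    in_all_go = (
        counts["n_go_terms"] == len(selected_go_terms)
        if selected_go_terms
        else pd.Series(True, index=counts.index)
    )
    final = counts.index[in_all_go & (counts["n_pathways"] >= pathway_min)]
    return IntersectionReport(
        selected_go_terms=list(selected_go_terms),
        selected_pathways=list(selected_pathways),
        pathway_min=pathway_min,
        gene_term_counts=counts,
        final_genes=sorted(final),
    )
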