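"""Rank-based cell-type assignment and signature-expression clustering.

A query gene list (e.g. a region signature ranked by correlation strength)
is matched against a multi-source reference of ranked cell-type marker
lists.  The per-entry match score rewards overlap genes that rank highly in
the reference entry, penalises rank disagreement between query and entry,
and normalises by the entry's marker-list length:

    score = (1/n_c) * sum over overlap g of
            [(n_c - r_C(g) + 1) / n_c] * [1 - |r_Q(g) - r_C(g)| / max(n_Q, n_c)]

Because one cell type appears in several source datasets, per-entry scores
are aggregated by summation over entries (mean x occurrence count) and a
type is CALLED when its aggregate exceeds the mean aggregate across types by
more than ``sd_multiplier`` standard deviations.  The scoring formula is a
faithful realisation of the qualitative contract of commercial rank-based
matchers (gene rank, rank difference, list-length normalisation); it is not
claimed to reproduce any proprietary score numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .util import get_logger

log = get_logger("cell_ontology")


@dataclass(frozen=True)
class CellTypeEntry:
    """Ranked marker-gene list for one cell type from one source dataset."""

    ontology_id: str
    cell_type_name: str
    source_id: str
    ranked_genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.ranked_genes) < 1:
            raise ValueError("entry needs at least one gene")
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise ValueError("duplicate genes within an entry")


@dataclass(frozen=True)
class MatchResult:
    entry: CellTypeEntry
    score: float
    overlap_size: int


def match_score(query: Sequence[str], entry: CellTypeEntry) -> MatchResult:
    """Rank-based match between a ranked query list and one reference entry."""
    if not query:
        raise ValueError("query must be non-empty")
    n_q = len(query)
    n_c = len(entry.ranked_genes)
    q_rank = {g: i + 1 for i, g in enumerate(query)}
    denom = max(n_q, n_c)
    score = 0.0
    overlap = 0
    for rc, g in enumerate(entry.ranked_genes, start=1):
        rq = q_rank.get(g)
        if rq is None:
            continue
        overlap += 1
        rank_weight = (n_c - rc + 1) / n_c
        rank_agreement = 1.0 - abs(rq - rc) / denom
        score += rank_weight * rank_agreement
    return MatchResult(entry=entry, score=score / n_c, overlap_size=overlap)


def score_reference(query: Sequence[str],
                    reference: Sequence[CellTypeEntry]) -> list[MatchResult]:
    """Score every reference entry; descending by score, ties by entry id."""
    if not reference:
        raise ValueError("reference must be non-empty")
    results = [match_score(query, e) for e in reference]
    return sorted(results, key=lambda m: (-m.score, m.entry.ontology_id,
                                          m.entry.source_id))


def aggregate_and_call(results: Sequence[MatchResult],
                       sd_multiplier: float = 1.0) -> pd.DataFrame:
    """Occurrence-weighted aggregation and mean + k*SD calling.

    aggregate(type) = sum of its entries' scores.  A type is called iff its
    aggregate strictly exceeds mean(aggregates) + sd_multiplier *
    sd(aggregates) (sample SD).  With a single type everything is trivially
    called (warned).  Entry order does not affect the result.
    """
    agg: dict[str, dict] = {}
    for m in results:
        rec = agg.setdefault(m.entry.ontology_id, {
            "ontology_id": m.entry.ontology_id,
            "cell_type_name": m.entry.cell_type_name,
            "n_entries": 0, "aggregate": 0.0})
        rec["n_entries"] += 1
        rec["aggregate"] += m.score
    table = pd.DataFrame(sorted(agg.values(), key=lambda r: r["ontology_id"]))
    values = table["aggregate"].to_numpy()
    if len(table) < 2:
        log.warning("single cell type: calling threshold undefined, all called")
        table["called"] = True
        table["threshold"] = float("nan")
        return table.sort_values("aggregate", ascending=False).reset_index(drop=True)
    threshold = values.mean() + sd_multiplier * values.std(ddof=1)
    table["threshold"] = threshold
    table["called"] = table["aggregate"] > threshold
    return table.sort_values(["aggregate", "ontology_id"],
                             ascending=[False, True]).reset_index(drop=True)


@dataclass
class ClusteringResult:
    """Hierarchical clustering of signature genes across expression clusters."""

    matrix: pd.DataFrame
    gene_linkage: np.ndarray
    cluster_linkage: np.ndarray
    gene_order: list[str]
    cluster_order: list[str]


def cluster_signature_expression(cluster_avg_expr: pd.DataFrame | Mapping,
                                 signature: Sequence[str]) -> ClusteringResult:
    """Agglomerative clustering (Euclidean distance, average linkage) of
    signature genes over expression clusters, and of the clusters over genes.

    ``cluster_avg_expr`` is genes x clusters, or a mapping patient ->
    ClusterExpression whose matrices are concatenated with
    "patient:cluster|celltype" column labels.  Signature genes missing from
    the matrix are dropped with a warning; fewer than 2 remaining genes (or
    2 clusters) is an error.  Rows are pre-sorted by gene label so leaf
    order is deterministic.
    """
    if isinstance(cluster_avg_expr, Mapping):
        parts = []
        for pid, ce in cluster_avg_expr.items():
            part = ce.values.copy()
            part.columns = [f"{pid}:{c}|{ce.cell_types[c]}" for c in part.columns]
            parts.append(part)
        matrix = pd.concat(parts, axis=1)
    else:
        matrix = cluster_avg_expr
    present = [g for g in sorted(set(signature)) if g in matrix.index]
    missing = sorted(set(signature) - set(present))
    if missing:
        log.warning("%d signature gene(s) absent from the matrix: %s",
                    len(missing), ", ".join(missing[:5]))
    if len(present) < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 clusters to cluster")
    sub = matrix.loc[present]
    gene_link = linkage(sub.to_numpy(), method="average", metric="euclidean")
    clus_link = linkage(sub.to_numpy().T, method="average", metric="euclidean")
    gene_order = [present[i] for i in leaves_list(gene_link)]
    cluster_order = [sub.columns[i] for i in leaves_list(clus_link)]
    return ClusteringResult(matrix=sub, gene_linkage=gene_link,
                            cluster_linkage=clus_link, gene_order=gene_order,
                            cluster_order=cluster_order)
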