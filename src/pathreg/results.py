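"""Presentation of enrichment results: ranked tables and similarity networks.

Terms are ranked by the absolute value of their regression coefficient
(strongest dysregulation first).  The network view connects top-ranked terms
whose pairwise similarity exceeds a threshold, exposing functional modules as
connected components; isolated terms are dropped from the view.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .genesets import MembershipMatrix, SimilarityMatrix
from .model import EnrichmentFit, ResponseVector

__all__ = ["rank_terms", "build_network", "write_network"]

logger = logging.getLogger(__name__)


def _term_stats(fit: EnrichmentFit, X: MembershipMatrix | None,
                y: ResponseVector | None, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    k = len(fit.term_ids)
    sizes = np.full(k, np.nan)
    frac_sig = np.full(k, np.nan)
    if X is not None:
        if tuple(X.term_ids) != tuple(fit.term_ids):
            raise ValueError("membership matrix term labels do not match the fit")
        sizes = X.column_sums()
        if y is not None:
            sig = (y.values < alpha).astype(float)
            with np.errstate(invalid="ignore"):
                frac_sig = (X.values.T @ sig) / np.where(sizes > 0, sizes, np.nan)
    return sizes, frac_sig


def rank_terms(fit: EnrichmentFit, top_n: int | None = None,
               X: MembershipMatrix | None = None, y: ResponseVector | None = None,
               alpha: float = 0.05) -> pd.DataFrame:
    """Rank terms by |beta| descending (ties broken by term_id ascending).

    With ``X`` and ``y`` supplied, each row also reports the term size within
    the gene universe and the fraction of member genes with P < ``alpha``.
    """
    k = len(fit.term_ids)
    top_n = k if top_n is None else top_n
    if not (1 <= top_n <= k):
        raise ValueError(f"top_n must lie in [1, {k}]")
    sizes, frac_sig = _term_stats(fit, X, y, alpha)
    df = pd.DataFrame({
        "term_id": list(fit.term_ids),
        "beta": fit.beta,
        "abs_beta": np.abs(fit.beta),
        "term_size": sizes,
        "frac_significant": frac_sig,
    })
    df = df.sort_values(["abs_beta", "term_id"], ascending=[False, True],
                        kind="mergesort").head(top_n)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


def build_network(fit: EnrichmentFit, S: SimilarityMatrix, top_n: int = 50,
                  edge_threshold: float = 0.1, X: MembershipMatrix | None = None,
                  y: ResponseVector | None = None, alpha: float = 0.05) -> nx.Graph:
    """Similarity network of the top terms: edges where similarity > threshold.

    Takes the ``top_n`` terms by |beta|, connects pairs whose similarity
    strictly exceeds ``edge_threshold``, and drops isolated nodes.  Node
    attributes: enrichment (signed beta), term_size, frac_significant.
    """
    if tuple(S.term_ids) != tuple(fit.term_ids):
        raise ValueError("similarity matrix labels do not match the fit")
    top = rank_terms(fit, top_n=min(top_n, len(fit.term_ids)), X=X, y=y, alpha=alpha)
    idx = {t: i for i, t in enumerate(fit.term_ids)}
    graph = nx.Graph()
    for _, row in top.iterrows():
        graph.add_node(row.term_id, enrichment=float(row.beta),
                       term_size=float(row.term_size),
                       frac_significant=float(row.frac_significant))
    terms = list(top.term_id)
    for a in range(len(terms)):
        for b in range(a + 1, len(terms)):
            sim = float(S.values[idx[terms[a]], idx[terms[b]]])
            if sim > edge_threshold:
                graph.add_edge(terms[a], terms[b], similarity=sim)
    isolated = [n for n in graph.nodes if graph.degree(n) == 0]
    graph.remove_nodes_from(isolated)
    if graph.number_of_nodes() == 0:
        logger.warning("all top terms are isolated at threshold %g; network is empty",
                       edge_threshold)
    return graph


def write_network(graph: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    """Serialize a network as GraphML and/or a plain edge-list TSV."""
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    if edgelist_path is not None:
        rows = [{"term_a": a, "term_b": b, "similarity": d["similarity"]}
                for a, b, d in graph.edges(data=True)]
        pd.DataFrame(rows, columns=["term_a", "term_b", "similarity"]).to_csv(
            edgelist_path, sep="\t", index=False)
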