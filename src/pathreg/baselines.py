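"""Reference enrichment methods for benchmarking: Fisher's exact test and a random null.

All methods emit a :class:`TermScoreTable` in which larger scores mean
stronger enrichment, the common currency consumed by the evaluation module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import MembershipMatrix
from .model import EnrichmentFit, ResponseVector

__all__ = [
    "TermScoreTable",
    "fisher_exact_enrichment",
    "null_model_scores",
    "fit_to_score_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermScoreTable:
    """Per-term enrichment scores, higher = more enriched.

    ``raw_values`` keeps the method's native quantity (e.g. the Fisher
    P-value) alongside the oriented score.
    """

    term_ids: tuple[str, ...]
    scores: np.ndarray
    score_kind: str  # abs_beta | one_minus_p | neg_log_p | random
    method_name: str
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.term_ids),):
            raise ValueError("one score per term required")
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        if len(set(self.term_ids)) != len(self.term_ids):
            raise ValueError("duplicate term ids")
        object.__setattr__(self, "scores", s)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"term_id": list(self.term_ids), "score": self.scores,
                           "method": self.method_name})
        if self.raw_values is not None:
            df["raw_value"] = self.raw_values
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, method_name: str | None = None) -> "TermScoreTable":
        df = pd.read_csv(path, sep="\t")
        name = method_name or (str(df["method"].iloc[0]) if "method" in df else "external")
        raw = df["raw_value"].to_numpy(float) if "raw_value" in df else None
        return cls(term_ids=tuple(df["term_id"].astype(str)),
                   scores=df["score"].to_numpy(float),
                   score_kind="external", method_name=name, raw_values=raw)


def fisher_exact_enrichment(y: ResponseVector, X: MembershipMatrix,
                            de_threshold: float = 0.05) -> TermScoreTable:
    """One-sided Fisher's exact test for over-representation of DE genes per term.

    Genes with P < ``de_threshold`` are called differentially expressed; each
    term is tested for DE over-representation against the rest of the universe
    with the exact hypergeometric tail.  Scores are 1 - p (larger = more
    enriched); raw P-values are retained.
    """
    if not (0.0 < de_threshold < 1.0):
        raise ValueError("de_threshold must lie in (0, 1)")
    if tuple(y.gene_ids) != tuple(X.gene_ids):
        raise ValueError("response and membership matrix gene labels differ")
    de = y.values < de_threshold
    n_de = int(de.sum())
    n = X.n_genes
    if n_de == 0:
        logger.warning("no gene below the DE threshold %g; all Fisher p-values are 1",
                       de_threshold)
    pvals = np.ones(X.n_terms)
    for j in range(X.n_terms):
        in_term = X.values[:, j] > 0
        a = int((de & in_term).sum())        # DE and in term
        b = int((de & ~in_term).sum())       # DE, outside term
        c = int((~de & in_term).sum())       # not DE, in term
        d = n - a - b - c
        _, pvals[j] = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return TermScoreTable(term_ids=tuple(X.term_ids), scores=1.0 - pvals,
                          score_kind="one_minus_p", method_name="fisher",
                          raw_values=pvals)


def null_model_scores(term_ids, seed: int = 0) -> TermScoreTable:
    """Random baseline: i.i.d. Uniform(0, 1) pseudo-P-values per term, scored as 1 - p."""
    term_ids = tuple(term_ids)
    if len(term_ids) < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=len(term_ids))
    return TermScoreTable(term_ids=term_ids, scores=1.0 - p, score_kind="random",
                          method_name="null", raw_values=p)


def fit_to_score_table(fit: EnrichmentFit) -> TermScoreTable:
    """Score terms of a regression fit by |beta| (ranking is sign-invariant)."""
    return TermScoreTable(term_ids=tuple(fit.term_ids), scores=np.abs(fit.beta),
                          score_kind="abs_beta", method_name="pathreg",
                          raw_values=fit.beta.copy())
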