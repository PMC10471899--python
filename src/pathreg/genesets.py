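"""Gene-set databases, membership matrices, and term-term similarity.

A gene-set database is an ordered collection of named terms (pathways), each
an unstructured set of gene identifiers.  From a database and a measured gene
universe we derive the binary N x K membership matrix X that serves as the
regression design, and K x K similarity matrices (Jaccard or overlap
coefficient) that serve both as the network-fusion penalty weights and as the
sampling bias of the synthetic-benchmark ground-truth sampler.

Gene identifiers are matched by exact, case-sensitive string equality; any
symbol aliasing or identifier conversion must happen upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetDatabase",
    "MembershipMatrix",
    "SimilarityMatrix",
    "read_gmt",
    "write_gmt",
    "filter_by_size",
    "membership_matrix",
    "jaccard_matrix",
    "overlap_matrix",
]


class GmtParseError(ValueError):
    """Raised when a GMT file line cannot be parsed."""


@dataclass(frozen=True)
class GeneSet:
    """A single named term: a set of gene identifiers with a description."""

    term_id: str
    description: str
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetDatabase:
    """An ordered collection of terms with unique ids.

    Term order is stable: the j-th term always maps to column j of any
    matrix derived from this database.
    """

    terms: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ValueError("a gene-set database must contain at least one term")
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate term ids: {dupes}")
        for t in self.terms:
            if t.size < 1:
                raise ValueError(f"term {t.term_id!r} has no genes")
            if any((not isinstance(g, str)) or g == "" for g in t.genes):
                raise ValueError(f"term {t.term_id!r} contains an empty gene identifier")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([t.size for t in self.terms], dtype=int)

    def gene_universe(self) -> list[str]:
        """Sorted union of all member genes (deterministic universe)."""
        union: set[str] = set()
        for t in self.terms:
            union |= t.genes
        return sorted(union)

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> GeneSet:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


@dataclass(frozen=True)
class MembershipMatrix:
    """Binary gene-by-term membership matrix X with x_ij = 1 iff gene i is in term j."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    term_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("membership matrix must be two-dimensional")
        if v.shape != (len(self.gene_ids), len(self.term_ids)):
            raise ValueError(
                f"shape {v.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.term_ids)} terms"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValueError("membership entries must be exactly 0 or 1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.term_ids)) != len(self.term_ids):
            raise ValueError("duplicate term ids")
        object.__setattr__(self, "values", v.astype(np.float64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.term_ids))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric K x K term-term similarity with entries in [0, 1]."""

    values: np.ndarray
    term_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.term_ids)
        if v.shape != (k, k):
            raise ValueError(f"similarity matrix shape {v.shape} does not match {k} terms")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("similarity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=list(self.term_ids), columns=list(self.term_ids))
        df.to_csv(path, sep="\t", float_format="%.8g")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("similarity TSV row and column labels differ")
        return cls(values=df.to_numpy(dtype=float), term_ids=tuple(str(t) for t in df.columns))


def read_gmt(path) -> GeneSetDatabase:
    """Read a GMT gene-set file (term, description, genes..., tab-separated).

    Genes are deduplicated within a term; file order is preserved.  Lines with
    fewer than three fields raise :class:`GmtParseError` naming the line.
    """
    terms: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields "
                    f"(term, description, >=1 gene), got {len(fields)}"
                )
            genes = frozenset(g for g in fields[2:] if g != "")
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: term {fields[0]!r} lists no genes")
            terms.append(GeneSet(term_id=fields[0], description=fields[1], genes=genes))
    if not terms:
        raise GmtParseError(f"{path}: file contains no gene sets")
    return GeneSetDatabase(terms=tuple(terms))


def write_gmt(db: GeneSetDatabase, path) -> None:
    """Write a database back to GMT (genes sorted for determinism)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in db.terms:
            fh.write("\t".join([t.term_id, t.description, *sorted(t.genes)]) + "\n")


def filter_by_size(db: GeneSetDatabase, min_size: int, max_size: int) -> GeneSetDatabase:
    """Keep terms whose full gene-list size lies in [min_size, max_size], inclusive.

    Sizes are counted on the term's full gene list, not its intersection with
    any particular gene universe.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(f"need 1 <= min_size <= max_size, got [{min_size}, {max_size}]")
    kept = tuple(t for t in db.terms if min_size <= t.size <= max_size)
    if not kept:
        raise ValueError(
            f"no terms with size in [{min_size}, {max_size}] "
            f"(database sizes span [{db.sizes.min()}, {db.sizes.max()}]); loosen the bounds"
        )
    return GeneSetDatabase(terms=kept)


def membership_matrix(db: GeneSetDatabase, gene_universe) -> MembershipMatrix:
    """Build the binary N x K membership matrix over an ordered gene universe.

    Rows follow ``gene_universe`` order, columns follow database term order.
    Universe genes belonging to no term yield all-zero rows and are kept.
    """
    universe = list(gene_universe)
    if not universe:
        raise ValueError("gene universe must be non-empty")
    if len(set(universe)) != len(universe):
        raise ValueError("gene universe contains duplicate identifiers")
    x = np.zeros((len(universe), db.n_terms), dtype=np.float64)
    index = {g: i for i, g in enumerate(universe)}
    for j, term in enumerate(db.terms):
        for g in term.genes:
            i = index.get(g)
            if i is not None:
                x[i, j] = 1.0
    return MembershipMatrix(values=x, gene_ids=tuple(universe), term_ids=tuple(db.term_ids))


def _pairwise(db: GeneSetDatabase, kind: str, gene_universe=None) -> SimilarityMatrix:
    gene_sets = [t.genes for t in db.terms]
    if gene_universe is not None:
        universe = frozenset(gene_universe)
        gene_sets = [g & universe for g in gene_sets]
        if any(len(g) == 0 for g in gene_sets):
            raise ValueError("a term is empty after restriction to the gene universe")
    k = len(gene_sets)
    # incidence-matrix trick: intersections via one integer matmul
    all_genes = sorted(set().union(*gene_sets))
    idx = {g: i for i, g in enumerate(all_genes)}
    inc = np.zeros((k, len(all_genes)), dtype=np.int64)
    for j, genes in enumerate(gene_sets):
        inc[j, [idx[g] for g in genes]] = 1
    inter = inc @ inc.T
    sizes = inc.sum(axis=1)
    if kind == "jaccard":
        denom = sizes[:, None] + sizes[None, :] - inter
    elif kind == "overlap":
        denom = np.minimum(sizes[:, None], sizes[None, :])
    else:  # pragma: no cover
        raise ValueError(kind)
    values = inter / denom
    return SimilarityMatrix(values=values, term_ids=tuple(db.term_ids))


def jaccard_matrix(db: GeneSetDatabase, gene_universe=None) -> SimilarityMatrix:
    """Jaccard similarity |Ti & Tj| / |Ti | Tj| between all term pairs.

    By default similarities use the full term gene lists; pass ``gene_universe``
    to restrict terms to measured genes first.
    """
    return _pairwise(db, "jaccard", gene_universe)


def overlap_matrix(db: GeneSetDatabase, gene_universe=None) -> SimilarityMatrix:
    """Overlap coefficient |Ti & Tj| / min(|Ti|, |Tj|) between all term pairs.

    Equals 1 whenever one term is a subset of the other, which makes it a
    natural choice for hierarchically organised collections.
    """
    return _pairwise(db, "overlap", gene_universe)
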