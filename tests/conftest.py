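import numpy as np
import pytest

from pathreg.genesets import GeneSet, GeneSetDatabase, MembershipMatrix, membership_matrix
from pathreg.model import ResponseVector


def make_db(sets: dict[str, set[str]]) -> GeneSetDatabase:
    """Build a database from a {term_id: genes} mapping (insertion order kept)."""
    return GeneSetDatabase(terms=tuple(
        GeneSet(term_id=k, description="", genes=frozenset(v)) for k, v in sets.items()
    ))


@pytest.fixture
def tiny_db() -> GeneSetDatabase:
    return make_db({"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g4"}})


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("A\tdescA\tg1\tg2\nB\tdescB\tg2\tg3\n")
    return path


def random_instance(seed: int, n: int = 30, k: int = 4):
    """A small random (y, X) pair for model tests."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=(n, k)).astype(float)
    x[0, 0] = 1.0  # ensure a nonzero column
    y = rng.uniform(0.01, 0.99, size=n)
    genes = tuple(f"g{i}" for i in range(n))
    terms = tuple(f"t{j}" for j in range(k))
    return (ResponseVector(values=y, gene_ids=genes),
            MembershipMatrix(values=x, gene_ids=genes, term_ids=terms))
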