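"""Synthetic differential-expression benchmarks with known enriched terms.

The generator emulates a DE experiment driven by a known set of activated
pathways: a term database (optionally with designed block/cluster structure
standing in for a real hierarchical collection), a similarity-biased sample
of activated terms D_A, a membership matrix degraded by annotation noise, and
per-gene P-values drawn from a beta distribution whose mean is the logistic
transform of the noisy linear predictor X_A beta_A.

Genes in no activated term have mean 1/2 and precision 1, i.e. their
simulated P-values are exactly Uniform(0, 1) — the correct behavior of a
well-calibrated DE test under the null.

Two generator dials mirror distinct real-world difficulties:

rho (similarity factor, in [0, 1])
    0 = activated terms are drawn uniformly; 1 = each next activated term is
    drawn proportionally to its similarity to the previously drawn one, so
    the ground truth forms a functional cluster.
eta (annotation noise, in [0, 1])
    the fraction of gene-to-activated-term memberships zeroed before
    simulating, weakening the link between truth and signal.

A master seed spawns independent child seeds for each step, so every step is
reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .genesets import GeneSet, GeneSetDatabase, MembershipMatrix, SimilarityMatrix, membership_matrix
from .model import ResponseVector

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_term_database",
    "sample_active_terms",
    "apply_membership_noise",
    "simulate_pvalues",
    "generate_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for one synthetic dataset.

    Defaults follow the benchmark design: 20 activated terms, activation
    coefficient -1, generative precision phi = 1.
    """

    n_active: int = 20
    rho: float = 0.0
    eta: float = 0.0
    phi: float = 1.0
    activation_value: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.n_active < 1:
            raise ValueError("n_active must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    active_terms: frozenset[str]
    beta_active: np.ndarray  # length-K activation vector b_k
    X_noisy: MembershipMatrix
    mu: np.ndarray  # per-gene generative means


@dataclass(frozen=True)
class SyntheticDataset:
    """Simulated P-values plus the truth that generated them."""

    truth: SyntheticTruth
    response: ResponseVector
    config: SyntheticConfig
    replicate_id: int = 0


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-step child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_term_database(n_terms: int, n_genes: int, size_range: tuple[int, int],
                           n_blocks: int = 1, within_block_overlap: float = 0.0,
                           seed: int = 0) -> GeneSetDatabase:
    """Generate a clustered term database over a synthetic gene pool.

    Terms are organised into ``n_blocks`` blocks.  Each block owns a seeded
    core gene list; a term of size L in that block takes its first
    ``round(within_block_overlap * L)`` genes as a prefix of the block core
    (so cores are nested, mimicking hierarchical collections) and draws the
    remainder uniformly from the rest of the pool.  Term sizes are uniform on
    ``size_range`` (inclusive).  Gene identifiers are "g000001", ... and term
    identifiers "T0001", ...
    """
    lo, hi = size_range
    if not (1 <= lo <= hi):
        raise ValueError("size_range must satisfy 1 <= min <= max")
    if not (1 <= n_blocks <= n_terms):
        raise ValueError("need 1 <= n_blocks <= n_terms")
    if not (0.0 <= within_block_overlap <= 1.0):
        raise ValueError("within_block_overlap must lie in [0, 1]")
    if hi > n_genes:
        raise ValueError(f"max term size {hi} exceeds gene pool size {n_genes}")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    pool = np.array([f"g{i:0{width}d}" for i in range(1, n_genes + 1)])

    block_of = np.arange(n_terms) % n_blocks
    cores = []
    for _ in range(n_blocks):
        cores.append(rng.choice(n_genes, size=hi, replace=False))

    terms = []
    for j in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        n_core = int(np.floor(within_block_overlap * size + 0.5))
        core_idx = cores[block_of[j]][:n_core]
        remaining = np.setdiff1d(np.arange(n_genes), core_idx, assume_unique=False)
        if size - n_core > remaining.size:
            raise ValueError("gene pool too small for requested sizes")
        extra = rng.choice(remaining, size=size - n_core, replace=False)
        genes = frozenset(pool[np.concatenate([core_idx, extra]).astype(int)])
        terms.append(GeneSet(term_id=f"T{j + 1:04d}", description=f"block{block_of[j]}",
                             genes=genes))
    return GeneSetDatabase(terms=tuple(terms))


def sample_active_terms(S: SimilarityMatrix, n_active: int, rho: float,
                        seed: int = 0) -> list[int]:
    """Sample ``n_active`` distinct term indices with similarity-biased chaining.

    The first term is uniform over all K terms.  Each subsequent term is drawn
    from the mixture (1 - rho) * U + rho * S_j over the not-yet-sampled terms,
    where S_j is the similarity column of the previously sampled term j and U
    is uniform.  If the mixture has zero mass (rho = 1 and all remaining
    similarities zero), the draw falls back to uniform and a warning is logged.
    """
    k = S.n_terms
    if not (1 <= n_active <= k):
        raise ValueError(f"n_active must lie in [1, {k}]")
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chosen: list[int] = [int(rng.integers(k))]
    while len(chosen) < n_active:
        j = chosen[-1]
        remaining = np.setdiff1d(np.arange(k), chosen, assume_unique=True)
        w = (1.0 - rho) / remaining.size + rho * S.values[remaining, j]
        total = w.sum()
        if total <= 0:
            logger.warning(
                "similarity sampling stuck (rho=%g, all remaining similarities 0); "
                "falling back to uniform", rho)
            w = np.full(remaining.size, 1.0 / remaining.size)
            total = 1.0
        chosen.append(int(rng.choice(remaining, p=w / total)))
    return chosen


def apply_membership_noise(X: MembershipMatrix, active: list[int], eta: float,
                           seed: int = 0) -> MembershipMatrix:
    """Zero a fraction eta of the 1-entries in the columns of activated terms.

    The count is round-half-up of eta times the number of such entries; the
    entries are chosen uniformly without replacement.  All other entries are
    untouched.
    """
    if not (0.0 <= eta <= 1.0):
        raise ValueError("eta must lie in [0, 1]")
    values = X.values.copy()
    active = sorted(int(a) for a in active)
    rows, cols = np.nonzero(values[:, active])
    m = rows.size
    n_flip = int(np.floor(eta * m + 0.5))
    if n_flip > 0:
        rng = np.random.default_rng(seed)
        pick = rng.choice(m, size=n_flip, replace=False)
        values[rows[pick], np.asarray(active)[cols[pick]]] = 0.0
    return MembershipMatrix(values=values, gene_ids=X.gene_ids, term_ids=X.term_ids)


def simulate_pvalues(X_noisy: MembershipMatrix, beta_active, phi: float,
                     seed: int = 0) -> ResponseVector:
    """Draw per-gene P-values from Beta(mu_i*phi, (1-mu_i)*phi), mu = logistic(X beta)."""
    beta_active = np.asarray(beta_active, dtype=float)
    if beta_active.shape != (X_noisy.n_terms,):
        raise ValueError("activation vector length must equal the number of terms")
    if phi <= 0:
        raise ValueError("phi must be positive")
    rng = np.random.default_rng(seed)
    mu = expit(X_noisy.values @ beta_active)
    p = rng.beta(mu * phi, (1.0 - mu) * phi)
    # guard against floating-point boundary draws
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - 1e-16)
    return ResponseVector(values=p, gene_ids=X_noisy.gene_ids)


def generate_dataset(db: GeneSetDatabase, S: SimilarityMatrix,
                     config: SyntheticConfig, replicate_id: int = 0) -> SyntheticDataset:
    """Compose sampling, activation, noise and beta draws into one seeded dataset.

    The gene universe is the sorted union of all term genes in ``db``.
    """
    if tuple(S.term_ids) != tuple(db.term_ids):
        raise ValueError("similarity matrix labels do not match the database")
    if config.n_active > db.n_terms:
        raise ValueError("n_active exceeds the number of terms")
    seeds = _child_seeds(config.seed, 3)
    universe = db.gene_universe()
    X = membership_matrix(db, universe)

    active_idx = sample_active_terms(S, config.n_active, config.rho, seed=seeds[0])
    beta_a = np.zeros(db.n_terms)
    beta_a[active_idx] = config.activation_value

    X_noisy = apply_membership_noise(X, active_idx, config.eta, seed=seeds[1])
    mu = expit(X_noisy.values @ beta_a)
    response = simulate_pvalues(X_noisy, beta_a, config.phi, seed=seeds[2])

    truth = SyntheticTruth(
        active_terms=frozenset(db.term_ids[i] for i in active_idx),
        beta_active=beta_a,
        X_noisy=X_noisy,
        mu=mu,
    )
    return SyntheticDataset(truth=truth, response=response, config=config,
                            replicate_id=replicate_id)
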