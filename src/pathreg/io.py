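"""Plain-text input/output: gene P-value tables, fit results, dataset dumps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import MembershipMatrix
from .model import EnrichmentFit, ResponseVector, clamp_pvalues
from .synthetic import SyntheticDataset

__all__ = [
    "read_pvalue_table",
    "write_pvalue_table",
    "write_fit",
    "write_dataset",
]


def read_pvalue_table(path, epsilon: float = 1e-6) -> ResponseVector:
    """Read a two-column TSV (gene, pvalue) with header; clamp into (0, 1)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, pvalue)")
    genes = df.iloc[:, 0].astype(str)
    if genes.duplicated().any():
        dupes = sorted(genes[genes.duplicated()].unique()[:5])
        raise ValueError(f"{path}: duplicate gene identifiers {dupes}")
    return clamp_pvalues(df.iloc[:, 1].to_numpy(float), tuple(genes), epsilon=epsilon)


def write_pvalue_table(y: ResponseVector, path) -> None:
    pd.DataFrame({"gene": list(y.gene_ids), "pvalue": y.values}).to_csv(
        path, sep="\t", index=False)


def write_fit(fit: EnrichmentFit, out_dir, prefix: str = "enrichment") -> None:
    """Write a fit as a ranked TSV plus a JSON sidecar with fit metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = np.argsort(-np.abs(fit.beta), kind="stable")
    df = pd.DataFrame({
        "term_id": [fit.term_ids[i] for i in order],
        "beta": fit.beta[order],
        "abs_beta": np.abs(fit.beta[order]),
    })
    df["rank"] = np.arange(1, len(df) + 1)
    df.to_csv(out_dir / f"{prefix}.tsv", sep="\t", index=False)
    meta = {
        "phi": fit.phi,
        "intercept": fit.intercept,
        "lambda": fit.config.lambda_,
        "psi": fit.config.psi,
        "converged": fit.converged,
        "n_epochs": int(len(fit.objective_trace) - 1),
        "final_objective": float(fit.objective_trace[-1]),
        "seed": fit.config.seed,
    }
    with open(out_dir / f"{prefix}.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write a synthetic dataset: P-value TSV, truth term list, JSON config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pvalue_table(dataset.response, out_dir / "pvalues.tsv")
    with open(out_dir / "active_terms.txt", "w", encoding="utf-8") as fh:
        for t in sorted(dataset.truth.active_terms):
            fh.write(t + "\n")
    cfg = dataset.config
    echo = {"n_active": cfg.n_active, "rho": cfg.rho, "eta": cfg.eta, "phi": cfg.phi,
            "activation_value": cfg.activation_value, "seed": cfg.seed,
            "replicate_id": dataset.replicate_id}
    with open(out_dir / "config.json", "w", encoding="utf-8") as fh:
        json.dump(echo, fh, indent=2)
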