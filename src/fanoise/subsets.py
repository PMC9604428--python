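"""Subset-based estimation of genome-wide intrinsic noise and trend tests.

If a single global drive buffers the whole transcriptional landscape, the
pooled intrinsic noise of an individual estimated from a *small random
subset* of genes should track the estimate from all genes.  This module
draws random gene subsets, computes the per-sample intrinsic noise on each,
and summarizes how well subset estimates correlate with the full-panel
estimate across samples — the practical question being how few qPCR genes
suffice to diagnose an individual's transcriptome-wide instability.

It also provides a rank-based trend test (Spearman rho with a seeded
permutation p-value) for intrinsic noise against a positional coordinate,
e.g. a distal-proximal slice index along an embryo axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import BilateralMatrix, individual_intrinsic_noise

__all__ = [
    "SubsetCorrelationResult",
    "sample_gene_subsets",
    "per_sample_intrinsic_noise",
    "subset_correlation_curve",
    "positional_trend",
]


@dataclass
class SubsetCorrelationResult:
    """Correlation of subset-based vs full-panel intrinsic noise per size."""

    subset_sizes: list
    n_subsets: int
    correlations: np.ndarray  # (n_sizes x n_subsets)
    medians: np.ndarray  # per size
    eta_all: np.ndarray  # per-sample full-panel eta_int
    seed: int
    method: str = "pearson"

    def to_dict(self) -> dict:
        return {
            "subset_sizes": list(map(int, self.subset_sizes)),
            "n_subsets": int(self.n_subsets),
            "medians": list(map(float, self.medians)),
            "seed": int(self.seed),
            "method": self.method,
        }


def sample_gene_subsets(
    gene_ids: Sequence,
    size: int,
    n_subsets: int,
    seed: int | np.random.Generator,
) -> list[list]:
    """Draw ``n_subsets`` random gene subsets of ``size`` without replacement.

    Draws are without replacement within a subset and independent between
    subsets; the same seed reproduces the same subsets exactly.
    """
    gene_ids = list(gene_ids)
    if size > len(gene_ids):
        raise ValueError(f"subset size {size} exceeds gene count {len(gene_ids)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [
        [gene_ids[i] for i in rng.choice(len(gene_ids), size=size, replace=False)]
        for _ in range(n_subsets)
    ]


def per_sample_intrinsic_noise(
    M: BilateralMatrix, gene_indices: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-individual pooled intrinsic noise, optionally on a gene subset."""
    if gene_indices is not None:
        sub = BilateralMatrix(
            gene_ids=[M.gene_ids[int(i)] for i in gene_indices],
            left=M.left[gene_indices],
            right=M.right[gene_indices],
            log_base=M.log_base,
            individual_ids=list(M.individual_ids),
        )
    else:
        sub = M
    return np.array(
        [individual_intrinsic_noise(sub, j) for j in range(sub.n_individuals)]
    )


def subset_correlation_curve(
    M: BilateralMatrix,
    sizes: Sequence[int] = (5, 10, 25, 50, 75, 100, 500, 1000),
    n_subsets: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> SubsetCorrelationResult:
    """Correlate subset-based with full-panel per-sample intrinsic noise.

    For every sample the pooled intrinsic noise eta_int is computed from
    all genes and from ``n_subsets`` random subsets of each size; the
    across-sample correlation between the full-panel and each subset
    estimate is recorded, with the per-size median as summary.

    ``method`` is ``"pearson"`` (default; correlations on the eta scale) or
    ``"spearman"``.
    """
    sizes = [s for s in sizes if s <= M.n_genes]
    if not sizes:
        raise ValueError("no subset size is <= the number of genes")
    if M.n_individuals < 5:
        raise ValueError("need at least 5 paired samples")
    eta_all = per_sample_intrinsic_noise(M)
    if np.all(eta_all == 0):
        raise ValueError("per-sample intrinsic noise is degenerate (all zero)")
    rng = np.random.default_rng(seed)
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    cors = np.empty((len(sizes), n_subsets))
    for si, size in enumerate(sizes):
        for b in range(n_subsets):
            idx = rng.choice(M.n_genes, size=size, replace=False)
            eta_sub = per_sample_intrinsic_noise(M, idx)
            cors[si, b] = corr_fn(eta_all, eta_sub)[0]
    return SubsetCorrelationResult(
        subset_sizes=list(sizes),
        n_subsets=n_subsets,
        correlations=cors,
        medians=np.median(cors, axis=1),
        eta_all=eta_all,
        seed=seed if isinstance(seed, int) else -1,
        method=method,
    )


def positional_trend(
    eta_int: Sequence[float],
    position: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman trend of intrinsic noise along a positional axis.

    Returns the Spearman rank correlation and its two-sided permutation
    p-value (``n_permutations`` seeded shuffles of the noise values against
    the fixed positions).  Rank-based, so any smoothing drawn over the same
    data is display-only and carries no inference.
    """
    eta = np.asarray(eta_int, dtype=float)
    pos = np.asarray(position, dtype=float)
    if eta.shape != pos.shape or eta.ndim != 1:
        raise ValueError("eta_int and position must be aligned 1-D vectors")
    if eta.size < 5:
        raise ValueError("need at least 5 positioned samples")
    if np.all(pos == pos[0]):
        raise ValueError("all positions identical: trend undefined")

    rho = float(stats.spearmanr(eta, pos)[0])
    # permutation null: correlate permuted noise ranks against position ranks
    rng = np.random.default_rng(seed)
    r_eta = stats.rankdata(eta)
    r_pos = stats.rankdata(pos)
    r_pos = (r_pos - r_pos.mean()) / r_pos.std()
    r_eta = (r_eta - r_eta.mean()) / r_eta.std()
    n = eta.size
    perms = np.array([r_eta[rng.permutation(n)] for _ in range(n_permutations)])
    null = perms @ r_pos / n
    p = float((np.sum(np.abs(null) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1))
    return rho, p
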