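"""Variance/noise partition of bilateral (left/right) measurements.

A bilaterally symmetric trait measured on the left (``l``) and right (``r``)
of the same individual carries two kinds of fluctuation.  Working with
log-transformed values ``u = log(l)`` and ``v = log(r)``, the variance of the
log expression partitions by the law of total variance into

* an **extrinsic** (canalization) component, the between-individual part,
  estimated by ``Var(u + v)`` — both sides move together when the shared
  upstream drive fluctuates; and
* an **intrinsic** (fluctuating-asymmetry, FA) component, the
  within-individual part, estimated by ``Var(u - v)`` — the two sides
  decouple only through side-local stochasticity.

For a gene with total noise eta^2 (squared coefficient of variation of the
raw expression) and left/right correlation rho these components equal
``2 eta^2 (1 + rho)`` and ``2 eta^2 (1 - rho)`` respectively.

Directional *additive* asymmetry (a constant offset between sides) and
per-side normalization constants drop out of both variances.  Directional
*multiplicative* asymmetry (``v ~ a u``) does not; it is cancelled by
rotating the paired data onto the principal axes of the 2x2 left/right
covariance.  The eigenvalue whose eigenvector lies along the (1, 1)
diagonal estimates half the extrinsic component; the orthogonal one
estimates half the intrinsic component (FA = 2 * lambda_int).

Pooling many genes requires removing each gene's own mean first
(:func:`center_genewise`); the intrinsic eigenvalue is insensitive to that
centering because per-gene means cancel in the left-minus-right direction,
which is what makes a per-individual intrinsic-noise estimate from the raw
(non-centered) gene x 2 matrix possible (:func:`individual_intrinsic_noise`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "BilateralMatrix",
    "NoiseComponents",
    "EigenResult",
    "FilterReport",
    "DegenerateSampleWarning",
    "UnequalSideVarianceWarning",
    "LOG2_TO_NATURAL_VARIANCE",
    "per_gene_noise_components",
    "eigen2x2",
    "center_genewise",
    "pooled_noise",
    "individual_intrinsic_noise",
    "pairwise_reference_free_intrinsic_noise",
    "log_transform_counts",
    "convert_variance_scale",
]

#: Multiply a log2-scale variance (e.g. from dCt values) by this factor to
#: express it on the natural-log scale: 1 / ln(2)^2.
LOG2_TO_NATURAL_VARIANCE = 1.0 / np.log(2.0) ** 2

LogBase = Literal["natural", "2"]

_DIAG = np.array([1.0, 1.0]) / np.sqrt(2.0)  # the left==right direction


class DegenerateSampleWarning(UserWarning):
    """Sample too small or too flat for a stable variance estimate."""


class UnequalSideVarianceWarning(UserWarning):
    """Side variances differ enough to strain the equal-variance assumption."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BilateralMatrix:
    """Paired left/right log-scale expression with per-individual metadata.

    ``left`` and ``right`` are (n_genes x n_individuals) arrays of
    log-transformed expression (natural log for FPKM-style input, log2 for
    dCt values).  Optional per-individual annotations carry the grouping
    factor, sex, a positional coordinate (e.g. an anterior-posterior slice
    index) and per-side normalization constants.
    """

    gene_ids: list
    left: np.ndarray
    right: np.ndarray
    log_base: LogBase = "natural"
    individual_ids: Optional[list] = None
    group_labels: Optional[np.ndarray] = None
    sex_labels: Optional[np.ndarray] = None
    position: Optional[np.ndarray] = None
    size_factors: Optional[np.ndarray] = None
    gene_means: Optional[np.ndarray] = None  # set by center_genewise

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.ndim == 1:
            self.left = self.left[:, None]
            self.right = self.right[:, None]
        if self.left.shape != self.right.shape:
            raise ValueError(
                f"left {self.left.shape} and right {self.right.shape} differ in shape"
            )
        if len(self.gene_ids) != self.left.shape[0]:
            raise ValueError("gene_ids length does not match matrix rows")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("bilateral matrices must be finite")
        if self.log_base not in ("natural", "2"):
            raise ValueError(f"unknown log_base {self.log_base!r}")
        if self.individual_ids is None:
            self.individual_ids = [f"ind{j}" for j in range(self.left.shape[1])]
        if len(self.individual_ids) != self.left.shape[1]:
            raise ValueError("individual_ids length does not match matrix columns")
        for name in ("group_labels", "sex_labels", "position"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape[0] != self.n_individuals:
                    raise ValueError(f"{name} length does not match individual count")
                setattr(self, name, val)

    @property
    def n_genes(self) -> int:
        return self.left.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.left.shape[1]

    def individual_matrix(self, individual) -> np.ndarray:
        """Return the (n_genes x 2) left/right matrix of one individual."""
        j = self._individual_index(individual)
        return np.column_stack([self.left[:, j], self.right[:, j]])

    def _individual_index(self, individual) -> int:
        if isinstance(individual, (int, np.integer)):
            return int(individual)
        return self.individual_ids.index(individual)

    def select_individuals(self, mask_or_indices) -> "BilateralMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return BilateralMatrix(
            gene_ids=list(self.gene_ids),
            left=self.left[:, idx],
            right=self.right[:, idx],
            log_base=self.log_base,
            individual_ids=[self.individual_ids[int(j)] for j in idx],
            group_labels=None if self.group_labels is None else self.group_labels[idx],
            sex_labels=None if self.sex_labels is None else self.sex_labels[idx],
            position=None if self.position is None else self.position[idx],
            size_factors=None if self.size_factors is None else np.asarray(self.size_factors)[..., idx],
        )

    def stacked(self) -> np.ndarray:
        """Stack (gene, individual) pairs into an (n_genes*n_individuals x 2) array."""
        return np.column_stack([self.left.ravel(), self.right.ravel()])


@dataclass
class NoiseComponents:
    """Extrinsic/intrinsic noise estimates and their building blocks.

    ``eta2_ext`` estimates 2 eta^2 (1 + rho) and ``eta2_int`` (= FA)
    2 eta^2 (1 - rho); ``sigma2_w`` is the mean per-side log variance
    (~ eta^2) and satisfies (eta2_ext + eta2_int) / 4 == sigma2_w exactly
    when all are computed from the same sample variances.
    """

    eta2_ext: float
    eta2_int: float
    sigma2_w: float
    rho: float  # NaN when undefined (a side with zero variance)
    n_pairs: int
    scale: LogBase = "natural"

    @property
    def eta_ext(self) -> float:
        return float(np.sqrt(self.eta2_ext))

    @property
    def eta_int(self) -> float:
        return float(np.sqrt(self.eta2_int))


@dataclass
class EigenResult:
    """2x2 eigen-decomposition of a paired left/right matrix.

    Components are assigned by eigenvector orientation: the eigenvector
    within 45 degrees of the (1, 1) diagonal is *extrinsic*, its orthogonal
    partner *intrinsic* — regardless of eigenvalue magnitude.  When the
    intrinsic eigenvalue exceeds the extrinsic one (FA dominating
    canalization) ``assignment_conflict`` is set instead of silently
    swapping.  With ``centered=False`` (no gene-wise centering applied to
    the input) only ``lambda_int`` is meaningful: per-gene mean variation
    inflates the diagonal eigenvalue, so ``lambda_ext_valid`` is False.
    """

    lambda_ext: float
    lambda_int: float
    evec_ext: np.ndarray
    evec_int: np.ndarray
    scores_pc1: np.ndarray  # projection on evec_ext
    scores_pc2: np.ndarray  # projection on evec_int
    centered: bool
    assignment_conflict: bool = False
    lambda_ext_valid: bool = True

    @property
    def eta_int(self) -> float:
        return float(np.sqrt(2.0 * self.lambda_int))

    @property
    def eta_ext(self) -> float:
        return float(np.sqrt(2.0 * self.lambda_ext))

    def to_dict(self) -> dict:
        return {
            "lambda_ext": self.lambda_ext,
            "lambda_int": self.lambda_int,
            "evec_ext": list(map(float, self.evec_ext)),
            "evec_int": list(map(float, self.evec_int)),
            "centered": self.centered,
            "assignment_conflict": self.assignment_conflict,
            "lambda_ext_valid": self.lambda_ext_valid,
        }


@dataclass
class FilterReport:
    """Bookkeeping for the non-zero expression filter."""

    n_input_genes: int
    n_kept_genes: int

    @property
    def n_dropped(self) -> int:
        return self.n_input_genes - self.n_kept_genes


# ---------------------------------------------------------------------------
# per-gene partition
# ---------------------------------------------------------------------------


def per_gene_noise_components(
    u: Sequence[float],
    v: Sequence[float],
    scale: LogBase = "natural",
) -> NoiseComponents:
    """Partition one gene's bilateral log expression into noise components.

    Parameters
    ----------
    u, v
        Log expression on the left and right sides across individuals.
    scale
        Log base tag propagated to the result.

    Returns
    -------
    NoiseComponents
        eta2_ext = Var(u+v), eta2_int = Var(u-v) (FA), sigma2_w the mean
        per-side variance, rho the left/right Pearson correlation (NaN when
        a side has zero variance).  Unbiased (n-1) variances throughout.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"u {u.shape} and v {v.shape} must be 1-D of equal length")
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("inputs must be finite")
    n = u.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if n == 2:
        warnings.warn(
            "variance estimates from 2 individuals are degenerate",
            DegenerateSampleWarning,
            stacklevel=2,
        )
    var_u = float(np.var(u, ddof=1))
    var_v = float(np.var(v, ddof=1))
    eta2_ext = float(np.var(u + v, ddof=1))
    eta2_int = float(np.var(u - v, ddof=1))
    if var_u > 0.0 and var_v > 0.0:
        rho = float(np.corrcoef(u, v)[0, 1])
    else:
        warnings.warn(
            "zero variance on a side: left/right correlation undefined",
            DegenerateSampleWarning,
            stacklevel=2,
        )
        rho = float("nan")
    return NoiseComponents(
        eta2_ext=eta2_ext,
        eta2_int=eta2_int,
        sigma2_w=0.5 * (var_u + var_v),
        rho=rho,
        n_pairs=n,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# 2x2 eigen machinery
# ---------------------------------------------------------------------------


def _check_equal_side_variance(var_u: float, var_v: float) -> None:
    if var_u > 0 and var_v > 0:
        ratio = var_u / var_v
        if not (2.0 / 3.0 <= ratio <= 1.5):
            warnings.warn(
                f"side variance ratio {ratio:.3g} outside [2/3, 3/2]; the "
                "equal-side-variance assumption behind the eigenvalue-to-noise "
                "mapping is strained",
                UnequalSideVarianceWarning,
                stacklevel=3,
            )


def eigen2x2(matrix: np.ndarray, centered: bool = True) -> EigenResult:
    """Eigen-decompose the 2x2 covariance of an (n x 2) left/right matrix.

    The sample covariance removes column means (as R's ``cov`` does), which
    is what makes additive directional asymmetry and per-side size factors
    drop out.  Rows are projected (about the column means) onto the
    eigenvectors, so the variance of each score vector equals its
    eigenvalue with the same (n-1) divisor.

    ``centered`` declares whether gene-wise centering was applied upstream;
    if not, only the intrinsic eigenvalue is meaningful and
    ``lambda_ext_valid`` is False.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"expected an (n x 2) matrix, got {X.shape}")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for a 2x2 covariance")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix must be finite")

    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc) / (n - 1)
    if np.allclose(C, 0.0):
        warnings.warn("rank-0 input: all rows identical", DegenerateSampleWarning, stacklevel=2)
    if centered:
        # the diagnostic only makes sense once per-gene means are removed;
        # on raw matrices both side variances are dominated by gene means
        _check_equal_side_variance(C[0, 0], C[1, 1])

    evals, evecs = np.linalg.eigh(C)  # ascending eigenvalues
    evals = np.clip(evals, 0.0, None)  # clip tiny negative round-off
    # orientation-based assignment: the eigenvector closer to (1,1)/sqrt(2)
    # is extrinsic; orthogonality guarantees exactly one qualifies (ties at
    # 45 degrees resolved toward the larger eigenvalue).
    align = np.abs(evecs.T @ _DIAG)
    if np.isclose(align[0], align[1]):
        ext_pos = 1  # larger eigenvalue (eigh sorts ascending)
    else:
        ext_pos = int(np.argmax(align))
    int_pos = 1 - ext_pos

    evec_ext = evecs[:, ext_pos].copy()
    evec_int = evecs[:, int_pos].copy()
    # deterministic signs: extrinsic along +(1,1), intrinsic along +(1,-1)
    if evec_ext.sum() < 0:
        evec_ext = -evec_ext
    if evec_int[0] - evec_int[1] < 0:
        evec_int = -evec_int

    lambda_ext = float(evals[ext_pos])
    lambda_int = float(evals[int_pos])
    return EigenResult(
        lambda_ext=lambda_ext,
        lambda_int=lambda_int,
        evec_ext=evec_ext,
        evec_int=evec_int,
        scores_pc1=Xc @ evec_ext,
        scores_pc2=Xc @ evec_int,
        centered=centered,
        assignment_conflict=lambda_int > lambda_ext,
        lambda_ext_valid=centered,
    )


# ---------------------------------------------------------------------------
# pooled / multi-gene estimation
# ---------------------------------------------------------------------------


def center_genewise(M: BilateralMatrix) -> BilateralMatrix:
    """Subtract each gene's mean over all its left and right entries.

    Removes the conditioning on per-gene expression level so that genes can
    be stacked into one pooled analysis; the per-gene means are retained in
    ``gene_means``.  Left-minus-right differences are unchanged (the mean
    cancels), which is why intrinsic-noise estimates tolerate skipping this
    step.
    """
    mu = (M.left.sum(axis=1) + M.right.sum(axis=1)) / (2.0 * M.n_individuals)
    out = replace(
        M,
        left=M.left - mu[:, None],
        right=M.right - mu[:, None],
        gene_means=mu,
    )
    return out


def pooled_noise(
    M: BilateralMatrix,
    stratum=None,
) -> tuple[NoiseComponents, EigenResult]:
    """Pooled extrinsic/intrinsic noise over many genes within one stratum.

    All (gene, individual) pairs in the stratum are stacked into an
    (n_genes * n_individuals x 2) matrix, gene-wise centered within the
    stratum, and eigen-decomposed.  eta_ext = sqrt(2 lambda_ext) and
    eta_int = sqrt(2 lambda_int); PC scores are retained for downstream
    distributional modeling of the eigenvalues.

    Parameters
    ----------
    M
        The bilateral matrix.
    stratum
        None (use everything), a group label (selects individuals whose
        ``group_labels`` entry equals it), or an explicit index/boolean
        array over individuals.
    """
    if stratum is not None:
        if M.group_labels is not None and np.isscalar(stratum) and stratum in set(
            np.asarray(M.group_labels).tolist()
        ):
            sub = M.select_individuals(np.asarray(M.group_labels) == stratum)
        else:
            sub = M.select_individuals(stratum)
    else:
        sub = M
    if sub.n_genes * sub.n_individuals < 3:
        raise ValueError("need at least 3 (gene, individual) pairs in the stratum")
    centered = center_genewise(sub)
    eig = eigen2x2(centered.stacked(), centered=True)
    W = centered.stacked()
    var_u = float(np.var(W[:, 0], ddof=1))
    var_v = float(np.var(W[:, 1], ddof=1))
    if var_u > 0 and var_v > 0:
        rho = float(np.corrcoef(W[:, 0], W[:, 1])[0, 1])
    else:
        rho = float("nan")
    comps = NoiseComponents(
        eta2_ext=2.0 * eig.lambda_ext,
        eta2_int=2.0 * eig.lambda_int,
        sigma2_w=0.5 * (var_u + var_v),
        rho=rho,
        n_pairs=W.shape[0],
        scale=M.log_base,
    )
    return comps, eig


def individual_intrinsic_noise(M: BilateralMatrix, individual) -> float:
    """Pooled intrinsic noise (eta_int) of one individual.

    Uses the individual's raw (non-centered) gene x 2 left/right matrix:
    per-gene means cancel in the intrinsic direction, so no gene-wise
    centering is needed, and eta_int = sqrt(2 * lambda_int).
    """
    X = M.individual_matrix(individual)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 genes measured on both sides")
    eig = eigen2x2(X, centered=False)
    return eig.eta_int


def pairwise_reference_free_intrinsic_noise(
    ct_left: Sequence[float], ct_right: Sequence[float]
) -> float:
    """Individual intrinsic noise from all pairwise gene dCts.

    Normalizing qPCR Ct values to a single reference gene injects that
    gene's own fluctuation into every dCt.  Taking Ct differences between
    all unordered gene pairs on each side instead removes the dependence on
    any one reference; the k(k-1)/2 x 2 pairwise-dCt matrix is
    eigen-decomposed exactly like an individual's expression matrix.
    """
    a = np.asarray(ct_left, dtype=float).ravel()
    b = np.asarray(ct_right, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("left and right Ct vectors differ in length")
    k = a.size
    if k < 3:
        raise ValueError("need at least 3 genes for pairwise dCts")
    pairs = np.array(list(itertools.combinations(range(k), 2)))
    d = np.column_stack([a[pairs[:, 0]] - a[pairs[:, 1]], b[pairs[:, 0]] - b[pairs[:, 1]]])
    eig = eigen2x2(d, centered=False)
    return eig.eta_int


# ---------------------------------------------------------------------------
# input transformation
# ---------------------------------------------------------------------------


def log_transform_counts(
    left_raw: np.ndarray,
    right_raw: np.ndarray,
    gene_ids: Sequence,
    mode: Literal["fpkm-natural-log", "ct-passthrough"] = "fpkm-natural-log",
    individual_ids: Optional[list] = None,
    **metadata,
) -> tuple[BilateralMatrix, FilterReport]:
    """Build a :class:`BilateralMatrix` from raw paired expression values.

    ``fpkm-natural-log``: genes with any zero across samples (either side)
    are dropped — log of zero is undefined and such genes cannot contribute
    a finite fluctuation — and the survivors are natural-log transformed.
    ``ct-passthrough``: dCt values are already log2-scale relative
    expression and pass through unchanged with ``log_base="2"``.
    """
    L = np.asarray(left_raw, dtype=float)
    R = np.asarray(right_raw, dtype=float)
    if L.shape != R.shape:
        raise ValueError("left and right raw matrices differ in shape")
    if L.ndim == 1:
        L, R = L[:, None], R[:, None]
    gene_ids = list(gene_ids)
    if mode == "ct-passthrough":
        mat = BilateralMatrix(
            gene_ids=gene_ids, left=L, right=R, log_base="2",
            individual_ids=individual_ids, **metadata,
        )
        return mat, FilterReport(n_input_genes=len(gene_ids), n_kept_genes=len(gene_ids))
    if mode != "fpkm-natural-log":
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(L < 0) or np.any(R < 0):
        raise ValueError("raw expression values must be nonnegative")
    keep = np.all(L > 0, axis=1) & np.all(R > 0, axis=1)
    report = FilterReport(n_input_genes=len(gene_ids), n_kept_genes=int(keep.sum()))
    if report.n_kept_genes == 0:
        raise ValueError("all genes filtered out (every gene has a zero)")
    mat = BilateralMatrix(
        gene_ids=[g for g, k in zip(gene_ids, keep) if k],
        left=np.log(L[keep]),
        right=np.log(R[keep]),
        log_base="natural",
        individual_ids=individual_ids,
        **metadata,
    )
    return mat, report


def convert_variance_scale(value: float, from_base: LogBase, to_base: LogBase) -> float:
    """Convert a log-scale variance (or squared noise) between log bases."""
    if from_base == to_base:
        return value
    if from_base == "2" and to_base == "natural":
        return value * LOG2_TO_NATURAL_VARIANCE
    if from_base == "natural" and to_base == "2":
        return value / LOG2_TO_NATURAL_VARIANCE
    raise ValueError(f"cannot convert {from_base!r} -> {to_base!r}")
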