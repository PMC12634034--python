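"""Shared latent space for scRNA-seq and spatial data via kernel PCA alignment.

Each modality is projected with its own kernel PCA (RBF kernel by default;
with a linear kernel the stage reduces exactly to classical PCA).  Because
kernel components live in modality-specific sample spaces, each component is
given a gene-space surrogate direction (``pseudo_loadings``, the normalized
back-projection Xᵀα).  The two loading sets are then aligned principal-vector
style: an SVD of their cross-product yields paired directions whose singular
values are the cosine similarities between components; only pairs above a
similarity threshold (default 0.3) are retained, and both datasets are
projected onto the reference-side aligned basis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg as sla
from sklearn.metrics.pairwise import euclidean_distances

from .data_model import (
    OmicsDataset,
    ValidationError,
    _dense,
    intersect_genes,
    normalize_expression,
)

logger = logging.getLogger("ksrv")

DEFAULT_THRESHOLD = 0.3
DEFAULT_N_COMPONENTS = 50
EIGVAL_REL_TOL = 1e-9  # eigenvalues below max * this are numerically zero


class AlignmentError(ValueError):
    """Raised when no component pair passes the similarity threshold."""


@dataclass
class KernelPCAModel:
    """Kernel PCA fit of one modality.

    ``dual_coefficients`` are the unit-norm eigenvectors of the double-centered
    kernel; scores are ``dual * sqrt(eigenvalue)``.  ``pseudo_loadings`` are
    unit-norm gene-space surrogate directions (columns of normalized Xᵀα),
    sign-fixed so each column's largest-magnitude entry is positive.
    """

    training_matrix: np.ndarray
    gamma: float
    eigenvalues: np.ndarray
    dual_coefficients: np.ndarray
    pseudo_loadings: np.ndarray
    kernel: str = "rbf"

    @property
    def n_components(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def scores(self) -> np.ndarray:
        return self.dual_coefficients * np.sqrt(self.eigenvalues)


@dataclass
class AlignedEmbedding:
    """Matched low-dimensional representations of both modalities."""

    ref_scores: np.ndarray
    spatial_scores: np.ndarray
    component_similarities: np.ndarray
    threshold: float
    basis_ref: np.ndarray
    basis_spatial: np.ndarray
    genes: Optional[list[str]] = None

    @property
    def n_components(self) -> int:
        return self.ref_scores.shape[1]


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel K[i, j] = exp(-gamma * ||A_i - B_j||^2)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValidationError("A and B must share the feature dimension")
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValidationError("non-finite values in kernel input")
    sq = euclidean_distances(A, B, squared=True)
    np.maximum(sq, 0.0, out=sq)
    K = np.exp(-gamma * sq)
    if A is B or (A.shape == B.shape and np.array_equal(A, B)):
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
    return K


def _sign_fix(columns: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    if columns.size == 0:
        return columns
    idx = np.argmax(np.abs(columns), axis=0)
    signs = np.sign(columns[idx, np.arange(columns.shape[1])])
    signs[signs == 0] = 1.0
    return columns * signs


def fit_kernel_pca(
    X,
    n_components: int,
    gamma: Optional[float] = None,
    kernel: str = "rbf",
) -> KernelPCAModel:
    """Fit kernel PCA on one expression matrix.

    The kernel is double-centered (row, column and grand mean) before the
    eigendecomposition.  ``gamma`` defaults to 1/n_genes, the conventional
    RBF width.  Components with eigenvalue below ``max_eig * 1e-9`` are
    dropped as numerically zero; requesting more than the available rank
    truncates with a warning.
    """
    X = _dense(X).astype(float)
    n_obs, n_genes = X.shape
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components > n_obs - 1:
        raise ValidationError(
            f"n_components={n_components} exceeds n_obs-1={n_obs - 1}"
        )
    if np.allclose(X.var(axis=0), 0):
        raise ValidationError("zero-variance input: all observations identical")
    if gamma is None:
        gamma = 1.0 / n_genes
    if kernel == "rbf":
        K = rbf_kernel(X, X, gamma)
    elif kernel == "linear":
        K = X @ X.T
    else:
        raise ValidationError(f"unsupported kernel {kernel!r}")

    # double-centering: K_c = (I - 1/n) K (I - 1/n)
    row_mean = K.mean(axis=0)
    Kc = K - row_mean[None, :] - K.mean(axis=1)[:, None] + row_mean.mean()
    Kc = 0.5 * (Kc + Kc.T)

    evals, evecs = sla.eigh(Kc)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    keep = evals > max(evals[0], 0) * EIGVAL_REL_TOL if evals.size else []
    rank = int(np.sum(keep))
    if rank == 0:
        raise ValidationError("centered kernel has zero rank (identical rows?)")
    if n_components > rank:
        warnings.warn(
            f"n_components truncated from {n_components} to numerical rank {rank}",
            stacklevel=2,
        )
        n_components = rank
    evals = evals[:n_components]
    alphas = evecs[:, :n_components]

    loadings = X.T @ alphas
    norms = np.linalg.norm(loadings, axis=0)
    norms[norms == 0] = 1.0
    loadings = loadings / norms
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    alphas = alphas * signs  # keep dual vectors consistent with the sign fix
    return KernelPCAModel(
        training_matrix=X,
        gamma=float(gamma),
        eigenvalues=evals,
        dual_coefficients=alphas,
        pseudo_loadings=loadings,
        kernel=kernel,
    )


def align_components(
    ref_model: KernelPCAModel,
    spatial_model: KernelPCAModel,
    threshold: float = DEFAULT_THRESHOLD,
) -> AlignedEmbedding:
    """Principal-vector alignment of the two modalities' component loadings.

    With P, Q the gene-space pseudo-loadings, the SVD ``PᵀQ = UΣVᵀ`` gives
    aligned direction pairs ``P·U`` / ``Q·V`` with cosine similarity diag(Σ);
    pairs with similarity > ``threshold`` are retained and both (column-mean
    centered) training matrices are projected onto the reference-side basis.
    """
    P = ref_model.pseudo_loadings
    Q = spatial_model.pseudo_loadings
    if P.shape[0] != Q.shape[0]:
        raise ValidationError("models were not built on the same gene set")
    U, s, Vt = np.linalg.svd(P.T @ Q, full_matrices=False)
    if np.any(s > 1 + 1e-9):
        logger.debug("similarities above 1 clipped (max %.3g)", s.max())
    s = np.clip(s, 0.0, 1.0)
    retained = s > threshold
    if not np.any(retained):
        raise AlignmentError(
            f"no component pair exceeds similarity threshold {threshold}; "
            f"best similarity {s[0]:.4f}" if s.size else "empty similarity spectrum"
        )
    U = U[:, retained]
    V = Vt.T[:, retained]
    basis_ref = P @ U
    basis_spatial = Q @ V
    # deterministic sign: flip aligned pairs together
    idx = np.argmax(np.abs(basis_ref), axis=0)
    signs = np.sign(basis_ref[idx, np.arange(basis_ref.shape[1])])
    signs[signs == 0] = 1.0
    basis_ref = basis_ref * signs
    basis_spatial = basis_spatial * signs

    Xr = ref_model.training_matrix
    Xs = spatial_model.training_matrix
    ref_scores = (Xr - Xr.mean(axis=0)) @ basis_ref
    spatial_scores = (Xs - Xs.mean(axis=0)) @ basis_ref
    logger.info(
        "alignment retained %d/%d components (similarities %s)",
        int(retained.sum()),
        s.size,
        np.array2string(s[retained], precision=3),
    )
    return AlignedEmbedding(
        ref_scores=ref_scores,
        spatial_scores=spatial_scores,
        component_similarities=s[retained],
        threshold=float(threshold),
        basis_ref=basis_ref,
        basis_spatial=basis_spatial,
    )


def integrate(
    ref: OmicsDataset,
    spatial: OmicsDataset,
    n_components: Optional[int] = None,
    threshold: float = DEFAULT_THRESHOLD,
    gamma: Optional[float] = None,
    kernel: str = "rbf",
    target_sum: Optional[float] = None,
    log1p: bool = True,
) -> AlignedEmbedding:
    """Full integration stage: shared genes → normalize → KPCA → alignment.

    Each dataset is normalized separately (library size to its own median,
    then log1p) on the shared gene panel before its kernel PCA.
    """
    gi = intersect_genes(ref, spatial)
    if len(gi.genes) < 2:
        raise ValidationError("need at least 2 shared genes to integrate")
    if ref.n_obs < 3 or spatial.n_obs < 3:
        raise ValidationError("need at least 3 observations in each dataset")
    ref_n = normalize_expression(ref.subset_genes(gi.ref_index), target_sum, log1p)
    sp_n = normalize_expression(
        spatial.subset_genes(gi.spatial_index), target_sum, log1p
    )

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    nc_ref = min(n_components or DEFAULT_N_COMPONENTS, ref.n_obs - 1)
    nc_sp = min(n_components or DEFAULT_N_COMPONENTS, spatial.n_obs - 1)
    ref_model = _stage(
        "kpca/ref", fit_kernel_pca, ref_n.matrix, nc_ref, gamma, kernel
    )
    sp_model = _stage(
        "kpca/spatial", fit_kernel_pca, sp_n.matrix, nc_sp, gamma, kernel
    )
    aligned = _stage("align", align_components, ref_model, sp_model, threshold)
    aligned.genes = gi.genes
    return aligned
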