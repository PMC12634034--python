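"""kNN transfer of spliced/unspliced expression and cell-type labels.

Each spatial spot finds its k nearest reference cells by cosine distance in
the aligned latent space.  Neighbor j of spot i receives weight

    a_ij  = 1 - d(i,j) / sum_j' d(i,j')
    a*_ij = a_ij / (k - 1)

which is inversely proportional to the cosine distance and sums to one over
the neighborhood by construction.  Spliced/unspliced expression is then the
a*-weighted average of the neighbors' reference rows (over *all* reference
genes, enabling prediction of genes absent from the spatial panel), and the
label score of type C is the summed weight of neighbors labeled C.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import GeneIntersection, OmicsDataset, ValidationError

logger = logging.getLogger("ksrv")

DEFAULT_K = 50


@dataclass
class NeighborAssignment:
    """Per-spot neighbor indices into the reference, cosine distances, weights."""

    neighbor_indices: np.ndarray  # spots x k, int
    cosine_distances: np.ndarray  # spots x k, in [0, 2]
    weights: Optional[np.ndarray] = None  # spots x k, rows sum to 1

    @property
    def n_spots(self) -> int:
        return self.neighbor_indices.shape[0]

    @property
    def k(self) -> int:
        return self.neighbor_indices.shape[1]


@dataclass
class LabelTransferResult:
    """Per-spot type scores (summed neighbor weights) and argmax assignment."""

    scores: np.ndarray  # spots x n_types, rows sum to 1
    assigned: np.ndarray  # spot labels
    types: list[str]


def _row_normalize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(M, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return M / safe[:, None], zero


def find_neighbors(
    spatial_scores: np.ndarray,
    ref_scores: np.ndarray,
    k: int = DEFAULT_K,
) -> NeighborAssignment:
    """k nearest reference cells per spot by cosine distance d = 1 - cos.

    Ties are broken by ascending reference index.  Zero-norm score vectors
    are treated as orthogonal to everything (distance 1) with a warning.
    """
    spatial_scores = np.asarray(spatial_scores, dtype=float)
    ref_scores = np.asarray(ref_scores, dtype=float)
    n_refs = ref_scores.shape[0]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n_refs:
        warnings.warn(f"k={k} clamped to the {n_refs} reference cells", stacklevel=2)
        k = n_refs
    if spatial_scores.shape[1] != ref_scores.shape[1]:
        raise ValidationError("score matrices must share the component dimension")

    Sn, s_zero = _row_normalize(spatial_scores)
    Rn, r_zero = _row_normalize(ref_scores)
    if s_zero.any() or r_zero.any():
        warnings.warn(
            "zero-norm latent vectors present; their cosine distance is set to 1",
            stacklevel=2,
        )
    D = 1.0 - Sn @ Rn.T
    D[s_zero, :] = 1.0
    D[:, r_zero] = 1.0
    np.clip(D, 0.0, 2.0, out=D)

    # stable sort on (distance, ref index): lexsort's last key is primary
    ref_idx = np.broadcast_to(np.arange(n_refs), D.shape)
    order = np.lexsort((ref_idx, D), axis=1)[:, :k]
    dists = np.take_along_axis(D, order, axis=1)
    return NeighborAssignment(neighbor_indices=order, cosine_distances=dists)


def compute_weights(assignment: NeighborAssignment) -> NeighborAssignment:
    """Fill in the normalized inverse-distance weights a*_ij.

    ``a_ij = 1 - d_ij / Σ_j d_ij`` lies in [0, 1] for k >= 2 (a distance can
    never exceed the row total), and ``a*_ij = a_ij/(k-1)`` sums to one per
    spot as an algebraic identity.  A spot whose k distances are all zero
    takes uniform weights 1/k (the continuity limit).
    """
    d = np.asarray(assignment.cosine_distances, dtype=float)
    k = d.shape[1]
    if k == 1:  # single neighbor: the weight is trivially 1
        return NeighborAssignment(
            neighbor_indices=assignment.neighbor_indices,
            cosine_distances=d,
            weights=np.ones_like(d),
        )
    if k < 2:
        raise ValidationError("weighting requires k >= 1")
    if np.any(d < 0):
        raise ValidationError("negative cosine distances")
    row_sums = d.sum(axis=1)
    degenerate = row_sums == 0
    if degenerate.any():
        logger.info(
            "%d spot(s) with all-zero neighbor distances take uniform weights",
            int(degenerate.sum()),
        )
    safe = np.where(degenerate, 1.0, row_sums)
    a = 1.0 - d / safe[:, None]
    w = a / (k - 1)
    w[degenerate] = 1.0 / k
    assert np.all(w >= -1e-15), "weights must be non-negative for k >= 2"
    np.clip(w, 0.0, None, out=w)
    return NeighborAssignment(
        neighbor_indices=assignment.neighbor_indices,
        cosine_distances=d,
        weights=w,
    )


def _weight_matrix(assignment: NeighborAssignment, n_refs: int) -> sp.csr_matrix:
    if assignment.weights is None:
        raise ValidationError("weights not computed; call compute_weights first")
    n_spots, k = assignment.neighbor_indices.shape
    rows = np.repeat(np.arange(n_spots), k)
    return sp.csr_matrix(
        (assignment.weights.ravel(), (rows, assignment.neighbor_indices.ravel())),
        shape=(n_spots, n_refs),
    )


def impute_layers(
    weights: NeighborAssignment,
    ref: OmicsDataset,
    gene_subset: Optional[GeneIntersection] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-average spliced and unspliced predictions per spot.

    Predictions cover all reference genes by default (the shared panel only
    anchors the latent space); pass ``gene_subset`` to restrict columns to
    the shared panel.
    """
    for name in ("spliced", "unspliced"):
        if getattr(ref, name) is None:
            raise ValidationError(f"reference dataset lacks the {name!r} layer")
    W = _weight_matrix(weights, ref.n_obs)
    S, U = ref.spliced, ref.unspliced
    if gene_subset is not None:
        S = S[:, gene_subset.ref_index]
        U = U[:, gene_subset.ref_index]
    S_pred = np.asarray((W @ S).todense()) if sp.issparse(S) else W @ S
    U_pred = np.asarray((W @ U).todense()) if sp.issparse(U) else W @ U
    return np.asarray(S_pred), np.asarray(U_pred)


def transfer_labels(
    weights: NeighborAssignment, ref_labels: np.ndarray
) -> LabelTransferResult:
    """Score each cell type by summed neighbor weight; assign the argmax.

    Scores sum to one per spot (they partition the neighbor weights).  Exact
    score ties are resolved toward the lexicographically smallest type.
    """
    ref_labels = np.asarray(ref_labels, dtype=object)
    if weights.weights is None:
        raise ValidationError("weights not computed; call compute_weights first")
    if np.any(pd.isnull(ref_labels)):
        raise ValidationError("every neighbor must carry a label")
    types = sorted({str(t) for t in ref_labels})
    type_pos = {t: i for i, t in enumerate(types)}
    neighbor_types = np.vectorize(lambda j: type_pos[str(ref_labels[j])])(
        weights.neighbor_indices
    )
    n_spots, k = weights.neighbor_indices.shape
    scores = np.zeros((n_spots, len(types)))
    np.add.at(
        scores,
        (np.repeat(np.arange(n_spots), k), neighbor_types.ravel()),
        weights.weights.ravel(),
    )
    # argmax returns the first maximum; types are sorted, so ties go lexicographic
    assigned = np.array([types[i] for i in np.argmax(scores, axis=1)], dtype=object)
    return LabelTransferResult(scores=scores, assigned=assigned, types=types)
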