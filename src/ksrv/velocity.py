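"""Steady-state RNA velocity, transition graph, and 2-D projection.

Under the splicing kinetics du/dt = alpha - beta*u, ds/dt = beta*u - gamma*s,
cells at extreme spliced abundance are assumed to sit on the equilibrium line
u = gamma*s (beta scaled to 1).  gamma is fitted per gene by zero-intercept
regression of u on s over the extreme quantiles of s, and velocity is the
residual v = u - gamma*s: positive where a gene is being induced, negative
where it is shutting down.

The high-dimensional velocity field is summarized as a transition graph over
an expression-space kNN (probability of moving toward a neighbor grows with
the cosine between the velocity vector and the displacement toward that
neighbor) and projected onto any 2-D embedding — tissue coordinates being the
intended one — as the transition-expected displacement minus the uniform
expectation over the neighborhood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

from .data_model import ValidationError, _dense

logger = logging.getLogger("ksrv")

DEFAULT_QUANTILE = 0.05
DEFAULT_GRAPH_NEIGHBORS = 30
DEFAULT_SIGMA = 0.05
MIN_NONZERO_CELLS = 10
PCA_GENE_CUTOFF = 500  # reduce to 30 PCs when more genes than this


@dataclass
class VelocityModel:
    """Per-gene steady-state fits and the resulting velocity matrix."""

    gamma: np.ndarray  # per gene; NaN for invalid genes
    r2: np.ndarray  # fit quality of u ~ gamma*s on the extreme cells
    velocity: np.ndarray  # obs x genes, v = u - gamma*s (0 for invalid genes)
    valid_genes: np.ndarray  # boolean mask


@dataclass
class VelocityField:
    """Transition graph plus its projection onto a 2-D embedding."""

    transition: sp.csr_matrix
    arrows: np.ndarray  # obs x 2
    embedding: np.ndarray  # obs x 2


def fit_steady_state(
    S, U, quantile: float = DEFAULT_QUANTILE
) -> VelocityModel:
    """Extreme-quantile steady-state fit of gamma per gene.

    Cells in the bottom and top ``quantile`` of spliced abundance anchor the
    fit; gamma = sum(u*s)/sum(s^2) over those cells (zero-intercept least
    squares).  Genes with fewer than 10 nonzero cells, zero spliced variance
    or a non-positive slope are masked invalid and carry zero velocity.
    """
    S = _dense(S).astype(float)
    U = _dense(U).astype(float)
    if S.shape != U.shape:
        raise ValidationError("spliced and unspliced shapes differ")
    if np.any(S < 0) or np.any(U < 0):
        raise ValidationError("expression layers must be non-negative")
    if not 0 < quantile <= 0.5:
        raise ValidationError("quantile must lie in (0, 0.5]")
    n_obs, n_genes = S.shape
    gamma = np.full(n_genes, np.nan)
    r2 = np.full(n_genes, np.nan)
    valid = np.zeros(n_genes, dtype=bool)
    velocity = np.zeros_like(S)
    for g in range(n_genes):
        s, u = S[:, g], U[:, g]
        if np.count_nonzero(s) < MIN_NONZERO_CELLS or s.var() == 0:
            continue
        lo, hi = np.quantile(s, [quantile, 1 - quantile])
        mask = (s <= lo) | (s >= hi)
        ss = float(np.sum(s[mask] ** 2))
        if ss == 0:
            continue
        g_hat = float(np.sum(u[mask] * s[mask])) / ss
        if g_hat <= 0:
            continue
        res = u[mask] - g_hat * s[mask]
        tot = u[mask] - u[mask].mean()
        sst = float(np.sum(tot**2))
        gamma[g] = g_hat
        r2[g] = 1.0 - float(np.sum(res**2)) / sst if sst > 0 else -np.inf
        valid[g] = True
        velocity[:, g] = u - g_hat * s
    if not valid.any():
        warnings.warn("no gene passed the steady-state fit filters", stacklevel=2)
    return VelocityModel(gamma=gamma, r2=r2, velocity=velocity, valid_genes=valid)


def expression_knn(S, n_neighbors: int) -> sp.csr_matrix:
    """Boolean kNN adjacency (self excluded) in expression space.

    When the gene dimension exceeds 500 the matrix is first reduced to 30
    principal components (deterministic full SVD).
    """
    X = _dense(S).astype(float)
    if X.shape[1] > PCA_GENE_CUTOFF:
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        X = Xc @ Vt[:30].T
    n = X.shape[0]
    n_neighbors = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(X)
    _, idx = nn.kneighbors(X)
    rows, cols = [], []
    for i in range(n):
        nbrs = idx[i][idx[i] != i][:n_neighbors]
        rows.extend([i] * nbrs.size)
        cols.extend(nbrs)
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )


def velocity_graph(
    velocity,
    S,
    neighbors: int = DEFAULT_GRAPH_NEIGHBORS,
    sigma: float = DEFAULT_SIGMA,
    knn: Optional[sp.spmatrix] = None,
) -> sp.csr_matrix:
    """Row-stochastic transition matrix from velocity/displacement cosines.

    pi_ij ∝ exp(cos(v_i, S_j - S_i)/sigma) over the kNN of i, restricted to
    neighbors with positive cosine; zero-velocity observations get a uniform
    outgoing row over their neighborhood.
    """
    V = _dense(velocity).astype(float)
    X = _dense(S).astype(float)
    if neighbors < 2:
        raise ValidationError("neighbors must be >= 2")
    if knn is None:
        knn = expression_knn(X, neighbors)
    knn = sp.csr_matrix(knn)
    n = X.shape[0]
    rows, cols, vals = [], [], []
    n_zero_velocity = 0
    for i in range(n):
        nbrs = knn.indices[knn.indptr[i] : knn.indptr[i + 1]]
        if nbrs.size == 0:
            continue
        v = V[i]
        vnorm = np.linalg.norm(v)
        if vnorm < 1e-12:
            n_zero_velocity += 1
            p = np.full(nbrs.size, 1.0 / nbrs.size)
            rows.extend([i] * nbrs.size)
            cols.extend(nbrs)
            vals.extend(p)
            continue
        disp = X[nbrs] - X[i]
        dnorm = np.linalg.norm(disp, axis=1)
        ok = dnorm > 0
        cos = np.zeros(nbrs.size)
        cos[ok] = (disp[ok] @ v) / (dnorm[ok] * vnorm)
        pos = cos > 0
        if not pos.any():
            continue  # no forward neighbor: empty (isolated) outgoing row
        w = np.exp(cos[pos] / sigma)
        w /= w.sum()
        rows.extend([i] * int(pos.sum()))
        cols.extend(nbrs[pos])
        vals.extend(w)
    if n_zero_velocity:
        logger.info(
            "%d observation(s) with zero velocity take uniform transitions",
            n_zero_velocity,
        )
    T = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return T


def project_velocity(
    transition: sp.spmatrix,
    embedding: np.ndarray,
    neighbor_graph: Optional[sp.spmatrix] = None,
    normalize_displacement: bool = True,
) -> np.ndarray:
    """Project the transition graph onto a 2-D embedding as arrows.

    arrow_i = Σ_j pi_ij δ_ij − (1/|N_i|) Σ_{j∈N_i} δ_ij, with δ_ij the
    displacement e_j − e_i (unit-normalized by default).  The correction term
    runs over the kNN set ``neighbor_graph`` (default: the support of the
    transition row), so a uniform transition row yields a zero arrow.
    """
    T = sp.csr_matrix(transition)
    E = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValidationError("embedding contains non-finite coordinates")
    if E.shape[0] != T.shape[0]:
        raise ValidationError("embedding and transition sizes differ")
    N = sp.csr_matrix(neighbor_graph) if neighbor_graph is not None else T
    arrows = np.zeros((T.shape[0], E.shape[1]))
    for i in range(T.shape[0]):
        t_idx = T.indices[T.indptr[i] : T.indptr[i + 1]]
        t_val = T.data[T.indptr[i] : T.indptr[i + 1]]
        if t_idx.size == 0 or t_val.sum() == 0:
            continue  # isolated / zero row: zero arrow
        n_idx = N.indices[N.indptr[i] : N.indptr[i + 1]]
        if n_idx.size == 0:
            n_idx = t_idx

        def _disp(idx):
            d = E[idx] - E[i]
            if normalize_displacement:
                norms = np.linalg.norm(d, axis=1)
                norms[norms == 0] = 1.0
                d = d / norms[:, None]
            return d

        arrows[i] = t_val @ _disp(t_idx) - _disp(n_idx).mean(axis=0)
    return arrows


def velocity_pseudotime(
    transition: sp.spmatrix, root: Optional[int] = None
) -> np.ndarray:
    """Diffusion arrival order through the transition graph, scaled to [0, 1].

    Probability mass diffuses from the root (default: the observation with
    minimal incoming transition mass); each observation is ranked by the
    iteration at which mass first reaches it, ties refined by the amount of
    arriving mass.  Disconnected components are ordered independently with a
    warning; the result is min-max normalized per component.
    """
    T = sp.csr_matrix(transition)
    n = T.shape[0]
    support = T.copy()
    support.setdiag(0)
    support.eliminate_zeros()
    n_comp, comp = connected_components(support, directed=True, connection="weak")
    if n_comp > 1:
        warnings.warn(
            f"transition graph has {n_comp} components; pseudotime computed "
            "per component",
            stacklevel=2,
        )
    incoming = np.asarray(T.sum(axis=0)).ravel()
    pt = np.zeros(n)
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if members.size == 1:
            pt[members] = 0.0
            continue
        sub = T[members][:, members]
        row_sums = np.asarray(sub.sum(axis=1)).ravel()
        # renormalize rows so mass is conserved inside the component
        scale = np.where(row_sums > 0, 1.0 / np.maximum(row_sums, 1e-300), 0.0)
        sub = sp.diags(scale) @ sub
        if root is not None and comp[root] == c:
            r = int(np.flatnonzero(members == root)[0])
        else:
            r = int(np.argmin(incoming[members]))
        m = members.size
        arrival = np.full(m, np.inf)
        arrival_mass = np.zeros(m)
        p = np.zeros(m)
        p[r] = 1.0
        eps = 1e-12
        for step in range(2 * m):
            newly = (p > eps) & ~np.isfinite(arrival)
            arrival[newly] = step
            arrival_mass[newly] = p[newly]
            if np.all(np.isfinite(arrival)):
                break
            p = sub.T @ p
            if p.sum() == 0:
                break
        unreached = ~np.isfinite(arrival)
        if unreached.any():
            arrival[unreached] = np.nanmax(arrival[~unreached]) + 1
        order = np.lexsort((np.arange(m), -arrival_mass, arrival))
        ranks = np.empty(m)
        ranks[order] = np.arange(m)
        pt[members] = ranks / (m - 1)
    return pt
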