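"""Quantitative comparison of velocity fields and expression predictions.

The headline metric is a magnitude-weighted cosine similarity between an
estimated and a reference vector field:

    score = Σ_i β_i · CS_i,   β_i = M_i / Σ_j M_j

where M_i is the reference vector's norm at observation i and CS_i the cosine
between the estimated and reference vectors there.  It applies unchanged to
high-dimensional (gene-space) velocities and to projected 2-D arrows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_model import ValidationError, _dense

logger = logging.getLogger("ksrv")


@dataclass
class SimilarityBreakdown:
    """Per-observation cosines, magnitude weights and the weighted score."""

    per_obs_cosine: np.ndarray
    magnitudes: np.ndarray
    weights: np.ndarray
    score: float


@dataclass
class PredictionMetrics:
    """Per-observation cosine/Spearman agreement of predicted expression."""

    per_obs_cosine: np.ndarray
    per_obs_spearman: np.ndarray
    mean_cosine: float
    mean_spearman: float
    n_excluded: int = 0


def _cosine_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise cosine; zero whenever either vector is zero."""
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    denom = na * nb
    out = np.zeros(A.shape[0])
    ok = denom > 0
    out[ok] = np.einsum("ij,ij->i", A[ok], B[ok]) / denom[ok]
    return np.clip(out, -1.0, 1.0)


def similarity_score(
    estimated,
    reference,
    weight_field: str = "reference",
) -> SimilarityBreakdown:
    """Magnitude-weighted cosine similarity between two vector fields.

    Weights derive from the reference field's vector norms by default
    (``weight_field="estimated"`` switches, for sensitivity checks).
    """
    E = _dense(estimated).astype(float)
    R = _dense(reference).astype(float)
    if E.shape != R.shape:
        raise ValidationError("estimated and reference shapes differ")
    if E.shape[1] < 2:
        raise ValidationError("vectors must have dimension >= 2")
    M = np.linalg.norm(R if weight_field == "reference" else E, axis=1)
    total = M.sum()
    if total == 0:
        raise ValidationError("all weighting vectors are zero; weights undefined")
    beta = M / total
    cs = _cosine_rows(E, R)
    # sum(M*cs)/sum(M) keeps the identity score(V, V) = 1 exact in float
    return SimilarityBreakdown(
        per_obs_cosine=cs,
        magnitudes=M,
        weights=beta,
        score=float(np.sum(M * cs) / total),
    )


def prediction_metrics(predicted, observed) -> PredictionMetrics:
    """Per-observation cosine and Spearman agreement, averaged over cells.

    Spearman uses average ranks for ties.  Observations whose observed gene
    vector has zero variance are excluded from the means (counted in
    ``n_excluded``); their per-observation Spearman is NaN.
    """
    P = _dense(predicted).astype(float)
    O = _dense(observed).astype(float)
    if P.shape != O.shape:
        raise ValidationError("predicted and observed shapes differ")
    cos = _cosine_rows(P, O)
    n_obs = P.shape[0]
    spear = np.full(n_obs, np.nan)
    excluded = np.zeros(n_obs, dtype=bool)
    for i in range(n_obs):
        o = O[i]
        if np.ptp(o) == 0:
            excluded[i] = True
            continue
        rp = rankdata(P[i])
        ro = rankdata(o)
        if np.ptp(rp) == 0:
            spear[i] = 0.0
            continue
        spear[i] = float(np.corrcoef(rp, ro)[0, 1])
    if excluded.any():
        logger.info(
            "%d observation(s) with zero-variance observed vector excluded "
            "from metric means",
            int(excluded.sum()),
        )
    keep = ~excluded
    return PredictionMetrics(
        per_obs_cosine=cos,
        per_obs_spearman=spear,
        mean_cosine=float(cos[keep].mean()) if keep.any() else np.nan,
        mean_spearman=float(np.nanmean(spear[keep])) if keep.any() else np.nan,
        n_excluded=int(excluded.sum()),
    )
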