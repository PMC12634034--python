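"""Spatiotemporal analytics: distance dynamics over pseudotime and omega.

Two downstream analyses of an inferred spatial trajectory:

* Distance dynamics — Euclidean distance of every spot from an origin,
  binned over ten equal pseudotime intervals; per-bin population variance and
  10th/90th-percentile distances are fitted with cubic polynomials of the
  bin-median time, describing spatial convergence or dispersion of the tissue
  over differentiation.

* Omega — per cell type, the weight ω ∈ [0, 1] in the pseudo-spatiotemporal
  model Y' = ωT + (1-ω)D balancing the temporal (pseudotime T) against the
  spatial (distance D) contribution to a spot's mean nonzero expression Y,
  fitted by least squares in closed form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import ValidationError, _dense

logger = logging.getLogger("ksrv")

DEFAULT_N_BINS = 10


@dataclass
class SpatioTemporalProfile:
    """Binned distance statistics over pseudotime plus cubic-trend fits.

    Bins with fewer than two observations carry NaN and are excluded from
    the cubic fits.  Cubic coefficients are ordered (a, b, c, d) for
    a·t³ + b·t² + c·t + d.
    """

    bin_edges: np.ndarray
    bin_median_times: np.ndarray
    bin_counts: np.ndarray
    variances: Optional[np.ndarray] = None
    p10: Optional[np.ndarray] = None
    p90: Optional[np.ndarray] = None
    cubic_coeffs_variance: Optional[tuple] = None
    cubic_coeffs_p10: Optional[tuple] = None
    cubic_coeffs_p90: Optional[tuple] = None


@dataclass
class OmegaEstimates:
    """Per-cell-type temporal-vs-spatial weights and their fit losses."""

    per_type_omega: dict[str, float]
    per_type_loss: dict[str, float]
    n_per_type: dict[str, int]
    missing: dict[str, str] = field(default_factory=dict)


def distance_from_origin(
    coords: np.ndarray, origin: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Euclidean distance of each observation from ``origin``."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coordinates contain non-finite values")
    o = np.asarray(origin, dtype=float)
    return np.sqrt(((coords - o) ** 2).sum(axis=1))


def _bin_assign(t: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bins over [min t, max t]; last bin closed on both ends."""
    edges = np.linspace(t.min(), t.max(), n_bins + 1)
    idx = np.digitize(t, edges[1:-1], right=False)  # 0..n_bins-1
    return edges, idx


def binned_variance(
    d: np.ndarray, t: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> SpatioTemporalProfile:
    """Population variance (1/n) of distances per equal-width pseudotime bin."""
    d, t, edges, idx, counts = _check_binned(d, t, n_bins)
    variances = np.full(n_bins, np.nan)
    medians = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if counts[b] >= 1:
            medians[b] = np.median(t[sel])
        if counts[b] >= 2:
            db = d[sel]
            variances[b] = float(np.mean((db - db.mean()) ** 2))
    return SpatioTemporalProfile(
        bin_edges=edges,
        bin_median_times=medians,
        bin_counts=counts,
        variances=variances,
    )


def percentile_trends(
    d: np.ndarray,
    t: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    lo: float = 10.0,
    hi: float = 90.0,
) -> SpatioTemporalProfile:
    """Per-bin linear-interpolation percentiles of distance (robust extrema)."""
    d, t, edges, idx, counts = _check_binned(d, t, n_bins)
    p_lo = np.full(n_bins, np.nan)
    p_hi = np.full(n_bins, np.nan)
    medians = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if counts[b] >= 1:
            medians[b] = np.median(t[sel])
        if counts[b] >= 2:
            p_lo[b], p_hi[b] = np.percentile(d[sel], [lo, hi], method="linear")
    profile = SpatioTemporalProfile(
        bin_edges=edges,
        bin_median_times=medians,
        bin_counts=counts,
        p10=p_lo,
        p90=p_hi,
    )
    ok = np.isfinite(medians) & np.isfinite(p_lo)
    if ok.sum() >= 4:
        profile.cubic_coeffs_p10 = cubic_fit(medians[ok], p_lo[ok])[0]
        profile.cubic_coeffs_p90 = cubic_fit(medians[ok], p_hi[ok])[0]
    return profile


def _check_binned(d, t, n_bins):
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    if d.shape != t.shape:
        raise ValidationError("distances and pseudotimes must align")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    edges, idx = _bin_assign(t, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return d, t, edges, idx, counts


def cubic_fit(x: np.ndarray, y: np.ndarray) -> tuple[tuple, float]:
    """Least-squares cubic a·x³ + b·x² + c·x + d; returns coefficients and RSS.

    Requires at least 4 finite points; a rank-deficient design (duplicated x)
    yields the minimum-norm solution with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValidationError("cubic fit requires at least 4 finite points")
    A = np.vander(x, 4)  # columns x^3, x^2, x, 1
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < 4:
        warnings.warn(
            "rank-deficient cubic design (duplicated x); minimum-norm solution",
            stacklevel=2,
        )
    rss = float(np.sum((A @ coef - y) ** 2))
    return tuple(coef), rss


def spatiotemporal_profile(
    coords: np.ndarray,
    t: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    origin: tuple[float, float] = (0.0, 0.0),
) -> SpatioTemporalProfile:
    """Full distance-dynamics profile: variance + percentiles + cubic trends."""
    d = distance_from_origin(coords, origin)
    var_part = binned_variance(d, t, n_bins)
    pct_part = percentile_trends(d, t, n_bins)
    profile = SpatioTemporalProfile(
        bin_edges=var_part.bin_edges,
        bin_median_times=var_part.bin_median_times,
        bin_counts=var_part.bin_counts,
        variances=var_part.variances,
        p10=pct_part.p10,
        p90=pct_part.p90,
        cubic_coeffs_p10=pct_part.cubic_coeffs_p10,
        cubic_coeffs_p90=pct_part.cubic_coeffs_p90,
    )
    ok = np.isfinite(profile.bin_median_times) & np.isfinite(profile.variances)
    if ok.sum() >= 4:
        profile.cubic_coeffs_variance = cubic_fit(
            profile.bin_median_times[ok], profile.variances[ok]
        )[0]
    return profile


def mean_nonzero_expression(X) -> np.ndarray:
    """Mean of strictly positive entries per observation row (0 if none)."""
    M = _dense(X).astype(float)
    if np.any(M < 0):
        raise ValidationError("expression must be non-negative")
    pos = M > 0
    counts = pos.sum(axis=1)
    sums = np.where(pos, M, 0.0).sum(axis=1)
    all_zero = counts == 0
    if all_zero.any():
        logger.info("%d all-zero observation(s); mean nonzero set to 0",
                    int(all_zero.sum()))
    return np.where(all_zero, 0.0, sums / np.maximum(counts, 1))


def _minmax(a: np.ndarray) -> np.ndarray:
    span = a.max() - a.min()
    return (a - a.min()) / span if span > 0 else np.zeros_like(a)


def estimate_omega(
    T: np.ndarray,
    D: np.ndarray,
    Y: np.ndarray,
    types: np.ndarray,
    rescale: bool = True,
) -> OmegaEstimates:
    """Per-type least-squares fit of Y ≈ ωT + (1-ω)D, ω clipped to [0, 1].

    T, D and Y are each min-max rescaled to [0, 1] before fitting (they mix
    physical units otherwise).  The closed form is
    ω* = Σ(T-D)(Y-D) / Σ(T-D)², restricted to observations of the type; a
    type with Σ(T-D)² = 0 has no identifiable ω and is reported missing.
    """
    T = np.asarray(T, dtype=float)
    D = np.asarray(D, dtype=float)
    Y = np.asarray(Y, dtype=float)
    types = np.asarray(types, dtype=object)
    if not (T.shape == D.shape == Y.shape == types.shape):
        raise ValidationError("T, D, Y and types must align per observation")
    if rescale:
        T, D, Y = _minmax(T), _minmax(D), _minmax(Y)
    omegas: dict[str, float] = {}
    losses: dict[str, float] = {}
    counts: dict[str, int] = {}
    missing: dict[str, str] = {}
    for typ in sorted({str(t) for t in types}):
        sel = types == typ
        t, d, y = T[sel], D[sel], Y[sel]
        counts[typ] = int(sel.sum())
        denom = float(np.sum((t - d) ** 2))
        if denom == 0:
            missing[typ] = "T and D coincide for every spot of this type"
            continue
        w = float(np.clip(np.sum((t - d) * (y - d)) / denom, 0.0, 1.0))
        omegas[typ] = w
        losses[typ] = float(np.sum((w * t + (1 - w) * d - y) ** 2))
    return OmegaEstimates(
        per_type_omega=omegas,
        per_type_loss=losses,
        n_per_type=counts,
        missing=missing,
    )
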