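"""Synthetic paired scRNA-seq + spatial datasets with known kinetics.

Every stage of the pipeline is testable against this generator: genes follow
the splicing ODE

    du/dt = alpha - beta*u,   ds/dt = beta*u - gamma*s    (beta ≡ 1)

solved in closed form along a pseudotime trajectory, with one induction
phase (alpha on) up to a per-gene switch time followed by repression
(alpha = 0).  Pseudotime t ∈ [0, 1] maps to ODE time t·t_max so that slow
genes still approach their steady state within the trajectory.  The
reference modality carries all genes plus noisy spliced/unspliced layers and
time-tercile cell-type labels; the spatial modality carries total expression
on a gene subset plus coordinates laid out along the trajectory (gradient,
radial or per-type cluster layouts).  True rates, times, velocities and
labels are returned alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import OmicsDataset, ValidationError

logger = logging.getLogger("ksrv")


@dataclass
class SimulationConfig:
    """Generator settings; the defaults define the standard benchmark regime."""

    n_ref_cells: int = 500
    n_spots: int = 300
    n_genes: int = 200
    n_shared_genes: int = 60
    n_types: int = 3
    gamma_range: tuple[float, float] = (0.3, 1.5)
    alpha_range: tuple[float, float] = (2.0, 8.0)
    switch_time_range: tuple[float, float] = (0.4, 0.8)
    noise_sd: float = 0.1
    spatial_layout: str = "gradient"
    spatial_noise_sd: float = 0.05
    t_max: float = 20.0  # ODE time spanned by pseudotime [0, 1]
    omega_true: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_shared_genes > self.n_genes:
            raise ValidationError("n_shared_genes cannot exceed n_genes")
        for name in ("gamma_range", "alpha_range", "switch_time_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 < lo <= hi")
        if self.spatial_layout not in ("gradient", "radial", "clusters"):
            raise ValidationError(f"unknown spatial_layout {self.spatial_layout!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must infer."""

    true_gamma: np.ndarray  # per gene
    ref_time: np.ndarray
    spot_time: np.ndarray
    ref_velocity: np.ndarray  # pre-noise ds/dt, cells x genes
    spot_velocity: np.ndarray
    ref_labels: np.ndarray
    spot_labels: np.ndarray
    shared_index: np.ndarray = field(default_factory=lambda: np.array([], int))
    true_omega: Optional[dict[str, float]] = None


def _kinetics_at(
    tau: np.ndarray, alpha: float, beta: float, gamma: float, t_switch: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form u(tau), s(tau): induction until t_switch, then repression."""

    def _uv(tau, alpha, u0, s0):
        e_b = np.exp(-beta * tau)
        u = u0 * e_b + alpha / beta * (1 - e_b)
        e_g = np.exp(-gamma * tau)
        if abs(gamma - beta) > 1e-9:
            s = (
                s0 * e_g
                + alpha / gamma * (1 - e_g)
                + (alpha - beta * u0) / (gamma - beta) * (e_g - e_b)
            )
        else:  # gamma -> beta limit
            s = s0 * e_g + alpha / gamma * (1 - e_g) + (beta * u0 - alpha) * tau * e_g
        return u, s

    tau = np.asarray(tau, dtype=float)
    u = np.empty_like(tau)
    s = np.empty_like(tau)
    ind = tau <= t_switch
    u[ind], s[ind] = _uv(tau[ind], alpha, 0.0, 0.0)
    u_sw, s_sw = _uv(np.array([t_switch]), alpha, 0.0, 0.0)
    u[~ind], s[~ind] = _uv(tau[~ind] - t_switch, 0.0, float(u_sw[0]), float(s_sw[0]))
    return u, s


def simulate_kinetics(
    config: SimulationConfig,
    times: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Forward-simulate noisy (U, S) for ``n_ref_cells`` cells.

    Per gene, alpha ~ U(alpha_range), gamma ~ U(gamma_range), beta = 1, one
    switch time ~ U(switch_time_range) (as a fraction of t_max).  Cell times
    are uniform on [0, 1] unless given.  Gaussian noise (sd ``noise_sd``,
    clipped at zero) corrupts the counts; the true velocity beta*u - gamma*s
    is recorded before noise.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_cells = config.n_ref_cells if times is None else len(times)
    t = rng.uniform(0, 1, n_cells) if times is None else np.asarray(times, float)
    alpha = rng.uniform(*config.alpha_range, config.n_genes)
    gamma = rng.uniform(*config.gamma_range, config.n_genes)
    t_sw = rng.uniform(*config.switch_time_range, config.n_genes) * config.t_max
    beta = 1.0
    U = np.empty((n_cells, config.n_genes))
    S = np.empty((n_cells, config.n_genes))
    tau = t * config.t_max
    for g in range(config.n_genes):
        U[:, g], S[:, g] = _kinetics_at(tau, alpha[g], beta, gamma[g], t_sw[g])
    velocity = beta * U - S * gamma[None, :]
    if config.noise_sd > 0:
        U = np.clip(U + rng.normal(0, config.noise_sd, U.shape), 0, None)
        S = np.clip(S + rng.normal(0, config.noise_sd, S.shape), 0, None)
    labels = _tercile_labels(t, config.n_types)
    truth = GroundTruth(
        true_gamma=gamma,
        ref_time=t,
        spot_time=np.array([]),
        ref_velocity=velocity,
        spot_velocity=np.empty((0, config.n_genes)),
        ref_labels=labels,
        spot_labels=np.array([], dtype=object),
    )
    return U, S, truth


def _tercile_labels(t: np.ndarray, n_types: int) -> np.ndarray:
    """Split times into n_types equal-count ordered groups ("type_0", ...)."""
    qs = np.quantile(t, np.linspace(0, 1, n_types + 1)[1:-1]) if n_types > 1 else []
    idx = np.digitize(t, qs)
    return np.array([f"type_{i}" for i in idx], dtype=object)


def _coords_for(
    t: np.ndarray,
    labels: np.ndarray,
    layout: str,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = t.size
    if layout == "gradient":
        x = t + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)
        y = rng.uniform(0, 1, n)
        return np.column_stack([x, y])
    if layout == "radial":
        r = t + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)
        theta = rng.uniform(0, 2 * np.pi, n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    # clusters: one center per type on a circle
    types = sorted(set(labels))
    centers = {
        typ: (np.cos(2 * np.pi * i / len(types)), np.sin(2 * np.pi * i / len(types)))
        for i, typ in enumerate(types)
    }
    pts = np.array([centers[l] for l in labels], dtype=float)
    return pts + rng.normal(0, max(noise_sd, 1e-3), (n, 2))


def simulate_paired(
    config: SimulationConfig,
) -> tuple[OmicsDataset, OmicsDataset, GroundTruth]:
    """Paired reference + spatial datasets from one kinetic model.

    Reference cells and spatial spots are independent draws along the same
    trajectory (held-out cells), so the two modalities share latent structure
    by construction.  The spatial dataset carries total expression on a
    random ``n_shared_genes`` subset and coordinates correlated with true
    time per the chosen layout.  When ``omega_true`` maps each type to a
    weight, spot expression is rescaled so its mean nonzero expression equals
    ω·T + (1-ω)·D, enabling omega-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    # one parameter draw shared by both modalities
    alpha = rng.uniform(*config.alpha_range, config.n_genes)
    gamma = rng.uniform(*config.gamma_range, config.n_genes)
    t_sw = rng.uniform(*config.switch_time_range, config.n_genes) * config.t_max
    beta = 1.0

    def _generate(n_obs: int):
        t = rng.uniform(0, 1, n_obs)
        tau = t * config.t_max
        U = np.empty((n_obs, config.n_genes))
        S = np.empty((n_obs, config.n_genes))
        for g in range(config.n_genes):
            U[:, g], S[:, g] = _kinetics_at(tau, alpha[g], beta, gamma[g], t_sw[g])
        vel = beta * U - S * gamma[None, :]
        if config.noise_sd > 0:
            U = np.clip(U + rng.normal(0, config.noise_sd, U.shape), 0, None)
            S = np.clip(S + rng.normal(0, config.noise_sd, S.shape), 0, None)
        return t, U, S, vel

    t_ref, U_ref, S_ref, vel_ref = _generate(config.n_ref_cells)
    t_sp, U_sp, S_sp, vel_sp = _generate(config.n_spots)
    labels_ref = _tercile_labels(t_ref, config.n_types)
    labels_sp = _tercile_labels(t_sp, config.n_types)
    shared = np.sort(
        rng.choice(config.n_genes, size=config.n_shared_genes, replace=False)
    )
    gene_ids = [f"gene_{g:04d}" for g in range(config.n_genes)]

    coords = _coords_for(
        t_sp, labels_sp, config.spatial_layout, config.spatial_noise_sd, rng
    )
    X_sp = (S_sp + U_sp)[:, shared]
    truth = GroundTruth(
        true_gamma=gamma,
        ref_time=t_ref,
        spot_time=t_sp,
        ref_velocity=vel_ref,
        spot_velocity=vel_sp,
        ref_labels=labels_ref,
        spot_labels=labels_sp,
        shared_index=shared,
        true_omega=dict(config.omega_true) if config.omega_true else None,
    )
    if config.omega_true:
        X_sp = _rescale_for_omega(
            X_sp, t_sp, coords, labels_sp, config.omega_true, rng, config.noise_sd
        )
    ref = OmicsDataset(
        matrix=S_ref + U_ref,
        gene_ids=gene_ids,
        obs_ids=[f"cell_{i:05d}" for i in range(config.n_ref_cells)],
        spliced=S_ref,
        unspliced=U_ref,
        labels=labels_ref,
        pseudotime=t_ref,
    )
    spatial = OmicsDataset(
        matrix=X_sp,
        gene_ids=[gene_ids[g] for g in shared],
        obs_ids=[f"spot_{i:05d}" for i in range(config.n_spots)],
        coords=coords,
        labels=labels_sp,
        pseudotime=t_sp,
    )
    return ref, spatial, truth


def _rescale_for_omega(X, t, coords, labels, omega_true, rng, noise_sd):
    """Rescale spot rows so mean nonzero expression follows ωT + (1-ω)D."""
    from .spatiotemporal import distance_from_origin, mean_nonzero_expression

    d = distance_from_origin(coords)
    span = d.max() - d.min()
    d_norm = (d - d.min()) / span if span > 0 else np.zeros_like(d)
    w = np.array([omega_true[str(l)] for l in labels], dtype=float)
    target = w * t + (1 - w) * d_norm
    if noise_sd > 0:
        target = target + rng.normal(0, noise_sd, target.size)
    target = np.clip(target, 1e-6, None)
    current = mean_nonzero_expression(X)
    factors = np.where(current > 0, target / np.maximum(current, 1e-300), 1.0)
    return X * factors[:, None]


def simulate_omega_data(
    omega_true: dict[str, float],
    n_per_type: int,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Direct draw of (T, D, Y, types) from Y = ωT + (1-ω)D + noise.

    T and D are independent uniforms on [0, 1]; each type contributes
    ``n_per_type`` observations with its own ω.
    """
    rng = np.random.default_rng(seed)
    Ts, Ds, Ys, types = [], [], [], []
    for typ in sorted(omega_true):
        w = float(omega_true[typ])
        if not 0 <= w <= 1:
            raise ValidationError("omega values must lie in [0, 1]")
        T = rng.uniform(0, 1, n_per_type)
        D = rng.uniform(0, 1, n_per_type)
        Y = w * T + (1 - w) * D + rng.normal(0, noise_sd, n_per_type)
        Ts.append(T)
        Ds.append(D)
        Ys.append(Y)
        types.extend([typ] * n_per_type)
    return (
        np.concatenate(Ts),
        np.concatenate(Ds),
        np.concatenate(Ys),
        np.array(types, dtype=object),
    )
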