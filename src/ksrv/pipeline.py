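"""End-to-end pipeline: integrate → impute → velocity → analytics.

:class:`PipelineConfig` collects every stage parameter with its default
(similarity threshold 0.3, k = 50 neighbors, 10 pseudotime bins);
:func:`run_pipeline` composes the stages on a reference/spatial dataset pair
and returns a :class:`PipelineResult` whose ``metrics`` dict is JSON-ready
and byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import imputation, integration, spatiotemporal, velocity
from .data_model import OmicsDataset, ValidationError, intersect_genes
from .evaluation import similarity_score

logger = logging.getLogger("ksrv")


class ConfigError(ValueError):
    """Raised when a pipeline configuration value is invalid."""


@dataclass
class PipelineConfig:
    """Resolved parameters of every stage (logged with each run)."""

    n_components: int = 50
    threshold: float = 0.3
    gamma: Optional[float] = None
    kernel: str = "rbf"
    k: int = 50
    velocity_mode: str = "steady_state"
    quantile: float = 0.05
    graph_neighbors: int = 30
    sigma: float = 0.05
    n_bins: int = 10
    origin: tuple[float, float] = (0.0, 0.0)
    embedding: str = "spatial"
    target_sum: Optional[float] = None
    log1p: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.threshold < 1:
            raise ConfigError("threshold must lie in [0, 1)")
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if not 0 < self.quantile <= 0.5:
            raise ConfigError("quantile must lie in (0, 0.5]")
        if self.kernel not in ("rbf", "linear"):
            raise ConfigError(f"unsupported kernel {self.kernel!r}")
        if self.velocity_mode != "steady_state":
            raise ConfigError("only the steady_state velocity mode is available")
        if self.embedding not in ("spatial",):
            raise ConfigError("embedding must be 'spatial' (coordinates)")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigError("gamma must be positive when given")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["origin"] = list(self.origin)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "origin" in d and not isinstance(d["origin"], tuple):
            d["origin"] = tuple(d["origin"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    config: PipelineConfig
    aligned: integration.AlignedEmbedding
    assignment: imputation.NeighborAssignment
    spliced_pred: np.ndarray
    unspliced_pred: np.ndarray
    labels: Optional[imputation.LabelTransferResult]
    velocity_model: velocity.VelocityModel
    field: velocity.VelocityField
    pseudotime: np.ndarray
    profile: Optional[spatiotemporal.SpatioTemporalProfile]
    omega: Optional[spatiotemporal.OmegaEstimates]
    metrics: dict = field(default_factory=dict)

    def enriched_spatial(self, spatial: OmicsDataset, ref: OmicsDataset):
        """AnnData container of the spatial modality enriched with predictions."""
        import anndata as ad
        import pandas as pd

        adata = ad.AnnData(
            X=self.spliced_pred + self.unspliced_pred,
            obs=pd.DataFrame(index=pd.Index(spatial.obs_ids, name="obs_id")),
            var=pd.DataFrame(index=pd.Index(ref.gene_ids, name="gene_id")),
        )
        adata.layers["spliced_pred"] = self.spliced_pred
        adata.layers["unspliced_pred"] = self.unspliced_pred
        adata.layers["velocity"] = self.velocity_model.velocity
        if spatial.coords is not None:
            adata.obsm["spatial"] = spatial.coords.copy()
            adata.obsm["velocity_spatial"] = self.field.arrows
        if self.labels is not None:
            adata.obs["cell_type_pred"] = pd.Categorical(self.labels.assigned)
            adata.obsm["cell_type_scores"] = self.labels.scores
        adata.obs["pseudotime"] = self.pseudotime
        adata.uns["component_similarities"] = self.aligned.component_similarities
        adata.uns["config"] = json.dumps(self.config.to_dict(), sort_keys=True)
        adata.var["velocity_gamma"] = self.velocity_model.gamma
        adata.var["velocity_r2"] = self.velocity_model.r2
        adata.var["velocity_genes"] = self.velocity_model.valid_genes
        return adata


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ValueError as exc:
        raise type(exc)(
            f"[stage {name}] {exc} (check the {name} inputs/parameters)"
        ) from exc


def run_pipeline(
    ref: OmicsDataset,
    spatial: OmicsDataset,
    config: Optional[PipelineConfig] = None,
    reference_velocity: Optional[np.ndarray] = None,
) -> PipelineResult:
    """Run integrate → impute → velocity → spatiotemporal on a dataset pair.

    ``reference_velocity`` (spots x ref genes, or spots x shared genes) adds
    an evaluation of the inferred high-dimensional velocity to the metrics.
    """
    config = config or PipelineConfig()
    np.random.seed(config.seed % (2**31))  # stages are deterministic; belt & braces
    logger.info("pipeline config: %s", json.dumps(config.to_dict(), sort_keys=True))

    aligned = _stage(
        "integration",
        integration.integrate,
        ref,
        spatial,
        n_components=config.n_components,
        threshold=config.threshold,
        gamma=config.gamma,
        kernel=config.kernel,
        target_sum=config.target_sum,
        log1p=config.log1p,
    )
    assignment = _stage(
        "imputation",
        imputation.find_neighbors,
        aligned.spatial_scores,
        aligned.ref_scores,
        config.k,
    )
    assignment = _stage("imputation", imputation.compute_weights, assignment)
    spliced_pred, unspliced_pred = _stage(
        "imputation", imputation.impute_layers, assignment, ref
    )
    labels = None
    if ref.labels is not None:
        labels = _stage(
            "imputation", imputation.transfer_labels, assignment, ref.labels
        )

    vm = _stage(
        "velocity",
        velocity.fit_steady_state,
        spliced_pred,
        unspliced_pred,
        config.quantile,
    )
    knn = velocity.expression_knn(spliced_pred, config.graph_neighbors)
    transition = _stage(
        "velocity",
        velocity.velocity_graph,
        vm.velocity,
        spliced_pred,
        config.graph_neighbors,
        config.sigma,
        knn,
    )
    if spatial.coords is None:
        raise ValidationError("[stage velocity] spatial dataset lacks coordinates")
    arrows = _stage(
        "velocity", velocity.project_velocity, transition, spatial.coords, knn
    )
    fld = velocity.VelocityField(
        transition=transition, arrows=arrows, embedding=spatial.coords
    )
    if spatial.pseudotime is not None:
        pt = spatial.pseudotime
    else:
        pt = _stage("velocity", velocity.velocity_pseudotime, transition)

    profile = None
    omega = None
    if spatial.coords is not None:
        profile = _stage(
            "spatiotemporal",
            spatiotemporal.spatiotemporal_profile,
            spatial.coords,
            pt,
            config.n_bins,
            config.origin,
        )
        if labels is not None:
            d = spatiotemporal.distance_from_origin(spatial.coords, config.origin)
            y = spatiotemporal.mean_nonzero_expression(spatial.matrix)
            omega = _stage(
                "spatiotemporal",
                spatiotemporal.estimate_omega,
                pt,
                d,
                y,
                labels.assigned,
            )

    metrics: dict = {
        "n_components_retained": int(aligned.n_components),
        "component_similarities": [
            round(float(s), 12) for s in aligned.component_similarities
        ],
        "n_velocity_genes": int(vm.valid_genes.sum()),
        "median_gamma": float(np.nanmedian(vm.gamma)),
        "k": int(assignment.k),
        "n_spots": int(spatial.n_obs),
        "n_ref_cells": int(ref.n_obs),
    }
    if labels is not None:
        counts = {
            t: int((labels.assigned == t).sum()) for t in labels.types
        }
        metrics["label_counts"] = counts
    if omega is not None:
        metrics["omega"] = {t: round(w, 12) for t, w in omega.per_type_omega.items()}
    if reference_velocity is not None:
        gi = intersect_genes(ref, spatial)
        est = vm.velocity[:, gi.ref_index]
        rv = np.asarray(reference_velocity, dtype=float)
        if rv.shape[1] == ref.n_genes:
            rv = rv[:, gi.ref_index]
        if rv.shape != est.shape:
            raise ValidationError(
                "reference_velocity must cover the spots on all or shared genes"
            )
        metrics["velocity_similarity_score"] = round(
            similarity_score(est, rv).score, 12
        )
    return PipelineResult(
        config=config,
        aligned=aligned,
        assignment=assignment,
        spliced_pred=spliced_pred,
        unspliced_pred=unspliced_pred,
        labels=labels,
        velocity_model=vm,
        field=fld,
        pseudotime=pt,
        profile=profile,
        omega=omega,
        metrics=metrics,
    )


def metrics_json(result: PipelineResult) -> str:
    """Canonical (sorted, fixed-precision) JSON rendering of run metrics."""
    return json.dumps(result.metrics, sort_keys=True, indent=2)
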