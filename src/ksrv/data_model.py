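"""Core containers and I/O for paired single-cell and spatial expression data.

The central container is :class:`OmicsDataset`, a light obs x genes matrix
holder with optional spliced/unspliced layers (for the reference scRNA-seq
modality), 2-D coordinates (for the spatial modality), categorical labels and
a pseudotime column.  Supported on-disk formats: h5ad (primary), an MTX
directory (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` with optional
``spliced.mtx``/``unspliced.mtx``/``coords.csv``/``obs.csv``) and a plain CSV
matrix.  MTX matrices are stored obs x genes (rows are observations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("ksrv")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as a supported format."""


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


SPARSE_DENSITY_CUTOFF = 0.5  # store sparse when more than half the entries are zero


def _as_2d(m) -> np.ndarray | sp.spmatrix:
    if sp.issparse(m):
        return m.tocsr()
    a = np.asarray(m)
    if a.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got shape {a.shape}")
    return a


def _density(m) -> float:
    if sp.issparse(m):
        return m.nnz / max(1, m.shape[0] * m.shape[1])
    return np.count_nonzero(m) / max(1, m.size)


def _maybe_sparsify(m):
    """Store sparse when >50% zeros, dense otherwise."""
    if _density(m) < SPARSE_DENSITY_CUTOFF:
        return sp.csr_matrix(m)
    return m.toarray() if sp.issparse(m) else np.asarray(m)


def _dense(m) -> np.ndarray:
    return np.asarray(m.todense()) if sp.issparse(m) else np.asarray(m)


@dataclass
class OmicsDataset:
    """Observations x genes expression with optional kinetic layers and metadata.

    Parameters
    ----------
    matrix
        Non-negative total expression, ``n_obs x n_genes``.
    gene_ids, obs_ids
        Ordered unique identifiers (whitespace-stripped, case preserved).
    spliced, unspliced
        Optional layers with the same shape as ``matrix`` (mature / nascent
        transcript abundance per cell and gene).
    coords
        Optional ``n_obs x 2`` spatial coordinates.
    labels
        Optional categorical annotation per observation (cell types).
    pseudotime
        Optional per-observation scalar; min-max normalized to [0, 1] on
        construction when it falls outside that range.
    raw
        Optional original count matrix kept alongside after normalization.
    """

    matrix: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    obs_ids: list[str]
    spliced: Optional[np.ndarray | sp.spmatrix] = None
    unspliced: Optional[np.ndarray | sp.spmatrix] = None
    coords: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    pseudotime: Optional[np.ndarray] = None
    raw: Optional[np.ndarray | sp.spmatrix] = None

    def __post_init__(self) -> None:
        self.matrix = _as_2d(self.matrix)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.obs_ids = [str(o).strip() for o in self.obs_ids]
        n_obs, n_genes = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.obs_ids) != n_obs:
            raise ValidationError(
                f"{len(self.obs_ids)} obs ids for {n_obs} matrix rows"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicated gene ids: {sorted(dup)}")
        for name in ("spliced", "unspliced"):
            layer = getattr(self, name)
            if layer is not None:
                layer = _as_2d(layer)
                if layer.shape != self.matrix.shape:
                    raise ValidationError(
                        f"layer {name!r} shape {layer.shape} != matrix shape "
                        f"{self.matrix.shape}"
                    )
                setattr(self, name, layer)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n_obs, 2):
                raise ValidationError(
                    f"coords shape {self.coords.shape} != ({n_obs}, 2)"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n_obs,):
                raise ValidationError("labels length mismatch")
        if self.pseudotime is not None:
            t = np.asarray(self.pseudotime, dtype=float)
            if t.shape != (n_obs,):
                raise ValidationError("pseudotime length mismatch")
            if not np.all(np.isfinite(t)):
                raise ValidationError("pseudotime contains non-finite values")
            if t.size and (t.min() < 0 or t.max() > 1):
                span = t.max() - t.min()
                t = (t - t.min()) / span if span > 0 else np.zeros_like(t)
            self.pseudotime = t

    # -- convenience ------------------------------------------------------

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "OmicsDataset":
        def _c(x):
            return None if x is None else x.copy()

        return OmicsDataset(
            matrix=self.matrix.copy(),
            gene_ids=list(self.gene_ids),
            obs_ids=list(self.obs_ids),
            spliced=_c(self.spliced),
            unspliced=_c(self.unspliced),
            coords=_c(self.coords),
            labels=_c(self.labels),
            pseudotime=_c(self.pseudotime),
            raw=_c(self.raw),
        )

    def subset_genes(self, index: Sequence[int]) -> "OmicsDataset":
        """Return a dataset restricted to the given gene positions (order kept)."""
        index = np.asarray(index, dtype=int)

        def _s(x):
            return None if x is None else x[:, index]

        return OmicsDataset(
            matrix=self.matrix[:, index],
            gene_ids=[self.gene_ids[i] for i in index],
            obs_ids=list(self.obs_ids),
            spliced=_s(self.spliced),
            unspliced=_s(self.unspliced),
            coords=None if self.coords is None else self.coords.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            pseudotime=None if self.pseudotime is None else self.pseudotime.copy(),
            raw=_s(self.raw),
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.matrix.copy(),
            obs=pd.DataFrame(index=pd.Index(self.obs_ids, name="obs_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        if self.spliced is not None:
            adata.layers["spliced"] = self.spliced.copy()
        if self.unspliced is not None:
            adata.layers["unspliced"] = self.unspliced.copy()
        if self.raw is not None:
            adata.layers["raw"] = self.raw.copy()
        if self.coords is not None:
            adata.obsm["spatial"] = self.coords.copy()
        if self.labels is not None:
            adata.obs["cell_type"] = pd.Categorical(self.labels)
        if self.pseudotime is not None:
            adata.obs["pseudotime"] = self.pseudotime.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "OmicsDataset":
        labels = None
        if "cell_type" in adata.obs:
            labels = np.asarray(adata.obs["cell_type"].astype(str))
        pseudotime = None
        if "pseudotime" in adata.obs:
            pseudotime = np.asarray(adata.obs["pseudotime"], dtype=float)
        coords = None
        if "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"], dtype=float)
        return cls(
            matrix=adata.X.copy(),
            gene_ids=list(map(str, adata.var_names)),
            obs_ids=list(map(str, adata.obs_names)),
            spliced=adata.layers.get("spliced"),
            unspliced=adata.layers.get("unspliced"),
            raw=adata.layers.get("raw"),
            coords=coords,
            labels=labels,
            pseudotime=pseudotime,
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


@dataclass(frozen=True)
class GeneIntersection:
    """Shared gene panel between a reference and a spatial dataset.

    ``genes`` is the lexicographically sorted intersection; ``ref_index`` and
    ``spatial_index`` are the matching column positions in each dataset.
    """

    genes: list[str]
    ref_index: np.ndarray
    spatial_index: np.ndarray

    def __post_init__(self):
        if not (len(self.genes) == len(self.ref_index) == len(self.spatial_index)):
            raise ValidationError("gene intersection fields must share a length")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dataset(path, format_hint: Optional[str] = None) -> OmicsDataset:
    """Read an :class:`OmicsDataset` from h5ad, an MTX directory or a CSV matrix.

    The format is inferred from the path (``.h5ad`` file, directory, ``.csv``)
    unless ``format_hint`` in ``{"h5ad", "mtx_dir", "csv"}`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    fmt = format_hint or _infer_format(path)
    if fmt == "h5ad":
        return _read_h5ad(path)
    if fmt == "mtx_dir":
        return _read_mtx_dir(path)
    if fmt == "csv":
        return _read_csv(path)
    raise FormatError(f"unsupported format {fmt!r}")


def write_dataset(ds: OmicsDataset, path, format: Optional[str] = None) -> None:
    """Write ``ds`` so that :func:`read_dataset` round-trips it.

    Integer counts round-trip bit-exactly; reals to relative 1e-12 (float64
    is stored unchanged in every format, CSV uses 17 significant digits).
    """
    path = Path(path)
    fmt = format or _infer_format(path, for_write=True)
    if fmt == "h5ad":
        ds.to_anndata().write_h5ad(path)
    elif fmt == "mtx_dir":
        _write_mtx_dir(ds, path)
    elif fmt == "csv":
        _write_csv(ds, path)
    else:
        raise FormatError(f"unsupported format {fmt!r}")


def _infer_format(path: Path, for_write: bool = False) -> str:
    if path.suffix == ".h5ad":
        return "h5ad"
    if path.suffix == ".csv":
        return "csv"
    if path.is_dir() or (for_write and not path.suffix):
        return "mtx_dir"
    raise FormatError(
        f"cannot infer format of {path}; pass format_hint h5ad/mtx_dir/csv"
    )


def _read_h5ad(path: Path) -> OmicsDataset:
    import anndata as ad

    try:
        adata = ad.read_h5ad(path)
    except Exception as exc:  # pragma: no cover - message depends on h5py
        raise FormatError(f"could not read h5ad file {path}: {exc}") from exc
    return OmicsDataset.from_anndata(adata)


def _read_csv(path: Path) -> OmicsDataset:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"could not parse CSV {path}: {exc}") from exc
    mat = df.to_numpy(dtype=float)
    return OmicsDataset(
        matrix=_maybe_sparsify(mat),
        gene_ids=list(map(str, df.columns)),
        obs_ids=list(map(str, df.index)),
    )


def _write_csv(ds: OmicsDataset, path: Path) -> None:
    df = pd.DataFrame(_dense(ds.matrix), index=ds.obs_ids, columns=ds.gene_ids)
    df.to_csv(path, float_format="%.17g")


_MTX_GENES = ("genes.tsv", "features.tsv")
_MTX_BARCODES = "barcodes.tsv"


def _read_mtx_dir(path: Path) -> OmicsDataset:
    from scipy.io import mmread

    matrix_file = path / "matrix.mtx"
    if not matrix_file.exists():
        raise FormatError(f"missing matrix file: {matrix_file}")
    gene_file = next((path / g for g in _MTX_GENES if (path / g).exists()), None)
    if gene_file is None:
        raise FormatError(f"missing gene annotation file: {path / _MTX_GENES[0]}")
    barcode_file = path / _MTX_BARCODES
    if not barcode_file.exists():
        raise FormatError(f"missing obs annotation file: {barcode_file}")

    matrix = sp.csr_matrix(mmread(matrix_file))  # stored obs x genes
    gene_ids = gene_file.read_text().splitlines()
    obs_ids = barcode_file.read_text().splitlines()

    layers = {}
    for name in ("spliced", "unspliced"):
        f = path / f"{name}.mtx"
        if f.exists():
            layers[name] = sp.csr_matrix(mmread(f))
    coords = None
    if (path / "coords.csv").exists():
        cdf = pd.read_csv(path / "coords.csv", index_col=0)
        coords = cdf.loc[obs_ids, ["x", "y"]].to_numpy(dtype=float)
    labels = pseudotime = None
    if (path / "obs.csv").exists():
        odf = pd.read_csv(path / "obs.csv", index_col=0)
        odf.index = odf.index.map(str)
        odf = odf.loc[obs_ids]
        if "cell_type" in odf:
            labels = odf["cell_type"].to_numpy(dtype=object)
        if "pseudotime" in odf:
            pseudotime = odf["pseudotime"].to_numpy(dtype=float)
    return OmicsDataset(
        matrix=_maybe_sparsify(matrix),
        gene_ids=gene_ids,
        obs_ids=obs_ids,
        spliced=layers.get("spliced"),
        unspliced=layers.get("unspliced"),
        coords=coords,
        labels=labels,
        pseudotime=pseudotime,
    )


def _write_mtx_dir(ds: OmicsDataset, path: Path) -> None:
    from scipy.io import mmwrite

    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(ds.matrix))
    (path / "genes.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    (path / _MTX_BARCODES).write_text("\n".join(ds.obs_ids) + "\n")
    for name in ("spliced", "unspliced"):
        layer = getattr(ds, name)
        if layer is not None:
            mmwrite(str(path / f"{name}.mtx"), sp.coo_matrix(layer))
    if ds.coords is not None:
        pd.DataFrame(ds.coords, index=ds.obs_ids, columns=["x", "y"]).to_csv(
            path / "coords.csv", float_format="%.17g"
        )
    if ds.labels is not None or ds.pseudotime is not None:
        odf = pd.DataFrame(index=ds.obs_ids)
        if ds.labels is not None:
            odf["cell_type"] = ds.labels
        if ds.pseudotime is not None:
            odf["pseudotime"] = ds.pseudotime
        odf.to_csv(path / "obs.csv", float_format="%.17g")


# ---------------------------------------------------------------------------
# gene intersection and normalization
# ---------------------------------------------------------------------------

def intersect_genes(ref: OmicsDataset, spatial: OmicsDataset) -> GeneIntersection:
    """Shared gene panel between the two modalities, sorted lexicographically.

    Matching is exact-string after whitespace stripping; no alias resolution.
    """
    if ref.n_genes == 0 or spatial.n_genes == 0:
        raise ValidationError("cannot intersect genes of an empty dataset")
    ref_pos = {g: i for i, g in enumerate(ref.gene_ids)}
    sp_pos = {g: i for i, g in enumerate(spatial.gene_ids)}
    shared = sorted(set(ref_pos) & set(sp_pos))
    if not shared:
        raise ValidationError(
            "no shared genes between datasets; harmonize gene identifiers "
            "(same nomenclature/species, strip version suffixes)"
        )
    return GeneIntersection(
        genes=shared,
        ref_index=np.array([ref_pos[g] for g in shared], dtype=int),
        spatial_index=np.array([sp_pos[g] for g in shared], dtype=int),
    )


def normalize_expression(
    ds: OmicsDataset,
    target_sum: Optional[float] = None,
    log1p: bool = True,
) -> OmicsDataset:
    """Library-size normalize each observation, optionally log1p transform X.

    Every observation row of X is scaled to ``target_sum`` total counts
    (default: the median total over non-empty rows).  The spliced and
    unspliced layers are scaled by the same per-observation factor, so
    spliced:unspliced ratios are preserved exactly; log1p is applied to X
    only.  The original X is kept in ``raw``.  All-zero rows are left
    unscaled with a warning.
    """
    X = ds.matrix
    totals = np.asarray(X.sum(axis=1)).ravel()
    nonzero = totals > 0
    if target_sum is None:
        if not np.any(nonzero):
            raise ValidationError("all observations have zero total counts")
        target_sum = float(np.median(totals[nonzero]))
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    if not np.all(nonzero):
        warnings.warn(
            f"{int((~nonzero).sum())} all-zero observation(s) left unscaled",
            stacklevel=2,
        )
    factors = np.ones_like(totals)
    factors[nonzero] = target_sum / totals[nonzero]

    def _scale(m):
        if m is None:
            return None
        if sp.issparse(m):
            return sp.diags(factors) @ m.tocsr()
        return m * factors[:, None]

    Xn = _scale(X)
    if log1p:
        if sp.issparse(Xn):
            Xn = Xn.copy()
            Xn.data = np.log1p(Xn.data)
        else:
            Xn = np.log1p(Xn)
    out = ds.copy()
    out.matrix = Xn
    out.raw = X.copy()
    out.spliced = _scale(ds.spliced)
    out.unspliced = _scale(ds.unspliced)
    return out
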