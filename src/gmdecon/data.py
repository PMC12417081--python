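"""Expression-matrix containers, readers/writers, and the shared preprocessing pipeline.

Both the scRNA-seq reference and the spatial (SRT) sample are carried as
:class:`CountMatrix` (units x genes raw counts).  Before entering the model,
both are restricted to highly variable genes shared between the two platforms
and pushed through the same pipeline: library-size normalization, log1p, and
gene-wise z-scoring.  Each dataset is standardized on its own statistics; the
residual platform shift is left to the adversarial domain-adaptation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


# --------------------------------------------------------------------- types
@dataclass
class CountMatrix:
    """Units x genes non-negative expression matrix with identifiers."""

    values: np.ndarray
    unit_ids: List[str]
    gene_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (units x genes)")
        if self.values.shape != (len(self.unit_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.unit_ids)} unit ids x {len(self.gene_ids)} gene ids"
            )
        if np.any(self.values < 0):
            raise ValueError("negative entry in count matrix")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def g(self) -> int:
        """Number of genes (feature width of downstream node features)."""
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return CountMatrix(self.values[:, cols], list(self.unit_ids), list(genes))


@dataclass
class FeatureMatrix:
    """Units x genes real-valued matrix (e.g. z-scored features); negatives allowed."""

    values: np.ndarray
    unit_ids: List[str]
    gene_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unit_ids), len(self.gene_ids)):
            raise ValueError("values dimensions must match id lists")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def g(self) -> int:
        return self.values.shape[1]


@dataclass
class CellAnnotation:
    """Per-unit cell-type labels over a fixed vocabulary."""

    unit_ids: List[str]
    cell_type: List[str]
    types: List[str] = field(default=None)  # vocabulary, in a fixed order

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.cell_type = [str(t) for t in self.cell_type]
        if len(self.unit_ids) != len(self.cell_type):
            raise ValueError("one label per unit required")
        if self.types is None:
            self.types = sorted(set(self.cell_type))
        unknown = set(self.cell_type) - set(self.types)
        if unknown:
            raise ValueError(f"labels outside vocabulary: {sorted(unknown)[:5]}")
        if len(self.types) < 1:
            raise ValueError("at least one cell type required")

    @property
    def CT(self) -> int:
        return len(self.types)

    def type_indices(self) -> np.ndarray:
        lut = {t: i for i, t in enumerate(self.types)}
        return np.array([lut[t] for t in self.cell_type], dtype=int)


@dataclass
class SpotCoordinates:
    """2-D spot positions in platform pixel units."""

    unit_ids: List[str]
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.unit_ids), 2):
            raise ValueError("xy must be (n_units, 2)")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite coordinate")


# ------------------------------------------------------------------- readers
def load_expression(
    path: Union[str, Path],
    layout: str = "dense",
    genes_path: Optional[Union[str, Path]] = None,
    units_path: Optional[Union[str, Path]] = None,
) -> CountMatrix:
    """Read an expression matrix.

    ``dense``: delimited table (TSV/CSV by extension), first column unit ids,
    header gene ids.  ``sparse``: Matrix Market triplet file (units x genes)
    with sidecar gene/unit id lists (defaults: ``<stem>_genes.tsv`` and
    ``<stem>_barcodes.tsv`` next to the matrix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pandas names the offending line
            raise ValueError(f"malformed expression table {path}: {exc}") from exc
        return CountMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))
    if layout == "sparse":
        genes_path = Path(genes_path) if genes_path else path.with_name(path.stem + "_genes.tsv")
        units_path = Path(units_path) if units_path else path.with_name(path.stem + "_barcodes.tsv")
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        units = pd.read_csv(units_path, sep="\t", header=None)[0].astype(str).tolist()
        dense = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
        return CountMatrix(dense, units, genes)
    raise ValueError(f"unknown layout: {layout!r}")


def save_expression(m: CountMatrix, path: Union[str, Path], layout: str = "dense") -> None:
    path = Path(path)
    if layout == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame(m.values, index=m.unit_ids, columns=m.gene_ids).to_csv(path, sep=sep)
    elif layout == "sparse":
        scipy.io.mmwrite(str(path), sp.coo_matrix(m.values))
        pd.Series(m.gene_ids).to_csv(path.with_name(path.stem + "_genes.tsv"),
                                     sep="\t", header=False, index=False)
        pd.Series(m.unit_ids).to_csv(path.with_name(path.stem + "_barcodes.tsv"),
                                     sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown layout: {layout!r}")


def load_labels(path: Union[str, Path]) -> CellAnnotation:
    """One- or two-column table: unit id, cell type (single column = types in file order)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 1:
        raise ValueError("label table must have unit-id and cell-type columns")
    return CellAnnotation(df[0].tolist(), df[1].tolist())


def load_coordinates(path: Union[str, Path]) -> SpotCoordinates:
    """Three-column table: unit id, x, y."""
    df = pd.read_csv(path, sep="\t", header=None)
    return SpotCoordinates(df[0].astype(str).tolist(), df[[1, 2]].to_numpy(float))


# ------------------------------------------------------------- preprocessing
def _values(m) -> np.ndarray:
    return m.values if isinstance(m, (CountMatrix, FeatureMatrix)) else np.asarray(m, dtype=float)


def _wrap_like(m, values: np.ndarray, signed: bool = False):
    if isinstance(m, (CountMatrix, FeatureMatrix)):
        cls = FeatureMatrix if signed or isinstance(m, FeatureMatrix) else CountMatrix
        return cls(values, list(m.unit_ids), list(m.gene_ids))
    return values


def normalize_library_size(m, target: Union[float, str] = "median"):
    """Scale each unit so its total equals ``target``; all-zero rows stay zero."""
    x = _values(m).astype(float)
    totals = x.sum(axis=1)
    nonzero = totals > 0
    if not np.any(nonzero):
        raise ValueError("all rows have zero total count")
    if target == "median":
        target_value = float(np.median(totals[nonzero]))
    else:
        target_value = float(target)
        if target_value <= 0:
            raise ValueError("target must be positive")
    out = x.copy()
    out[nonzero] = x[nonzero] * (target_value / totals[nonzero])[:, None]
    return _wrap_like(m, out)


def log1p_transform(m):
    """Elementwise natural log of (1 + value)."""
    x = _values(m)
    if np.any(x < 0):
        raise ValueError("negative entry passed to log1p")
    return _wrap_like(m, np.log1p(x))


def zscore_genes(m):
    """Gene-wise standardization (population s.d.); constant genes map to zero."""
    x = _values(m).astype(float)
    if x.shape[0] < 2:
        raise ValueError("z-scoring needs at least two units")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population (n denominator)
    out = np.zeros_like(x)
    # a column is constant when its range is exactly zero (sd can pick up
    # float noise of order 1e-16 on constant columns)
    ok = (x.max(axis=0) - x.min(axis=0)) > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return _wrap_like(m, out, signed=True)


def preprocess(m, target: Union[float, str] = "median"):
    """The full shared pipeline: library-size normalize -> log1p -> gene z-score."""
    return zscore_genes(log1p_transform(normalize_library_size(m, target)))


# ----------------------------------------------------------------------- HVG
def _hvg_mask(counts: np.ndarray, gene_ids: Sequence[str],
              min_mean: float, max_mean: float, min_disp: float, n_bins: int) -> np.ndarray:
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=np.asarray(counts, dtype=np.float32))
    adata.var_names = list(gene_ids)
    sc.pp.normalize_total(adata)
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, flavor="seurat", min_mean=min_mean,
                                max_mean=max_mean, min_disp=min_disp, n_bins=n_bins)
    return adata.var["highly_variable"].to_numpy()


def select_shared_hvgs(
    ref: CountMatrix,
    srt: CountMatrix,
    min_genes: int = 100,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = 0.5,
    n_bins: int = 20,
) -> List[str]:
    """Highly variable genes computed per dataset on the shared genes.

    Each dataset is restricted to the gene intersection, HVGs are selected
    independently by the dispersion-vs-mean binning criterion, and the
    intersection of the two HVG sets is returned.  If that has fewer than
    ``min_genes`` genes the union is used, then all shared genes.
    """
    shared = [g for g in ref.gene_ids if g in set(srt.gene_ids)]
    if not shared:
        raise ValueError("reference and SRT gene sets are disjoint")
    ref_s = ref.subset_genes(shared)
    srt_s = srt.subset_genes(shared)
    kw = dict(min_mean=min_mean, max_mean=max_mean, min_disp=min_disp, n_bins=n_bins)
    mask_ref = _hvg_mask(ref_s.values, shared, **kw)
    mask_srt = _hvg_mask(srt_s.values, shared, **kw)
    inter = [g for g, a, b in zip(shared, mask_ref, mask_srt) if a and b]
    if len(inter) >= min_genes:
        return inter
    union = [g for g, a, b in zip(shared, mask_ref, mask_srt) if a or b]
    if len(union) >= min_genes:
        return union
    return shared
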