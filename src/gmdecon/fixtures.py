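"""Synthetic reference and tissue generators with known ground truth.

The generator emulates the statistical structure the deconvolution problem
presents in practice: a scRNA-seq reference whose cell types differ by a
disjoint set of marker genes (negative-binomial counts, so overdispersion and
platform shift are separable), and a spatial sample laid out on a rectangular
lattice partitioned into contiguous horizontal band domains — mimicking
cortical layers — each with its own skewed type mixture, so most spots carry a
dominant cell type.  SRT expression is built by resampling reference cells and
summing their raw counts, then applying a gene-wise multiplicative log-normal
platform factor shared across spots, which is the platform effect the
adversarial domain loss is meant to absorb.

It does not emulate platform chemistry (dropout curves, segmentation error,
spot-size heterogeneity beyond the Poisson cell count), so passing recovery
tests here demonstrates correctness of the machinery, not real-data accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .data import CellAnnotation, CountMatrix, SpotCoordinates


@dataclass
class FixtureSpec:
    n_types: int = 5
    n_genes: int = 200
    markers_per_type: int = 8
    marker_fold: float = 8.0
    n_ref_cells: int = 1000
    grid_shape: Tuple[int, int] = (20, 20)   # (n_rows, n_cols) of spots
    spot_spacing: float = 100.0              # pixels between lattice spots
    n_domains: int = 4
    mixtures: Optional[np.ndarray] = None    # (n_domains, n_types) rows on simplex
    dominant_weight: float = 0.7             # used when mixtures is None
    mean_cells_per_spot: float = 5.0
    baseline_mean: float = 0.5
    dispersion: float = 0.3                  # NB: var = mu + dispersion * mu^2
    platform_sigma: float = 0.3              # log-normal gene-wise platform shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("marker genes exceed the gene panel")
        if self.n_domains > self.grid_shape[0] * self.grid_shape[1]:
            raise ValueError("more domains than grid cells")
        if self.mixtures is not None:
            self.mixtures = np.asarray(self.mixtures, dtype=float)
            if self.mixtures.shape != (self.n_domains, self.n_types):
                raise ValueError("mixtures must be (n_domains, n_types)")
            if not np.allclose(self.mixtures.sum(axis=1), 1.0):
                raise ValueError("mixture rows must sum to 1")


@dataclass
class SimulatedTissue:
    counts: CountMatrix
    coords: SpotCoordinates
    proportions: np.ndarray
    type_names: List[str]
    domain_labels: np.ndarray
    cells_per_spot: np.ndarray
    platform_factor: np.ndarray


def default_mixtures(spec: FixtureSpec) -> np.ndarray:
    """One dominant type per domain (round-robin), remainder spread uniformly."""
    w = spec.dominant_weight
    mix = np.full((spec.n_domains, spec.n_types), (1.0 - w) / (spec.n_types - 1))
    for d in range(spec.n_domains):
        mix[d, d % spec.n_types] = w
    return mix


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson when dispersion=0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def type_mean_matrix(spec: FixtureSpec) -> np.ndarray:
    """(n_types, n_genes) expected counts: baseline, markers multiplied by the fold."""
    means = np.full((spec.n_types, spec.n_genes), spec.baseline_mean)
    for t in range(spec.n_types):
        lo = t * spec.markers_per_type
        means[t, lo:lo + spec.markers_per_type] *= spec.marker_fold
    return means


def make_reference(spec: FixtureSpec) -> Tuple[CountMatrix, CellAnnotation]:
    """Reference cells with disjoint marker blocks, negative-binomial counts."""
    rng = np.random.default_rng(spec.seed)
    means = type_mean_matrix(spec)
    type_names = [f"type_{t}" for t in range(spec.n_types)]
    cell_types = np.arange(spec.n_ref_cells) % spec.n_types  # balanced assignment
    counts = np.zeros((spec.n_ref_cells, spec.n_genes), dtype=np.int64)
    for i, t in enumerate(cell_types):
        counts[i] = _nb_draw(rng, means[t], spec.dispersion)
    ids = [f"cell_{i}" for i in range(spec.n_ref_cells)]
    genes = [f"gene_{j}" for j in range(spec.n_genes)]
    ann = CellAnnotation(ids, [type_names[t] for t in cell_types], types=type_names)
    return CountMatrix(counts, ids, genes), ann


def make_tissue(
    spec: FixtureSpec,
    ref: CountMatrix,
    labels: CellAnnotation,
) -> SimulatedTissue:
    """Spots on a lattice of horizontal band domains, built from resampled reference cells."""
    rng = np.random.default_rng(spec.seed + 1)
    n_rows, n_cols = spec.grid_shape
    mixtures = spec.mixtures if spec.mixtures is not None else default_mixtures(spec)
    type_idx = labels.type_indices()
    cells_by_type = [np.flatnonzero(type_idx == t) for t in range(labels.CT)]
    for t, pool in enumerate(cells_by_type):
        if pool.size == 0:
            raise ValueError(f"reference has no cells of type {labels.types[t]}")

    n_spots = n_rows * n_cols
    counts = np.zeros((n_spots, ref.g), dtype=float)
    props = np.zeros((n_spots, labels.CT), dtype=float)
    domains = np.zeros(n_spots, dtype=int)
    n_cells = np.zeros(n_spots, dtype=int)
    xy = np.zeros((n_spots, 2), dtype=float)

    i = 0
    for r in range(n_rows):
        domain = min(spec.n_domains - 1, r * spec.n_domains // n_rows)
        for c in range(n_cols):
            xy[i] = (c * spec.spot_spacing, r * spec.spot_spacing)
            nc = int(rng.poisson(spec.mean_cells_per_spot)) + 1
            spot_types = rng.choice(labels.CT, size=nc, p=mixtures[domain])
            for t in spot_types:
                pool = cells_by_type[t]
                counts[i] += ref.values[pool[rng.integers(0, pool.size)]]
            realized = np.bincount(spot_types, minlength=labels.CT)
            props[i] = realized / nc
            domains[i] = domain
            n_cells[i] = nc
            i += 1

    factor = np.exp(rng.normal(0.0, spec.platform_sigma, size=ref.g)) \
        if spec.platform_sigma > 0 else np.ones(ref.g)
    counts *= factor[None, :]

    ids = [f"srt_{i}" for i in range(n_spots)]
    return SimulatedTissue(
        counts=CountMatrix(counts, ids, list(ref.gene_ids)),
        coords=SpotCoordinates(ids, xy),
        proportions=props,
        type_names=list(labels.types),
        domain_labels=domains,
        cells_per_spot=n_cells,
        platform_factor=factor,
    )


def make_fixture(spec: Optional[FixtureSpec] = None):
    """Convenience: reference + annotation + tissue in one call."""
    spec = spec or FixtureSpec()
    ref, ann = make_reference(spec)
    tissue = make_tissue(spec, ref, ann)
    return ref, ann, tissue
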