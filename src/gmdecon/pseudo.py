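"""Pseudo-spot sampling from an annotated scRNA-seq reference.

A pseudo-spot mimics a multi-cell capture spot: the number of member cells is
nc = Poisson(lambda) + 1 (lambda defaults to 5, so spots hold ~1-16 cells), the
number of member cell types is nk ~ U{1, ..., NK} (NK defaults to 4), the nk
types are chosen uniformly from the reference's type vocabulary — deliberately
NOT from the reference's empirical type frequencies, since the tissue's true
composition is unknown — and each member cell is drawn uniformly (with
replacement) within its type.  Expression is the sum of the members' raw
counts; the label is the realized type-frequency vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .data import CellAnnotation, CountMatrix


@dataclass
class PseudoSpotBatch:
    """A batch of sampled pseudo-spots with known proportions."""

    counts: CountMatrix            # spots x genes raw-count sums
    proportions: np.ndarray        # (n_spots, CT) realized proportions
    type_names: List[str]
    nc: np.ndarray                 # cells per spot
    nk: np.ndarray                 # types drawn per spot
    cell_indices: List[np.ndarray]  # reference cell indices per spot
    seed: int
    lam: float
    NK: int

    def __post_init__(self) -> None:
        if np.any(self.nc < 1):
            raise ValueError("nc must be >= 1")
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")

    @property
    def n_spots(self) -> int:
        return self.counts.n_units


def sample_spot_size(rng: np.random.Generator, lam: float) -> int:
    """Number of cells in a pseudo-spot: Poisson(lam) + 1."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return int(rng.poisson(lam)) + 1


def sample_spot_size_normal(rng: np.random.Generator, mean: float) -> int:
    """Alternative sampler: round(N(mean, 1)), floored at 1 (mean-matched to Poisson+1)."""
    return max(1, int(round(rng.normal(mean, 1.0))))


def sample_num_types(rng: np.random.Generator, NK: int, available: int) -> int:
    """Number of distinct types in a pseudo-spot: uniform on [1, min(NK, available)]."""
    if NK < 1 or available < 1:
        raise ValueError("NK and available must be >= 1")
    hi = min(NK, available)
    return int(rng.integers(1, hi + 1))


def sample_num_types_normal(rng: np.random.Generator, NK: int, available: int) -> int:
    """Alternative sampler: round(N(mean of U{1..hi}, 1)) clamped to [1, hi]."""
    hi = min(NK, available)
    val = int(round(rng.normal((1 + hi) / 2.0, 1.0)))
    return min(hi, max(1, val))


def generate_pseudo_spots(
    ref: CountMatrix,
    labels: CellAnnotation,
    n_spots: int,
    lam: float = 5.0,
    NK: int = 4,
    seed: int = 0,
    size_sampler: str = "poisson",
) -> PseudoSpotBatch:
    """Sample ``n_spots`` pseudo-spots from the reference.

    ``size_sampler`` switches nc/nk between the default Poisson/uniform draws
    and the mean-matched normal alternative.
    """
    if n_spots <= 0:
        raise ValueError("n_spots must be positive")
    if ref.unit_ids != labels.unit_ids:
        raise ValueError("reference matrix and labels must share unit ids and order")
    if size_sampler not in ("poisson", "normal"):
        raise ValueError(f"unknown size_sampler: {size_sampler!r}")

    rng = np.random.default_rng(seed)
    type_names = list(labels.types)
    CT = len(type_names)
    type_idx = labels.type_indices()
    cells_by_type = [np.flatnonzero(type_idx == t) for t in range(CT)]
    present = [t for t in range(CT) if cells_by_type[t].size > 0]
    if not present:
        raise ValueError("reference has no annotated cells")

    values = ref.values
    expr = np.zeros((n_spots, ref.g), dtype=float)
    props = np.zeros((n_spots, CT), dtype=float)
    nc_arr = np.zeros(n_spots, dtype=int)
    nk_arr = np.zeros(n_spots, dtype=int)
    cell_indices: List[np.ndarray] = []
    present_arr = np.asarray(present)

    for i in range(n_spots):
        if size_sampler == "poisson":
            nc = sample_spot_size(rng, lam)
            nk = sample_num_types(rng, NK, len(present))
        else:
            nc = sample_spot_size_normal(rng, lam + 1.0)
            nk = sample_num_types_normal(rng, NK, len(present))
        chosen_types = rng.choice(present_arr, size=nk, replace=False)
        which = rng.integers(0, nk, size=nc)           # type slot per member cell
        members = np.empty(nc, dtype=int)
        for j, slot in enumerate(which):
            pool = cells_by_type[chosen_types[slot]]
            members[j] = pool[rng.integers(0, pool.size)]
        expr[i] = values[members].sum(axis=0)
        realized = np.bincount(type_idx[members], minlength=CT)
        props[i] = realized / nc
        nc_arr[i] = nc
        nk_arr[i] = nk
        cell_indices.append(members)

    ids = [f"pseudo_{i}" for i in range(n_spots)]
    return PseudoSpotBatch(
        counts=CountMatrix(expr, ids, list(ref.gene_ids)),
        proportions=props,
        type_names=type_names,
        nc=nc_arr,
        nk=nk_arr,
        cell_indices=cell_indices,
        seed=seed,
        lam=lam,
        NK=NK,
    )
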