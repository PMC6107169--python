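"""Dimension-agnostic HDF5 chunk-shape planning.

A chunked HDF5 dataset is tiled by a repeating chunk shape fixed at
creation time, and the library allocates the minimum integer number of
chunks covering the dataset, so chunk shapes that are far from a divisor
of the dataset extent waste allocated space at the edges.  The planner
here chooses a chunk shape from the dataset dimensions and a single
target chunk size in bytes: for a candidate per-dimension target extent
``T`` it takes ``x_i = ceil(D_i / T)`` chunks in dimension *i* and the
minimal extent ``C_i = ceil(D_i / x_i)`` that still covers the dataset
with ``x_i`` chunks, which minimises edge waste for that chunk count.
The planner searches for the largest ``T`` whose chunk stays within the
byte budget (or spans the whole dataset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "DatasetShape",
    "ChunkShape",
    "PlannerConfig",
    "ChunkGrid",
    "calculate_chunk_dims",
    "plan_chunks",
    "chunk_grid",
    "default_chunk",
]

#: Default target chunk size in bytes (128 KiB). 1 MiB is recommended
#: for large problems, matching common parallel-filesystem stripe sizes.
DEFAULT_TARGET_BYTES = 128 * 2**10


@dataclass(frozen=True)
class DatasetShape:
    """Extents of a multidimensional dataset plus bytes per element.

    For the 3-D cardiac-simulation output handled elsewhere in this
    package, ``dims`` is (time, nodes, variables).
    """

    dims: tuple[int, ...]
    element_size: int = 8

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) < 1:
            raise ValueError("dataset must have at least one dimension")
        if any(d < 1 for d in dims):
            raise ValueError(f"dataset dims must be positive, got {dims}")
        if self.element_size < 1:
            raise ValueError("element_size must be a positive integer")

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def n_elements(self) -> int:
        return math.prod(self.dims)

    @property
    def nbytes(self) -> int:
        return self.n_elements * self.element_size


@dataclass(frozen=True)
class ChunkShape:
    """A chunk extent vector with its byte size and spans-dataset flag."""

    dims: tuple[int, ...]
    byte_size: int
    spans: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if any(c < 1 for c in self.dims):
            raise ValueError(f"chunk dims must be positive, got {self.dims}")

    @property
    def n_elements(self) -> int:
        return math.prod(self.dims)


@dataclass(frozen=True)
class PlannerConfig:
    """Planner tuning: the target chunk size in bytes."""

    target_bytes: int = DEFAULT_TARGET_BYTES

    def __post_init__(self) -> None:
        if self.target_bytes < 1:
            raise ValueError("target_bytes must be a positive integer")


@dataclass(frozen=True)
class ChunkGrid:
    """How a chunk shape tiles a dataset, with edge-waste accounting."""

    counts: tuple[int, ...]
    total_chunks: int
    allocated_elements: int
    waste_fraction: float


def calculate_chunk_dims(dataset: DatasetShape, target_elems: int) -> ChunkShape:
    """Chunk dims for a per-dimension target extent of ``target_elems``.

    In each dimension the minimum number of target-sized chunks spanning
    the dataset is ``x_i = ceil(D_i / target_elems)``; the chunk extent
    is then the minimal ``C_i = ceil(D_i / x_i)`` covering the dataset
    with that many chunks.  ``spans`` is true iff a single chunk covers
    the whole dataset (``x_i == 1`` everywhere).
    """
    if target_elems < 1:
        raise ValueError("target_elems must be a positive integer")
    byte_size = dataset.element_size
    dims = []
    spans = True
    for d in dataset.dims:
        x = -(-d // target_elems)
        c = -(-d // x)
        dims.append(c)
        byte_size *= c
        spans = spans and x == 1
    return ChunkShape(dims=tuple(dims), byte_size=byte_size, spans=spans)


def _plan_incremental(dataset: DatasetShape, target_bytes: int) -> ChunkShape:
    """Reference search: grow T by one until the byte budget is reached."""
    t = 0
    chunk = None
    while chunk is None or (chunk.byte_size < target_bytes and not chunk.spans):
        t += 1
        chunk = calculate_chunk_dims(dataset, t)
    if chunk.byte_size > target_bytes:
        t -= 1
        chunk = calculate_chunk_dims(dataset, t)
    return chunk


def _plan_bisect(dataset: DatasetShape, target_bytes: int) -> ChunkShape:
    """Binary-search fast path, equal to the incremental search everywhere.

    ``byte_size`` is non-decreasing in T and ``spans`` is monotone (it
    holds exactly when T >= max(D)), so the predicate "byte_size >=
    target or spans" is monotone in T and the smallest T satisfying it
    can be bisected; the final pull-back below the budget then matches
    the incremental loop.
    """
    lo, hi = 1, max(dataset.dims)

    def stop(t: int) -> bool:
        c = calculate_chunk_dims(dataset, t)
        return c.byte_size >= target_bytes or c.spans

    while lo < hi:
        mid = (lo + hi) // 2
        if stop(mid):
            hi = mid
        else:
            lo = mid + 1
    chunk = calculate_chunk_dims(dataset, lo)
    if chunk.byte_size > target_bytes:
        chunk = calculate_chunk_dims(dataset, lo - 1)
    return chunk


def plan_chunks(
    dataset: DatasetShape,
    config: PlannerConfig | None = None,
    *,
    method: str = "bisect",
) -> ChunkShape:
    """Plan a chunk shape within ``config.target_bytes``.

    Returns the chunk for the largest target extent T such that the
    chunk either spans the dataset or fits the byte budget.

    Parameters
    ----------
    dataset:
        Dataset extents and element size.
    config:
        Target chunk size in bytes; defaults to 128 KiB.
    method:
        ``"bisect"`` (default) or ``"incremental"``; both return the
        same chunk, the incremental form is the reference definition.
    """
    config = config or PlannerConfig()
    if config.target_bytes < dataset.element_size:
        raise ValueError(
            f"target_bytes={config.target_bytes} is smaller than one "
            f"element ({dataset.element_size} B); no chunk can satisfy it"
        )
    if method == "incremental":
        return _plan_incremental(dataset, config.target_bytes)
    if method == "bisect":
        return _plan_bisect(dataset, config.target_bytes)
    raise ValueError(f"unknown method {method!r}")


def chunk_grid(dataset: DatasetShape, chunk: ChunkShape) -> ChunkGrid:
    """Tile ``dataset`` with ``chunk`` and account for edge waste."""
    if len(chunk.dims) != dataset.ndim:
        raise ValueError("chunk and dataset dimensionality differ")
    if any(c > d for c, d in zip(chunk.dims, dataset.dims)):
        raise ValueError(
            f"chunk {chunk.dims} exceeds dataset {dataset.dims} in some dimension"
        )
    counts = tuple(-(-d // c) for d, c in zip(dataset.dims, chunk.dims))
    allocated = math.prod(x * c for x, c in zip(counts, chunk.dims))
    waste = 1.0 - dataset.n_elements / allocated
    return ChunkGrid(
        counts=counts,
        total_chunks=math.prod(counts),
        allocated_elements=allocated,
        waste_fraction=waste,
    )


def default_chunk(dataset: DatasetShape, max_write_bytes: int = 2**31) -> ChunkShape:
    """The conventional time-sliced chunk ``(C_t, D_2, ..., D_N)``.

    The chunk spans every dimension but the first; its time extent is
    capped so one chunk stays within ``max_write_bytes`` (default 2 GiB,
    the signed-32-bit single-write limit of ROMIO/MPI-IO).
    """
    if dataset.ndim < 2:
        raise ValueError("default-style chunks need a dataset of >= 2 dimensions")
    slab_bytes = dataset.element_size * math.prod(dataset.dims[1:])
    if slab_bytes > max_write_bytes:
        raise ValueError(
            f"one time slab is {slab_bytes} B, over the {max_write_bytes} B "
            f"write limit; raise max_write_bytes to at least {slab_bytes}"
        )
    c_t = min(dataset.dims[0], max_write_bytes // slab_bytes)
    dims = (c_t,) + dataset.dims[1:]
    return ChunkShape(
        dims=dims,
        byte_size=dataset.element_size * math.prod(dims),
        spans=dims == dataset.dims,
    )
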