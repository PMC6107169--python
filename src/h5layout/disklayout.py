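"""Analytic model of chunked-dataset serialization and seek cost.

Disk storage is one-dimensional, so a multidimensional dataset must be
serialized to a linear byte address space.  Unchunked HDF5 datasets are
laid out in row-major order; chunked datasets store each chunk as a
contiguous block.  This module models that mapping deterministically and
counts the maximal contiguous byte runs ("segments") a hyperslab access
touches — each extra segment costs a disk seek, which is the mechanism
that makes column-style reads expensive under a row-major layout and
cheap under column-shaped chunks.

Modeling assumptions: chunks are placed in row-major chunk-grid order,
packed sequentially from ``base_offset`` (real HDF5 places chunks in
write order at irregular offsets via a B-tree; a fixed order is needed
for a testable cost model); chunk-index metadata costs are ignored.
Indexing is 0-based half-open internally, with 1-based helpers mirroring
conventional matrix notation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

from .planner import ChunkShape, DatasetShape, chunk_grid

__all__ = [
    "LinearLayout",
    "Hyperslab",
    "SegmentReport",
    "element_offset",
    "element_ordinal",
    "segments_for_selection",
    "process_slab",
    "chunks_touched_by_process",
    "unchunked_layout",
]


@dataclass(frozen=True)
class Hyperslab:
    """A rectangular selection: 0-based inclusive start, per-dim count."""

    start: tuple[int, ...]
    count: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", tuple(int(s) for s in self.start))
        object.__setattr__(self, "count", tuple(int(c) for c in self.count))
        if len(self.start) != len(self.count):
            raise ValueError("start and count lengths differ")
        if any(s < 0 for s in self.start) or any(c < 1 for c in self.count):
            raise ValueError("start must be >= 0 and count >= 1 in every dimension")

    @classmethod
    def from_matrix_notation(
        cls, first: Sequence[int], last: Sequence[int]
    ) -> "Hyperslab":
        """Build from 1-based inclusive corner indices, e.g. (4,3)–(8,3)."""
        start = tuple(f - 1 for f in first)
        count = tuple(l - f + 1 for f, l in zip(first, last))
        return cls(start=start, count=count)

    def validate(self, dataset: DatasetShape) -> None:
        if len(self.start) != dataset.ndim:
            raise ValueError("hyperslab and dataset dimensionality differ")
        for s, c, d in zip(self.start, self.count, dataset.dims):
            if s + c > d:
                raise ValueError(
                    f"selection [{s}, {s + c}) exceeds dataset extent {d}"
                )

    @property
    def n_elements(self) -> int:
        return math.prod(self.count)


@dataclass(frozen=True)
class SegmentReport:
    """Seek-cost summary of one hyperslab access."""

    segments: int
    bytes_read: int
    gap_bytes: int
    chunks_touched: int


@dataclass(frozen=True)
class LinearLayout:
    """Deterministic element → byte-offset mapping for a chunked dataset.

    ``alignment`` > 0 pads every chunk start up to the next multiple of
    that many bytes (the model of aligning chunks to stripe boundaries);
    0 means chunks are packed back to back.
    """

    dataset: DatasetShape
    chunk: ChunkShape
    base_offset: int = 0
    alignment: int = 0

    def __post_init__(self) -> None:
        if len(self.chunk.dims) != self.dataset.ndim:
            raise ValueError("chunk and dataset dimensionality differ")
        if any(c > d for c, d in zip(self.chunk.dims, self.dataset.dims)):
            raise ValueError("chunk exceeds dataset in some dimension")
        if self.base_offset < 0 or self.alignment < 0:
            raise ValueError("base_offset and alignment must be >= 0")

    @property
    def grid_counts(self) -> tuple[int, ...]:
        return chunk_grid(self.dataset, self.chunk).counts

    @property
    def chunk_bytes(self) -> int:
        return self.dataset.element_size * self.chunk.n_elements

    def chunk_start(self, chunk_index: Sequence[int]) -> int:
        """Byte offset at which a chunk (by grid coordinates) starts."""
        counts = self.grid_counts
        rank = _row_major_rank(chunk_index, counts)
        if self.alignment > 0:
            stride = -(-self.chunk_bytes // self.alignment) * self.alignment
            return self.base_offset + rank * stride
        return self.base_offset + rank * self.chunk_bytes

    @property
    def file_bytes(self) -> int:
        """Bytes from ``base_offset`` to the end of the last chunk."""
        n = chunk_grid(self.dataset, self.chunk).total_chunks
        if self.alignment > 0:
            stride = -(-self.chunk_bytes // self.alignment) * self.alignment
            return (n - 1) * stride + self.chunk_bytes
        return n * self.chunk_bytes


def unchunked_layout(dataset: DatasetShape, base_offset: int = 0) -> LinearLayout:
    """Row-major contiguous layout: one chunk spanning the dataset."""
    chunk = ChunkShape(dims=dataset.dims, byte_size=dataset.nbytes, spans=True)
    return LinearLayout(dataset=dataset, chunk=chunk, base_offset=base_offset)


def _row_major_rank(index: Sequence[int], dims: Sequence[int]) -> int:
    rank = 0
    for i, d in zip(index, dims):
        rank = rank * d + i
    return rank


def element_offset(index: Sequence[int], layout: LinearLayout) -> int:
    """Byte offset of one element (0-based multidimensional index)."""
    index = tuple(int(i) for i in index)
    if len(index) != layout.dataset.ndim:
        raise ValueError("index and dataset dimensionality differ")
    if any(i < 0 or i >= d for i, d in zip(index, layout.dataset.dims)):
        raise ValueError(f"index {index} out of range for {layout.dataset.dims}")
    cdims = layout.chunk.dims
    chunk_idx = tuple(i // c for i, c in zip(index, cdims))
    within = tuple(i % c for i, c in zip(index, cdims))
    return layout.chunk_start(chunk_idx) + layout.dataset.element_size * _row_major_rank(
        within, cdims
    )


def element_ordinal(index_1based: Sequence[int], layout: LinearLayout) -> int:
    """1-based linear ordinal of a 1-based matrix index, e.g. (4,3) → 33.

    Mirrors conventional matrix notation for an unchunked layout: the
    ordinal is offset / element_size + 1 relative to ``base_offset``.
    """
    index = tuple(i - 1 for i in index_1based)
    off = element_offset(index, layout) - layout.base_offset
    return off // layout.dataset.element_size + 1


def _chunk_runs(
    layout: LinearLayout,
    chunk_idx: tuple[int, ...],
    sel_start: tuple[int, ...],
    sel_count: tuple[int, ...],
) -> Iterator[tuple[int, int]]:
    """Yield (byte_start, byte_len) runs of a sub-selection inside a chunk.

    ``sel_start``/``sel_count`` are within-chunk coordinates.  Trailing
    dimensions the selection covers completely merge into each run.
    """
    cdims = layout.chunk.dims
    es = layout.dataset.element_size
    n = len(cdims)
    # First dimension index (from the end) not fully covered; dims after
    # `m` contribute a contiguous tail of each run.
    m = n - 1
    while m >= 0 and sel_start[m] == 0 and sel_count[m] == cdims[m]:
        m -= 1
    base = layout.chunk_start(chunk_idx)
    tail = math.prod(cdims[m + 1 :]) if m + 1 <= n else 1
    if m < 0:
        yield base, es * layout.chunk.n_elements
        return
    run_len = es * sel_count[m] * tail
    # Enumerate selected indices in dims < m; dim m contributes the run.
    def rec(dim: int, prefix: list[int]) -> Iterator[tuple[int, int]]:
        if dim == m:
            within = tuple(prefix) + (sel_start[m],) + (0,) * (n - m - 1)
            yield base + es * _row_major_rank(within, cdims), run_len
            return
        for i in range(sel_start[dim], sel_start[dim] + sel_count[dim]):
            yield from rec(dim + 1, prefix + [i])

    yield from rec(0, [])


def segments_for_selection(slab: Hyperslab, layout: LinearLayout) -> SegmentReport:
    """Count maximal contiguous byte runs touched by a hyperslab read.

    Works analytically per chunk, then merges runs that abut across
    chunk boundaries, so it scales to full benchmark dimensions.
    """
    slab.validate(layout.dataset)
    cdims = layout.chunk.dims
    # Chunk-grid index range intersected by the selection, per dimension.
    lo = tuple(s // c for s, c in zip(slab.start, cdims))
    hi = tuple((s + n - 1) // c for s, n, c in zip(slab.start, slab.count, cdims))
    chunks_touched = math.prod(h - l + 1 for l, h in zip(lo, hi))

    runs: list[tuple[int, int]] = []

    def walk(dim: int, idx: list[int]) -> None:
        if dim == len(cdims):
            chunk_idx = tuple(idx)
            s = []
            c = []
            for i, (ci, cd) in enumerate(zip(chunk_idx, cdims)):
                a = max(slab.start[i], ci * cd)
                b = min(slab.start[i] + slab.count[i], (ci + 1) * cd)
                s.append(a - ci * cd)
                c.append(b - a)
            runs.extend(_chunk_runs(layout, chunk_idx, tuple(s), tuple(c)))
            return
        for i in range(lo[dim], hi[dim] + 1):
            walk(dim + 1, idx + [i])

    walk(0, [])
    runs.sort()
    segments = 0
    gap_bytes = 0
    end = None
    for start, length in runs:
        if end is not None and start == end:
            end += length
        else:
            if end is not None:
                gap_bytes += start - end
            segments += 1
            end = start + length
    es = layout.dataset.element_size
    return SegmentReport(
        segments=segments,
        bytes_read=es * slab.n_elements,
        gap_bytes=gap_bytes,
        chunks_touched=chunks_touched,
    )


def process_slab(rank: int, nprocs: int, dataset: DatasetShape) -> Hyperslab:
    """Contiguous node block owned by one of ``nprocs`` processes.

    The node dimension (dimension 2 of a time × nodes × variables
    dataset) is split into ``nprocs`` contiguous blocks; earlier ranks
    take the remainder nodes.  Each slab spans all other dimensions.
    """
    if dataset.ndim < 2:
        raise ValueError("process slabs need a dataset of >= 2 dimensions")
    d_n = dataset.dims[1]
    if not 0 <= rank < nprocs:
        raise ValueError(f"rank {rank} out of range for {nprocs} processes")
    if nprocs > d_n:
        raise ValueError(f"{nprocs} processes exceed {d_n} nodes")
    base, rem = divmod(d_n, nprocs)
    if rank < rem:
        start = rank * (base + 1)
        count = base + 1
    else:
        start = rem * (base + 1) + (rank - rem) * base
        count = base
    full_start = (0, start) + (0,) * (dataset.ndim - 2)
    full_count = (dataset.dims[0], count) + dataset.dims[2:]
    return Hyperslab(start=full_start, count=full_count)


def chunks_touched_by_process(
    rank: int, nprocs: int, dataset: DatasetShape, chunk: ChunkShape
) -> int:
    """Number of chunks intersecting one process's node slab."""
    slab = process_slab(rank, nprocs, dataset)
    cdims = chunk.dims
    n = 1
    for s, c, cd in zip(slab.start, slab.count, cdims):
        n *= (s + c - 1) // cd - s // cd + 1
    return n
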