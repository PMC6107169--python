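"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by enumeration rather
than calling the library's own fast paths, so tests compare two
independent routes to the same quantity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from h5layout import DatasetShape, LinearLayout

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def oracle_chunk_dims(dims: tuple[int, ...], t: int) -> tuple[tuple[int, ...], bool]:
    """Independent chunk-dims formula: x=ceil(D/T), C=ceil(D/x)."""
    out = []
    spans = True
    for d in dims:
        x = math.ceil(d / t)
        out.append(math.ceil(d / x))
        spans &= x == 1
    return tuple(out), spans


def oracle_plan(dims: tuple[int, ...], element_size: int, target_bytes: int):
    """Exhaustive linear scan over T in [1, max(dims)] mirroring the
    incremental search's stopping rule: stop at the first T whose chunk
    meets the byte target or spans the dataset, then step back one if
    the target was exceeded."""
    for t in range(1, max(dims) + 1):
        c, spans = oracle_chunk_dims(dims, t)
        nbytes = element_size * math.prod(c)
        if nbytes >= target_bytes or spans:
            if nbytes > target_bytes:
                c, spans = oracle_chunk_dims(dims, t - 1)
                nbytes = element_size * math.prod(c)
            return c, nbytes, spans
    raise AssertionError("unreachable: T = max(dims) always spans")


def oracle_offsets(slab_start, slab_count, layout: LinearLayout) -> list[int]:
    """Byte offset of every selected element, by direct per-element math
    (chunk coordinates and row-major ranks via numpy, not the library)."""
    ddims = layout.dataset.dims
    cdims = layout.chunk.dims
    es = layout.dataset.element_size
    counts = tuple(math.ceil(d / c) for d, c in zip(ddims, cdims))
    chunk_elems = math.prod(cdims)
    chunk_bytes = es * chunk_elems
    if layout.alignment > 0:
        stride = math.ceil(chunk_bytes / layout.alignment) * layout.alignment
    else:
        stride = chunk_bytes
    offsets = []
    ranges = [range(s, s + c) for s, c in zip(slab_start, slab_count)]
    for idx in itertools.product(*ranges):
        cidx = tuple(i // c for i, c in zip(idx, cdims))
        within = tuple(i % c for i, c in zip(idx, cdims))
        crank = int(np.ravel_multi_index(cidx, counts))
        erank = int(np.ravel_multi_index(within, cdims))
        offsets.append(layout.base_offset + crank * stride + es * erank)
    return offsets


def oracle_segments(offsets: list[int], element_size: int) -> int:
    """Run-length count: sort offsets and count maximal contiguous runs."""
    offsets = sorted(offsets)
    segments = 1
    for prev, cur in zip(offsets, offsets[1:]):
        if cur != prev + element_size:
            segments += 1
    return segments


@pytest.fixture
def benchmark_dataset() -> DatasetShape:
    """Full-scale cardiac benchmark dims: 151 × 3,253,316 × 2 doubles."""
    return DatasetShape(dims=(151, 3_253_316, 2), element_size=8)
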