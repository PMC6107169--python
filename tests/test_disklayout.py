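"""Serialization model: offsets, segment counting, process slabs."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from h5layout import (
    ChunkShape,
    DatasetShape,
    Hyperslab,
    LinearLayout,
    chunks_touched_by_process,
    element_offset,
    element_ordinal,
    process_slab,
    segments_for_selection,
    unchunked_layout,
)
from conftest import oracle_offsets, oracle_segments


def _layout(dims, chunk_dims, element_size=8, alignment=0, base=0):
    return LinearLayout(
        dataset=DatasetShape(dims, element_size=element_size),
        chunk=ChunkShape(chunk_dims, element_size * math.prod(chunk_dims), chunk_dims == tuple(dims)),
        base_offset=base,
        alignment=alignment,
    )


class TestElementOffset:
    def test_matrix_ordinals_10x10(self):
        """The worked 10x10 example: corners at 1, 10, 91, 100; (4,3) at 33."""
        lay = unchunked_layout(DatasetShape((10, 10)))
        assert element_ordinal((1, 1), lay) == 1
        assert element_ordinal((1, 10), lay) == 10
        assert element_ordinal((10, 1), lay) == 91
        assert element_ordinal((10, 10), lay) == 100
        assert element_ordinal((4, 3), lay) == 33

    def test_column_ordinals(self):
        lay = unchunked_layout(DatasetShape((10, 10)))
        assert [element_ordinal((r, 3), lay) for r in range(4, 9)] == [33, 43, 53, 63, 73]

    def test_first_element_is_base(self):
        lay = _layout((4, 5), (2, 3), base=0)
        assert element_offset((0, 0), lay) == 0

    def test_out_of_range(self):
        lay = unchunked_layout(DatasetShape((3, 3)))
        with pytest.raises(ValueError):
            element_offset((3, 0), lay)

    @given(
        dims=st.lists(st.integers(1, 8), min_size=1, max_size=3),
        data=st.data(),
    )
    def test_offsets_bijective_and_packed(self, dims, data):
        """All element offsets are distinct and, packed, land inside the
        allocated chunk bytes."""
        cdims = tuple(data.draw(st.integers(1, d)) for d in dims)
        lay = _layout(tuple(dims), cdims)
        offs = [
            element_offset(idx, lay)
            for idx in itertools.product(*(range(d) for d in dims))
        ]
        assert len(set(offs)) == len(offs)
        allocated = math.prod(
            math.ceil(d / c) * c for d, c in zip(dims, cdims)
        )
        assert all(0 <= o < allocated * 8 for o in offs)
        assert all(o % 8 == 0 for o in offs)


class TestSegments:
    def test_row_read_is_one_segment(self):
        lay = unchunked_layout(DatasetShape((10, 10)))
        slab = Hyperslab.from_matrix_notation((3, 4), (3, 8))
        assert segments_for_selection(slab, lay).segments == 1

    def test_column_read_needs_five_seeks(self):
        lay = unchunked_layout(DatasetShape((10, 10)))
        slab = Hyperslab.from_matrix_notation((4, 3), (8, 3))
        rep = segments_for_selection(slab, lay)
        assert rep.segments == 5
        assert rep.bytes_read == 5 * 8

    def test_column_chunk_makes_column_contiguous(self):
        lay = _layout((10, 10), (10, 1))
        slab = Hyperslab.from_matrix_notation((4, 3), (8, 3))
        assert segments_for_selection(slab, lay).segments == 1

    def test_chunks_touched_counts_distinct_chunks(self):
        lay = _layout((10, 10), (5, 5))
        rep = segments_for_selection(Hyperslab((0, 0), (10, 1)), lay)
        assert rep.chunks_touched == 2

    def test_alignment_introduces_gaps_not_values(self):
        lay = _layout((4, 4), (2, 4), alignment=1024)
        rep = segments_for_selection(Hyperslab((0, 0), (4, 4)), lay)
        assert rep.segments == 2
        assert rep.gap_bytes == 1024 - 2 * 4 * 8

    @given(
        dims=st.lists(st.integers(1, 10), min_size=1, max_size=3).filter(
            lambda d: math.prod(d) <= 10_000
        ),
        data=st.data(),
    )
    def test_equals_run_length_oracle(self, dims, data):
        dims = tuple(dims)
        cdims = tuple(data.draw(st.integers(1, d)) for d in dims)
        align = data.draw(st.sampled_from([0, 64, 256]))
        start = tuple(data.draw(st.integers(0, d - 1)) for d in dims)
        count = tuple(
            data.draw(st.integers(1, d - s)) for d, s in zip(dims, start)
        )
        lay = _layout(dims, cdims, alignment=align)
        rep = segments_for_selection(Hyperslab(start, count), lay)
        offs = oracle_offsets(start, count, lay)
        assert rep.segments == oracle_segments(offs, 8)
        assert rep.bytes_read == 8 * len(offs)

    @given(
        d_t=st.integers(2, 12),
        d_n=st.integers(4, 30),
        c_t=st.integers(1, 12),
        c_n=st.integers(1, 6),
    )
    def test_node_series_no_worse_under_small_chunks(self, d_t, d_n, c_t, c_n):
        """Reading one node's full series never needs more element-level
        segments under small planned-style chunks than under a
        node-spanning default-style layout."""
        ds = DatasetShape((d_t, d_n, 2))
        small = _layout((d_t, d_n, 2), (min(c_t, d_t), min(c_n, d_n), 2))
        default = _layout((d_t, d_n, 2), (min(c_t, d_t), d_n, 2))
        for node in range(d_n):
            slab = Hyperslab((0, node, 0), (d_t, 1, 2))
            assert (
                segments_for_selection(slab, small).segments
                <= segments_for_selection(slab, default).segments
            )


class TestProcessSlabs:
    def test_equal_partition(self):
        slab = process_slab(0, 4, DatasetShape((151, 100, 2)))
        assert slab.start == (0, 0, 0)
        assert slab.count == (151, 25, 2)

    def test_remainder_goes_to_early_ranks(self):
        ds = DatasetShape((151, 10, 2))
        sizes = [process_slab(r, 3, ds).count[1] for r in range(3)]
        assert sizes == [4, 3, 3]

    @given(
        d_n=st.integers(1, 200),
        nprocs=st.integers(1, 16),
    )
    def test_partition_covers_disjointly(self, d_n, nprocs):
        if nprocs > d_n:
            return
        ds = DatasetShape((7, d_n, 2))
        covered = []
        for r in range(nprocs):
            slab = process_slab(r, nprocs, ds)
            assert slab.count[0] == 7 and slab.count[2] == 2
            covered.extend(range(slab.start[1], slab.start[1] + slab.count[1]))
        assert covered == list(range(d_n))

    def test_too_many_processes(self):
        with pytest.raises(ValueError):
            process_slab(0, 11, DatasetShape((5, 10, 2)))


class TestChunksTouchedByProcess:
    def test_default_style_touches_every_time_chunk(self):
        """Node-spanning chunks are orthogonal to process slabs: every
        process touches all ceil(D_t/C_t) chunks."""
        ds = DatasetShape((151, 1000, 2))
        chunk = ChunkShape((41, 1000, 2), 8 * 41 * 1000 * 2, False)
        for rank in range(8):
            assert chunks_touched_by_process(rank, 8, ds, chunk) == math.ceil(151 / 41)

    def test_chunk_equal_to_slab_touches_one(self):
        ds = DatasetShape((10, 100, 2))
        chunk = ChunkShape((10, 25, 2), 8 * 10 * 25 * 2, False)
        assert chunks_touched_by_process(0, 4, ds, chunk) == 1

    @given(rank=st.integers(0, 11), data=st.data())
    def test_matches_brute_force_grid_intersection(self, rank, data):
        d_t = data.draw(st.integers(1, 12))
        d_n = data.draw(st.integers(12, 60))
        c_t = data.draw(st.integers(1, d_t))
        c_n = data.draw(st.integers(1, d_n))
        nprocs = 12
        ds = DatasetShape((d_t, d_n, 2))
        chunk = ChunkShape((c_t, c_n, 2), 8 * c_t * c_n * 2, False)
        slab = process_slab(rank, nprocs, ds)
        # brute force: enumerate the chunk grid, intersect with the slab
        n = 0
        for it in range(math.ceil(d_t / c_t)):
            for jn in range(math.ceil(d_n / c_n)):
                t_overlap = max(0, min(d_t, (it + 1) * c_t) - max(0, it * c_t))
                lo = max(slab.start[1], jn * c_n)
                hi = min(slab.start[1] + slab.count[1], (jn + 1) * c_n)
                if t_overlap > 0 and hi > lo:
                    n += 1
        assert chunks_touched_by_process(rank, nprocs, ds, chunk) == n

    def test_full_scale_matches_grid_enumeration(self, benchmark_dataset):
        chunk = ChunkShape((151, 434, 2), 1_048_544, False)
        total = sum(
            chunks_touched_by_process(r, 192, benchmark_dataset, chunk)
            for r in range(192)
        )
        # 7497 node-column chunks, some shared by two adjacent ranks
        assert total >= 7497
        assert total <= 7497 + 191
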