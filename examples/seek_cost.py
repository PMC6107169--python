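"""Count the disk seeks a row versus a column read costs in a 10x10 dataset.

Under the default row-major layout a row is one contiguous read while a
column needs a seek before every element; column-shaped chunks turn the
column into a single contiguous read.  The printed segment counts are
the number of maximal contiguous byte runs each access touches.
"""

from h5layout import (
    ChunkShape,
    DatasetShape,
    Hyperslab,
    LinearLayout,
    element_ordinal,
    segments_for_selection,
    unchunked_layout,
)

dataset = DatasetShape(dims=(10, 10), element_size=8)
flat = unchunked_layout(dataset)

print("entry (4,3) is element", element_ordinal((4, 3), flat), "on disk")

row = Hyperslab.from_matrix_notation((3, 4), (3, 8))
col = Hyperslab.from_matrix_notation((4, 3), (8, 3))
print("row (3,4)-(3,8)    :", segments_for_selection(row, flat).segments, "segment(s)")
print("column (4,3)-(8,3) :", segments_for_selection(col, flat).segments, "segment(s)")

column_chunks = LinearLayout(dataset=dataset, chunk=ChunkShape((10, 1), 80, False))
print("same column, column-shaped chunks:",
      segments_for_selection(col, column_chunks).segments, "segment(s)")
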