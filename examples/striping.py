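"""Map a striped file onto its storage targets and size the stripe count.

A 4.5 MB file with 1 MB stripes over 3 OSTs starting at OST6 lands as
five round-robin stripes ending with a half stripe on OST7.  The
rule-of-thumb stripe count (1 stripe per 1-4 decimal GB) is applied to
the ~5.21 GB benchmark dataset, and the effect of aligning ~1 MB chunks
to stripe boundaries is shown: unaligned, a chunk can straddle two OSTs.
"""

from h5layout import (
    StripingConfig,
    dataset_bytes,
    format_decimal_bytes,
    osts_touched_by_range,
    recommended_stripe_count,
    stripes_of_file,
)

MB = 2**20
cfg = StripingConfig(stripe_size=MB, stripe_count=3, first_ost=6)

for i, ost, size in stripes_of_file(int(4.5 * MB), cfg).stripes:
    print(f"stripe {i}: OST{ost}, {size / MB:.1f} MB")

_, total = dataset_bytes(100, 3_253_316, 2)
low, high = recommended_stripe_count(total)
print(f"\n{format_decimal_bytes(total)} dataset -> stripe count between {low} and {high}")

chunk = 1_048_544  # the planned benchmark chunk, slightly under 1 MiB
print("\nOSTs touched by one chunk read:")
print("  packed at offset 1048544 :", osts_touched_by_range(1_048_544, chunk, cfg))
print("  aligned to a stripe      :", osts_touched_by_range(2 * MB, chunk, cfg))
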