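# Methods

## Problem setting

Large parallel simulations — the motivating case is bidomain cardiac
electrophysiology on a ~3.25 million node heart–torso mesh — print their
state to an HDF5 dataset of shape (time, nodes, variables) every
printing time step.  Two antagonistic access patterns then meet the same
file: the solver writes one time slab at a time, while post-processing
(activation-time maps, peak-voltage maps, conversion to visualization
formats) reads one node's full time series at a time.  On-disk layout
decides which of these is cheap.  `h5layout` implements three coupled
pieces: a chunk-shape planner, an aggregating write cache, and analytic
cost models (serialization/seek counting and Lustre-style striping) that
make layout consequences measurable deterministically, without a
parallel filesystem.

## Chunk-shape planning

For a dataset with extents D⃗ = (D₁, …, D_N) and a target chunk size T_B
in bytes, the planner searches over a per-dimension target extent T.
For each dimension it takes the minimum chunk count covering the
dataset, x_i = ⌈D_i/T⌉, and then the minimum extent that still covers
with that count, C_i = ⌈D_i/x_i⌉.  This second rounding is what keeps
edge waste low: given x_i chunks, no smaller extent covers the dataset,
so over-allocation in each dimension is less than one chunk row.  The
planner returns the chunk for the first T at which the chunk byte size
reaches T_B (stepping back one if it overshot) or the chunk spans the
whole dataset.

The byte size element_size·∏C_i is non-decreasing in T, which justifies
the single step-back and makes the stopping predicate monotone; the
default search is therefore a binary search over T ∈ [1, max D⃗], with
the incremental scan kept as the reference definition.  A property test
asserts the two are equal everywhere on small instances, and an
exhaustive oracle over all T confirms the result on every dataset with
∏D_i ≤ 10⁴.

Parameters:

* `target_bytes` — default 131072 (128 KiB), a size that behaves well
  for small runs; 1 MiB is recommended for large problems, matching the
  common parallel-filesystem stripe size.  Values below one element are
  rejected (the constraint is unsatisfiable).
* `element_size` — default 8 B (double precision).  The planner is
  generic over element size; at the default it reproduces the published
  behaviour exactly: dims (151, 3253316, 2) with a 1 MiB target give
  chunk {151, 434, 2} of 1,048,544 B, i.e. 7497 chunks with 0.012 %
  edge waste.

The conventional layout it replaces — `default_chunk` — spans every
dimension but time, with the time extent capped by a single-write limit
(default 2³¹ B, the signed-32-bit ROMIO/MPI-IO cap, which yields
C_t = 41 on the benchmark dims).  Chunk shape is fixed at dataset
creation; adapting it later is out of scope, as is access-pattern-driven
optimization (deliberately: it tends to be problem- and
machine-specific).

A note on the time extent: the benchmark run had 150 printing steps but
a 151-slice time dimension (the initial state is slice 0).  All
computations here use D_t = 151 as the dataset extent; a related
wrinkle is that ⌈151/41⌉ = 4 conventional chunks, though the source
discussion speaks of three.

## Serialization and seek-cost model

`LinearLayout` maps every element to a byte offset: row-major within a
chunk, chunks placed row-major over the chunk grid, packed sequentially
from a base offset.  Real HDF5 places chunks in write order at irregular
offsets tracked by a B-tree; the fixed deterministic order is a modeling
assumption required for testable cost accounting, and B-tree metadata
costs are ignored.  With `alignment > 0`, every chunk start is padded up
to the next multiple (the model of aligning chunks to stripe
boundaries).

`segments_for_selection` counts the maximal contiguous byte runs a
hyperslab touches — each run boundary is a seek.  It is computed
analytically: within each intersected chunk, trailing dimensions the
selection covers completely merge into single runs; runs are then sorted
and merged across chunk boundaries where they abut.  This makes the
model usable at full benchmark dimensions, while tests compare it
against a brute-force enumerate-sort-count oracle on small instances.
Indexing is 0-based half-open internally, with 1-based helpers matching
conventional matrix notation (entry (4,3) of a 10×10 dataset is the 33rd
element on disk; reading column entries (4,3)–(8,3) costs 5 segments
unchunked and 1 under column-shaped chunks).

Process decomposition is modeled by `process_slab`: the node dimension
is split into contiguous blocks, earlier ranks receiving the remainder
(any deterministic rule works; this one is stated).  Node-spanning
chunks are orthogonal to these slabs, so every process touches every
time chunk — the structural reason conventional chunks coordinate badly.

## Benchmark read-cost metric

The serial HDF5 driver reads whole chunks whenever a chunk fits its
chunk cache, and falls back to direct access otherwise.  The benchmark's
`read_segments` metric models exactly that: a chunk no larger than the
cache limit (default 2²⁰ B, HDF5's default `rdcc_nbytes`) costs one
contiguous read per touched chunk regardless of how scattered the
selected elements are inside it; a larger chunk is charged its
element-level run count.  This is the mechanism that separates the
strategies: at desk scale a node's time series costs D_t runs inside one
huge node-spanning chunk, versus a handful of whole-chunk reads under
planned small chunks.  The pure element-level counter remains available
as `segments_for_selection`; under it the two layouts tie on the
node-series pattern (both cost D_t runs), which is why the cache-aware
metric is the benchmark's default.

## Cached writes

The writer optionally buffers time steps in a reserved
C_t × N_n × N_v array (chunk time extent × owned nodes × variables) and
writes the whole window in one storage operation when C_t steps have
accumulated, reducing the write-call count from D_t to ⌈D_t/C_t⌉.
Caching is chosen at construction and cannot be toggled, which removes
mid-run flush logic.  Behaviour left open by the window rule is pinned
as follows: a partially filled window is flushed on `close()`, so runs
with D_t not a multiple of C_t lose nothing; writes must arrive in time
order; the dataset extent is fixed at creation (extendable time is a
non-goal).  Values are little-endian IEEE float64.  Cached and uncached
writers are bit-identical on disk — a property test sweeps a
(D_t, C_t, N_n, N_v) grid including non-divisible windows.

File-level alignment is delegated to HDF5's native facility (h5py's
`alignment_threshold`/`alignment_interval`); it changes offsets and file
size, never values.

## Striping model

Files are cut into stripes of size S (a multiple of 64 KiB; default
2²⁰ B) placed round-robin over c of the available OSTs starting from a
first OST chosen by the filesystem — here an explicit parameter, with a
seeded random helper for realism.  The model enumerates stripes, maps
offsets to OSTs, and counts distinct OSTs a byte range touches: a chunk
slightly under one stripe that is packed right after another straddles a
boundary and needs two OSTs, while stripe-aligned chunk starts keep
every such chunk on one OST.  The stripe-count heuristic (1 stripe per
decimal GB down to 1 per 4 GB, ceiling division) gives (2, 6) for the
~5.21 GB hundred-step benchmark file.  Units are deliberately mixed the
way practice mixes them: stripes are binary MB, dataset sizes are
reported in decimal MB/GB to three significant figures (52.1 MB per
step, 5.21 GB per 100 steps); outputs are unit-labeled.  OST bandwidth,
contention and lock hold times are out of scope.

## Synthetic data

The generator emulates the benchmark's data shape, not its physics: per
node, the transmembrane potential rests at −85 mV until a planar
activation wave arrives (node i activates at step ⌊i/speed⌋), steps to
+40 mV, and relaxes exponentially with a 30-step time constant;
φ_e = −0.1·V_m is a placeholder second variable; optional Gaussian noise
is seeded.  The default wave speed traverses all nodes within two thirds
of the window so every node activates.  print_dt defaults to 25 µs, the
benchmark's printing step.  This surrogate gives post-processing an
exact ground truth (with zero noise, recovered activation times and
peaks are bitwise exact; at 1 mV noise, ≥ 99 % of activation times land
within one printing step), but it shares none of the spatial
correlation, upstroke shape or repolarization heterogeneity of real
bidomain output — passing tests certify the I/O and detection machinery,
not electrophysiological fidelity.

The activation detector is a configurable upward threshold crossing at
−70 mV (the choice is a convention, so it is a logged parameter);
peak detection takes the earliest maximum on ties.

## Benchmark driver and problem sizes

`run_benchmark` writes one synthetic run per strategy — conventional
chunks, planned chunks, planned chunks + cache — then runs conversion
(per-time-step records; minimal `.npy` payloads stand in for
visualization files, whose format is irrelevant to the read pattern) and
post-processing (per-node series), reporting instrumented storage write
calls, model read segments, chunks touched and bytes moved.  Wall
seconds are printed for interest only; they are hardware-dependent and
never asserted.  Multi-process writing is modeled analytically via
process slabs rather than spawned processes; a true MPI mode is not
included.

Default problem sizes are desk scale — thousands of nodes, 151 steps —
chosen so the whole suite and the benchmark complete in seconds while
preserving every structural property of the full-scale runs (planned
chunk shape logic, cache window arithmetic, pattern costs); full-scale
quantities (chunk {151,434,2}, 7497 chunks, C_t = 41, 52.1 MB/step) are
computed exactly by the planner and size calculator, which need no
allocation.

## Known limitations

* The disk model's packed sequential chunk placement understates the
  irregularity of real HDF5 files; segment counts are a lower bound on
  real seek behaviour.
* The striping model ignores bandwidth, contention and aggregator
  scheduling; it quantifies placement only.
* The cache-aware read metric uses a single fixed cache limit; real
  `rdcc` tuning (slots, preemption policy) is not modeled.
* The synthetic waveform is an I/O-grade surrogate, not a cell model.
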