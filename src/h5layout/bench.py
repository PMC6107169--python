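"""Post-processing stages and the three-strategy I/O benchmark.

The two post-processing products — per-node activation-time and
peak-voltage maps, and per-timestep conversion to visualization records
— exercise the two antagonistic access patterns: reading one node's full
time series (column-style, expensive under time-sliced chunks) versus
reading one time step's full node slab (row-style).

``run_benchmark`` compares the three layout strategies:

* ``default`` — conventional chunks spanning nodes and variables, time
  extent capped by the ~2 GiB single-write limit;
* ``new`` — planned chunks at a target byte size;
* ``new+cache`` — planned chunks plus the aggregating write cache.

Cost is reported with deterministic metrics (storage write calls, read
segments, chunks touched, bytes moved) computed from instrumented writes
and the analytic disk-layout model; wall-clock seconds are printed for
interest but are hardware-dependent and never asserted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .disklayout import Hyperslab, LinearLayout, segments_for_selection
from .io import SimulationOutputSpec, SimulationReader, WriterConfig, write_output
from .planner import (
    ChunkShape,
    DatasetShape,
    PlannerConfig,
    default_chunk,
    plan_chunks,
)
from .synthetic import SimulationOutput, SyntheticParams, generate

__all__ = [
    "activation_time",
    "peak_voltage",
    "activation_map",
    "peak_map",
    "convert_timesteps",
    "modeled_read_segments",
    "BenchStrategy",
    "StageMetrics",
    "BenchReport",
    "standard_strategies",
    "run_benchmark",
]

ACTIVATION_THRESHOLD_MV = -70.0

#: Default chunk-cache capacity of the HDF5 serial (POSIX) driver.
DEFAULT_CHUNK_CACHE_BYTES = 2**20


def modeled_read_segments(
    slab: Hyperslab,
    layout: LinearLayout,
    chunk_cache_bytes: int = DEFAULT_CHUNK_CACHE_BYTES,
) -> int:
    """Contiguous reads one hyperslab access costs under the caching reader.

    The serial HDF5 driver reads whole chunks when a chunk fits its
    chunk cache, so a cacheable chunk costs one contiguous read no
    matter how scattered the selected elements are inside it; a chunk
    too large to cache is accessed directly, element run by element
    run.  This is the mechanism that makes small planned chunks cheap
    for node-series reads and huge node-spanning chunks expensive.
    """
    rep = segments_for_selection(slab, layout)
    if layout.chunk_bytes <= chunk_cache_bytes:
        return rep.chunks_touched
    return rep.segments


def activation_time(
    series: np.ndarray, print_dt: float, threshold: float = ACTIVATION_THRESHOLD_MV
) -> Optional[float]:
    """Time of the first sample with V_m >= threshold, or None if never.

    The detector is a simple upward threshold crossing at −70 mV by
    default; both the threshold and its direction are conventions, so
    the threshold is an explicit parameter.
    """
    series = np.asarray(series)
    if series.size < 1:
        raise ValueError("series must be non-empty")
    hits = np.nonzero(series >= threshold)[0]
    if hits.size == 0:
        return None
    return float(hits[0] * print_dt)


def peak_voltage(series: np.ndarray) -> float:
    """Maximum of the series (earliest sample on ties)."""
    series = np.asarray(series)
    if series.size < 1:
        raise ValueError("series must be non-empty")
    return float(series[int(np.argmax(series))])


def activation_map(
    reader: SimulationReader,
    variable: int = 0,
    threshold: float = ACTIVATION_THRESHOLD_MV,
) -> np.ndarray:
    """Per-node activation times read node by node (NaN = no activation)."""
    d_t, d_n, _ = reader.shape
    out = np.full(d_n, np.nan)
    for node in range(d_n):
        t = activation_time(
            reader.read_node_series(node, variable), reader.print_dt, threshold
        )
        if t is not None:
            out[node] = t
    return out


def peak_map(reader: SimulationReader, variable: int = 0) -> np.ndarray:
    """Per-node peak voltages read node by node."""
    d_n = reader.shape[1]
    return np.array(
        [peak_voltage(reader.read_node_series(node, variable)) for node in range(d_n)]
    )


def convert_timesteps(reader: SimulationReader, out_dir: Union[str, Path]) -> list[Path]:
    """Write one per-timestep record file holding that step's node slab.

    The records are minimal .npy arrays, standing in for visualization
    files: what matters for I/O is the time-slab read pattern, not the
    output format (true VTK would need mesh geometry).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(reader.shape[0]):
        p = out_dir / f"step_{t:05d}.npy"
        np.save(p, reader.read_timestep_slab(t))
        paths.append(p)
    return paths


@dataclass(frozen=True)
class BenchStrategy:
    """One of the three compared layout/caching configurations."""

    label: str
    use_default_chunks: bool
    cache_enabled: bool
    target_bytes: int = 128 * 2**10
    max_write_bytes: int = 2**31
    alignment_bytes: int = 0

    def chunk_for(self, dataset: DatasetShape) -> ChunkShape:
        if self.use_default_chunks:
            return default_chunk(dataset, self.max_write_bytes)
        return plan_chunks(dataset, PlannerConfig(self.target_bytes))


def standard_strategies(
    target_bytes: int = 128 * 2**10, max_write_bytes: int = 2**31
) -> tuple[BenchStrategy, BenchStrategy, BenchStrategy]:
    """The three configurations compared in the benchmark."""
    return (
        BenchStrategy("default", True, False, target_bytes, max_write_bytes),
        BenchStrategy("new", False, False, target_bytes, max_write_bytes),
        BenchStrategy("new+cache", False, True, target_bytes, max_write_bytes),
    )


@dataclass(frozen=True)
class StageMetrics:
    """Deterministic cost of one stage under one strategy."""

    storage_write_calls: int = 0
    read_segments: int = 0
    chunks_touched: int = 0
    bytes_moved: int = 0
    wall_seconds: float = 0.0  # informational only, never asserted

    def as_dict(self) -> dict:
        return {
            "storage_write_calls": self.storage_write_calls,
            "read_segments": self.read_segments,
            "chunks_touched": self.chunks_touched,
            "bytes_moved": self.bytes_moved,
            "wall_seconds": self.wall_seconds,
        }


@dataclass
class BenchReport:
    """Strategy × stage (Output, DataConv, PostProc) metric table."""

    spec: SimulationOutputSpec
    chunks: dict[str, tuple[int, ...]]
    metrics: dict[str, dict[str, StageMetrics]]
    activation: dict[str, np.ndarray]
    peaks: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, stages in self.metrics.items():
            for stage, m in stages.items():
                rows.append({"strategy": label, "stage": stage, **m.as_dict()})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "dims": list(self.spec.dims),
            "chunks": {k: list(v) for k, v in self.chunks.items()},
            "metrics": {
                k: {s: m.as_dict() for s, m in v.items()}
                for k, v in self.metrics.items()
            },
        }


def _node_series_cost(
    layout: LinearLayout, chunk_cache_bytes: int = DEFAULT_CHUNK_CACHE_BYTES
) -> tuple[int, int]:
    """Total (modeled read segments, chunks touched) for reading every
    node's full time series with all variables — the post-processing
    pattern."""
    d_t, d_n, d_v = layout.dataset.dims
    c_t, c_n, c_v = layout.chunk.dims
    cacheable = layout.chunk_bytes <= chunk_cache_bytes
    segments = 0
    chunks = 0
    # Cost is identical for nodes sharing a within-chunk node position,
    # so evaluate one node per position and multiply by its multiplicity.
    for pos in range(min(c_n, d_n)):
        rep = segments_for_selection(
            Hyperslab(start=(0, pos, 0), count=(d_t, 1, d_v)), layout
        )
        mult = (d_n - pos - 1) // c_n + 1
        segments += (rep.chunks_touched if cacheable else rep.segments) * mult
        chunks += rep.chunks_touched * mult
    return segments, chunks


def _time_slab_cost(
    layout: LinearLayout, chunk_cache_bytes: int = DEFAULT_CHUNK_CACHE_BYTES
) -> tuple[int, int]:
    """Total (modeled read segments, chunks touched) for reading every
    time step's full node slab — the conversion pattern."""
    d_t, d_n, d_v = layout.dataset.dims
    c_t = layout.chunk.dims[0]
    cacheable = layout.chunk_bytes <= chunk_cache_bytes
    segments = 0
    chunks = 0
    for pos in range(min(c_t, d_t)):
        rep = segments_for_selection(
            Hyperslab(start=(pos, 0, 0), count=(1, d_n, d_v)), layout
        )
        mult = (d_t - pos - 1) // c_t + 1
        segments += (rep.chunks_touched if cacheable else rep.segments) * mult
        chunks += rep.chunks_touched * mult
    return segments, chunks


def run_benchmark(
    params: SyntheticParams,
    workdir: Union[str, Path],
    strategies: Optional[Sequence[BenchStrategy]] = None,
    nprocs_model: int = 1,
) -> BenchReport:
    """Write, convert and post-process one synthetic run per strategy.

    All strategies receive the same generated data; the report carries
    instrumented write counts, model-derived read segments and chunks
    touched per stage, and the (strategy-invariant) activation and peak
    maps.  ``nprocs_model`` partitions the write accounting into that
    many analytic process slabs without spawning processes.
    """
    if strategies is None:
        strategies = standard_strategies()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    output, _truth = generate(params)
    spec = SimulationOutputSpec(
        n_timesteps=output.n_timesteps,
        n_nodes=output.n_nodes,
        n_variables=output.n_variables,
        print_dt=params.print_dt,
    )
    dataset = spec.dataset_shape

    chunks: dict[str, tuple[int, ...]] = {}
    metrics: dict[str, dict[str, StageMetrics]] = {}
    activation: dict[str, np.ndarray] = {}
    peaks: dict[str, np.ndarray] = {}

    for strat in strategies:
        chunk = strat.chunk_for(dataset)
        chunks[strat.label] = chunk.dims
        layout = LinearLayout(
            dataset=dataset, chunk=chunk, alignment=strat.alignment_bytes
        )
        path = workdir / f"{strat.label.replace('+', '_')}.h5"

        t0 = time.perf_counter()
        writer = write_output(
            output.values,
            WriterConfig(
                chunk=chunk,
                cache_enabled=strat.cache_enabled,
                alignment_bytes=strat.alignment_bytes,
            ),
            path,
            spec=spec,
        )
        out_metrics = StageMetrics(
            storage_write_calls=writer.storage_writes * nprocs_model,
            bytes_moved=dataset.nbytes,
            wall_seconds=time.perf_counter() - t0,
        )

        with SimulationReader(path) as reader:
            t0 = time.perf_counter()
            conv_dir = workdir / f"{strat.label.replace('+', '_')}_conv"
            convert_timesteps(reader, conv_dir)
            conv_wall = time.perf_counter() - t0
            seg, tch = _time_slab_cost(layout)
            conv_metrics = StageMetrics(
                read_segments=seg,
                chunks_touched=tch,
                bytes_moved=dataset.nbytes,
                wall_seconds=conv_wall,
            )

            t0 = time.perf_counter()
            activation[strat.label] = activation_map(reader)
            peaks[strat.label] = peak_map(reader)
            pp_wall = time.perf_counter() - t0
            seg, tch = _node_series_cost(layout)
            pp_metrics = StageMetrics(
                read_segments=seg,
                chunks_touched=tch,
                bytes_moved=dataset.nbytes,
                wall_seconds=pp_wall,
            )

        metrics[strat.label] = {
            "Output": out_metrics,
            "DataConv": conv_metrics,
            "PostProc": pp_metrics,
        }

    return BenchReport(
        spec=spec, chunks=chunks, metrics=metrics, activation=activation, peaks=peaks
    )
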