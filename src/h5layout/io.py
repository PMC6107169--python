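"""HDF5 reading and writing of the simulation dataset, with cached writes.

The on-file schema is one 3-D float64 dataset named ``Data`` with
dimensions (time, nodes, variables) and attributes ``Variable Names``,
``Variable Units`` and ``Print timestep (s)``.

Writers emit one time step at a time, the way a simulation prints its
state.  Parallel filesystems favour few large writes over many small
ones, so the writer optionally aggregates time steps in a memory cache
with reserved capacity C_t × N_n × N_v (C_t = chunk extent in time, N_n
= owned nodes, N_v = variables) and flushes the whole window in a single
storage operation once C_t steps have accumulated.  Caching is chosen at
construction and cannot be toggled afterwards, which avoids mid-run
flush logic.  A partially filled window is flushed on close so a run
whose step count is not a multiple of C_t loses nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np

from .planner import ChunkShape, DatasetShape, PlannerConfig, plan_chunks

__all__ = [
    "SimulationOutputSpec",
    "WriterConfig",
    "SimulationWriter",
    "SimulationReader",
    "create_dataset",
    "write_output",
]

DATASET_NAME = "Data"


@dataclass(frozen=True)
class SimulationOutputSpec:
    """Shape and metadata of one simulation output dataset."""

    n_timesteps: int
    n_nodes: int
    n_variables: int = 2
    variable_names: tuple[str, ...] = ("V_m", "phi_e")
    variable_units: tuple[str, ...] = ("mV", "mV")
    print_dt: float = 25e-6

    def __post_init__(self) -> None:
        if min(self.n_timesteps, self.n_nodes, self.n_variables) < 1:
            raise ValueError("all extents must be >= 1")
        if len(self.variable_names) != self.n_variables:
            raise ValueError("variable_names length must equal n_variables")
        if len(self.variable_units) != self.n_variables:
            raise ValueError("variable_units length must equal n_variables")

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.n_timesteps, self.n_nodes, self.n_variables)

    @property
    def dataset_shape(self) -> DatasetShape:
        return DatasetShape(dims=self.dims, element_size=8)


@dataclass(frozen=True)
class WriterConfig:
    """Chunking, caching and alignment choices for one writer.

    Exactly one of ``chunk`` (an explicit shape) or ``target_bytes``
    (plan a shape) selects the chunking.  ``node_range`` is the (start,
    count) of nodes this writer owns; None means all nodes.
    """

    chunk: Optional[ChunkShape] = None
    target_bytes: Optional[int] = None
    cache_enabled: bool = False
    alignment_bytes: int = 0
    node_range: Optional[tuple[int, int]] = None

    def resolve_chunk(self, spec: SimulationOutputSpec) -> ChunkShape:
        if (self.chunk is None) == (self.target_bytes is None):
            raise ValueError("specify exactly one of chunk or target_bytes")
        if self.chunk is not None:
            if any(c > d for c, d in zip(self.chunk.dims, spec.dims)):
                raise ValueError("chunk exceeds dataset dims")
            return self.chunk
        return plan_chunks(spec.dataset_shape, PlannerConfig(self.target_bytes))


class SimulationWriter:
    """Sequential per-timestep writer over one HDF5 file.

    ``storage_writes`` counts the dataset-level write operations issued,
    which is the deterministic stand-in for write cost: with the cache
    enabled it ends at ceil(D_t / C_t) instead of D_t.
    """

    def __init__(
        self,
        spec: SimulationOutputSpec,
        config: WriterConfig,
        path: Union[str, Path],
    ) -> None:
        self.spec = spec
        self.config = config
        self.chunk = config.resolve_chunk(spec)
        self.node_start, self.n_nodes_owned = config.node_range or (0, spec.n_nodes)
        if self.node_start < 0 or self.node_start + self.n_nodes_owned > spec.n_nodes:
            raise ValueError("node_range outside [0, n_nodes)")

        fkw = {}
        if config.alignment_bytes > 0:
            fkw = dict(alignment_threshold=1, alignment_interval=config.alignment_bytes)
        self._file = h5py.File(path, "w", **fkw)
        self._dset = self._file.create_dataset(
            DATASET_NAME, shape=spec.dims, dtype="<f8", chunks=self.chunk.dims
        )
        self._dset.attrs["Variable Names"] = list(spec.variable_names)
        self._dset.attrs["Variable Units"] = list(spec.variable_units)
        self._dset.attrs["Print timestep (s)"] = float(spec.print_dt)

        self.cache_window = self.chunk.dims[0]  # C_t
        self._cache: Optional[np.ndarray] = None
        if config.cache_enabled:
            self._cache = np.empty(
                (self.cache_window, self.n_nodes_owned, spec.n_variables),
                dtype=np.float64,
            )
        self.fill = 0
        self.next_t = 0
        self.storage_writes = 0
        self._closed = False

    def __enter__(self) -> "SimulationWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def write_timestep(self, t: int, values: np.ndarray) -> None:
        """Append one step's N_n × N_v block; steps must arrive in order."""
        if self._closed:
            raise RuntimeError("writer is closed")
        if t != self.next_t:
            raise ValueError(f"expected timestep {self.next_t}, got {t}")
        if t >= self.spec.n_timesteps:
            raise ValueError("timestep beyond dataset extent")
        values = np.asarray(values, dtype=np.float64)
        want = (self.n_nodes_owned, self.spec.n_variables)
        if values.shape != want:
            raise ValueError(f"value block shape {values.shape} != {want}")

        if self._cache is None:
            self._store(t, t + 1, values[None, :, :])
        else:
            self._cache[self.fill] = values
            self.fill += 1
            if self.fill == self.cache_window:
                # flush the whole window [t - C_t + 1, t] in one operation
                self._store(t + 1 - self.fill, t + 1, self._cache[: self.fill])
                self.fill = 0
        self.next_t = t + 1

    def _store(self, t0: int, t1: int, block: np.ndarray) -> None:
        s = self.node_start
        self._dset[t0:t1, s : s + self.n_nodes_owned, :] = block
        self.storage_writes += 1

    def close(self) -> None:
        """Flush any partial cache window and close the file."""
        if self._closed:
            return
        if self._cache is not None and self.fill > 0:
            t1 = self.next_t
            t0 = t1 - self.fill
            try:
                self._store(t0, t1, self._cache[: self.fill])
            except Exception as err:
                raise IOError(
                    f"failed to flush {self.fill} cached timesteps"
                ) from err
            self.fill = 0
        self._file.close()
        self._closed = True


class SimulationReader:
    """Read access over one written file, in the two post-processing patterns."""

    def __init__(self, path: Union[str, Path]) -> None:
        self._file = h5py.File(path, "r")
        self._dset = self._file[DATASET_NAME]

    def __enter__(self) -> "SimulationReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self._dset.shape)

    @property
    def chunk_dims(self) -> Optional[tuple[int, ...]]:
        return tuple(self._dset.chunks) if self._dset.chunks else None

    @property
    def variable_names(self) -> list[str]:
        return [str(v) for v in self._dset.attrs["Variable Names"]]

    @property
    def variable_units(self) -> list[str]:
        return [str(v) for v in self._dset.attrs["Variable Units"]]

    @property
    def print_dt(self) -> float:
        return float(self._dset.attrs["Print timestep (s)"])

    def read_node_series(self, node: int, variable: int) -> np.ndarray:
        """All time points of one variable at one node (post-processing)."""
        d_t, d_n, d_v = self.shape
        if not (0 <= node < d_n and 0 <= variable < d_v):
            raise IndexError(f"(node={node}, variable={variable}) out of range")
        return self._dset[:, node, variable]

    def read_node_block(self, node: int) -> np.ndarray:
        """All time points of all variables at one node, shape (D_t, D_v)."""
        if not 0 <= node < self.shape[1]:
            raise IndexError(f"node {node} out of range")
        return self._dset[:, node, :]

    def read_timestep_slab(self, t: int) -> np.ndarray:
        """One time step's full nodes × variables block (conversion pattern)."""
        if not 0 <= t < self.shape[0]:
            raise IndexError(f"timestep {t} out of range")
        return self._dset[t, :, :]

    def read_all(self) -> np.ndarray:
        return self._dset[...]

    def close(self) -> None:
        self._file.close()


def create_dataset(
    spec: SimulationOutputSpec, config: WriterConfig, path: Union[str, Path]
) -> SimulationWriter:
    """Create the HDF5 file and return a writer handle for it."""
    return SimulationWriter(spec, config, path)


def write_output(
    values: np.ndarray,
    config: WriterConfig,
    path: Union[str, Path],
    spec: Optional[SimulationOutputSpec] = None,
) -> SimulationWriter:
    """Write a full (time, nodes, variables) array step by step; returns
    the closed writer so callers can inspect ``storage_writes``."""
    if spec is None:
        spec = SimulationOutputSpec(
            n_timesteps=values.shape[0],
            n_nodes=values.shape[1],
            n_variables=values.shape[2],
        )
    writer = SimulationWriter(spec, config, path)
    ns, nn = writer.node_start, writer.n_nodes_owned
    for t in range(spec.n_timesteps):
        writer.write_timestep(t, values[t, ns : ns + nn, :])
    writer.close()
    return writer
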