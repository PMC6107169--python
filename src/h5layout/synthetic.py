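"""Synthetic cardiac-simulation output with known ground truth.

Produces the time × nodes × variables array a bidomain cardiac solver
would print — transmembrane potential V_m and extracellular potential
phi_e per node per printing time step — at configurable scale, with
known per-node activation times and peaks so post-processing can be
verified exactly.

The waveform is a deliberately simple action-potential surrogate, not a
biophysical cell model: each node rests at ``resting_potential`` until a
planar activation wave reaches it, jumps to ``peak_potential`` at its
activation step, then relaxes exponentially back toward rest with time
constant ``repolarization_tau`` (in printing steps).  phi_e is a scaled
mirror of V_m (−0.1 × V_m); any second variable suffices for I/O
purposes.  Its only job is to give the I/O and post-processing layers a
well-defined truth; it reproduces none of the spatial correlation,
upstroke morphology or repolarization heterogeneity of real output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "SimulationOutput",
    "generate",
    "dataset_bytes",
    "format_decimal_bytes",
    "BENCHMARK_NODES",
    "BENCHMARK_TIMESTEPS",
    "BENCHMARK_VARIABLES",
]

# Full-scale benchmark shape: 151 time slices (150 printing steps plus
# the initial state) over a ~3.25 M-node heart-torso mesh, two variables.
BENCHMARK_NODES = 3_253_316
BENCHMARK_TIMESTEPS = 151
BENCHMARK_VARIABLES = 2

PHI_E_SCALE = -0.1

VARIABLE_NAMES = ("V_m", "phi_e")
VARIABLE_UNITS = ("mV", "mV")


@dataclass(frozen=True)
class SyntheticParams:
    """Scale, waveform and noise parameters for the generator.

    ``activation_speed`` is the planar-wave speed in nodes per printing
    step; node ``i`` activates at step ``floor(i / activation_speed)``.
    The default (None) picks a speed at which the wave traverses all
    nodes within two thirds of the time window, so every node activates.
    """

    n_nodes: int
    n_timesteps: int = BENCHMARK_TIMESTEPS
    print_dt: float = 25e-6
    activation_speed: Optional[float] = None
    resting_potential: float = -85.0
    peak_potential: float = 40.0
    repolarization_tau: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_timesteps < 1:
            raise ValueError("n_nodes and n_timesteps must be >= 1")
        if self.print_dt <= 0:
            raise ValueError("print_dt must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.peak_potential <= self.resting_potential:
            raise ValueError("peak_potential must exceed resting_potential")
        if self.activation_speed is not None and self.activation_speed <= 0:
            raise ValueError("activation_speed must be positive")
        if self.repolarization_tau <= 0:
            raise ValueError("repolarization_tau must be positive")

    @property
    def effective_speed(self) -> float:
        if self.activation_speed is not None:
            return self.activation_speed
        span = max(1, (2 * self.n_timesteps) // 3)
        return max(1.0, self.n_nodes / span)


@dataclass(frozen=True)
class GroundTruth:
    """Per-node truth the generator guarantees: activation time and peak.

    ``activation_time`` is in seconds; NaN marks a node whose activation
    step falls outside the simulated window.
    """

    activation_time: np.ndarray
    peak_vm: np.ndarray


@dataclass(frozen=True)
class SimulationOutput:
    """In-memory time × nodes × variables block with variable metadata."""

    values: np.ndarray  # float64, shape (n_timesteps, n_nodes, 2)
    variable_names: tuple[str, ...] = VARIABLE_NAMES
    variable_units: tuple[str, ...] = VARIABLE_UNITS
    print_dt: float = 25e-6

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_variables(self) -> int:
        return self.values.shape[2]


def generate(params: SyntheticParams) -> tuple[SimulationOutput, GroundTruth]:
    """Generate one synthetic run; reproducible for a fixed seed."""
    t = np.arange(params.n_timesteps)[:, None]
    nodes = np.arange(params.n_nodes)[None, :]
    act_step = np.floor(nodes / params.effective_speed).astype(np.int64)

    elapsed = t - act_step
    amp = params.peak_potential - params.resting_potential
    vm = np.where(
        elapsed >= 0,
        params.resting_potential
        + amp * np.exp(-np.maximum(elapsed, 0) / params.repolarization_tau),
        params.resting_potential,
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        vm = vm + rng.normal(0.0, params.noise_sd, size=vm.shape)

    values = np.empty((params.n_timesteps, params.n_nodes, 2), dtype=np.float64)
    values[:, :, 0] = vm
    values[:, :, 1] = PHI_E_SCALE * vm

    act_step_1d = act_step[0]
    act_time = act_step_1d.astype(np.float64) * params.print_dt
    act_time[act_step_1d >= params.n_timesteps] = np.nan
    peak = np.where(
        act_step_1d < params.n_timesteps, params.peak_potential, params.resting_potential
    ).astype(np.float64)

    output = SimulationOutput(values=values, print_dt=params.print_dt)
    return output, GroundTruth(activation_time=act_time, peak_vm=peak)


def dataset_bytes(
    n_timesteps: int,
    n_nodes: int,
    n_variables: int = BENCHMARK_VARIABLES,
    element_size: int = 8,
) -> tuple[int, int]:
    """(bytes per printing step, total bytes) for a run of this shape.

    At full benchmark scale one step is 8 B × 3,253,316 × 2 ≈ 52.1 MB
    and 100 steps ≈ 5.21 GB (decimal units).
    """
    per_step = element_size * n_nodes * n_variables
    return per_step, per_step * n_timesteps


def format_decimal_bytes(n_bytes: int, sig_figs: int = 3) -> str:
    """Render a byte count in decimal kB/MB/GB/TB to 3 significant figures."""
    units = [("TB", 10**12), ("GB", 10**9), ("MB", 10**6), ("kB", 10**3)]
    for name, scale in units:
        if n_bytes >= scale:
            v = n_bytes / scale
            digits = max(0, sig_figs - 1 - int(math.floor(math.log10(v))))
            return f"{v:.{digits}f} {name}"
    return f"{n_bytes} B"
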