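"""Trajectory record: time-stamped snapshots and observable streams."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SystemState

__all__ = ["TrajectoryRecord"]


@dataclass
class TrajectoryRecord:
    """Output of a simulation run.

    Positions in ``snapshots`` are unwrapped (never folded into the box),
    so mean squared displacements can be computed directly; wrap modulo
    the box only when a wrapped view is needed.  Energy series are
    sampled every ``energy_stride`` steps, snapshots every
    ``snapshot_stride``; ``times`` / ``snapshot_times`` are in internal
    time units.
    """

    metadata: dict = field(default_factory=dict)
    times: list = field(default_factory=list)
    potential_energies: list = field(default_factory=list)
    kinetic_energies: list = field(default_factory=list)
    residual_g: list = field(default_factory=list)
    residual_p: list = field(default_factory=list)
    snapshot_times: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    observables: dict = field(default_factory=dict)
    unstable: bool = False
    abort_reason: str | None = None
    n_steps_completed: int = 0
    final_state: SystemState | None = None

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times)

    @property
    def potential_array(self) -> np.ndarray:
        return np.asarray(self.potential_energies)

    @property
    def kinetic_array(self) -> np.ndarray:
        return np.asarray(self.kinetic_energies)

    @property
    def snapshot_times_array(self) -> np.ndarray:
        return np.asarray(self.snapshot_times)

    @property
    def snapshot_array(self) -> np.ndarray:
        """Snapshots stacked to shape (n_frames, n_atoms, n_dim)."""
        return np.asarray(self.snapshots)

    @property
    def max_residual_g(self) -> float:
        return float(np.max(self.residual_g)) if self.residual_g else 0.0

    def observable_array(self, name: str) -> np.ndarray:
        return np.asarray(self.observables[name])
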