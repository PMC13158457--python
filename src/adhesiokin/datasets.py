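"""Replicate-level force-time observations for one experimental condition.

An :class:`AdhesionDataset` holds the raw extraction-force measurements for a
single condition: each observation is an adhesion time (minutes), a force
(piconewtons) and a replicate identifier.  All downstream stages (deterministic
SLS fit, hybrid PINN training, Bayesian inference, leave-one-out evaluation)
operate on these replicate-level points, never on per-time means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AdhesionDataset"]


@dataclass(frozen=True)
class AdhesionDataset:
    """Force-time observations for one condition.

    Parameters
    ----------
    condition
        Condition label (e.g. ``"fibroblast"``).
    times
        Adhesion times in minutes, one per observation. Must be >= 0.
    forces
        Extraction forces in piconewtons, one per observation.
    replicates
        Integer replicate identifier per observation.
    """

    condition: str
    times: np.ndarray
    forces: np.ndarray
    replicates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        forces = np.asarray(self.forces, dtype=float)
        if times.ndim != 1 or forces.ndim != 1:
            raise ValueError("times and forces must be one-dimensional")
        if times.size != forces.size:
            raise ValueError("times and forces must have equal length")
        if times.size == 0:
            raise ValueError("dataset must contain at least one observation")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(forces)):
            raise ValueError("times and forces must be finite")
        if np.any(times < 0):
            raise ValueError("adhesion times must be non-negative")
        reps = self.replicates
        if reps is None:
            reps = np.zeros(times.size, dtype=int)
        else:
            reps = np.asarray(reps, dtype=int)
            if reps.shape != times.shape:
                raise ValueError("replicates must match times in length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "forces", forces)
        object.__setattr__(self, "replicates", reps)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_distinct_times(self) -> int:
        return np.unique(self.times).size

    @property
    def t_max(self) -> float:
        return float(self.times.max())

    def subset(self, mask: np.ndarray) -> "AdhesionDataset":
        """Return the dataset restricted to a boolean or index mask."""
        return AdhesionDataset(
            condition=self.condition,
            times=self.times[mask],
            forces=self.forces[mask],
            replicates=self.replicates[mask],
        )

    def drop_observation(self, i: int) -> "AdhesionDataset":
        """Return a copy with observation ``i`` removed (leave-one-out fold)."""
        mask = np.ones(len(self), dtype=bool)
        mask[i] = False
        return self.subset(mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "time_min": self.times,
                "force_pN": self.forces,
                "replicate": self.replicates,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str) -> "AdhesionDataset":
        sub = df[df["condition"] == condition]
        return cls(
            condition=condition,
            times=sub["time_min"].to_numpy(dtype=float),
            forces=sub["force_pN"].to_numpy(dtype=float),
            replicates=sub["replicate"].to_numpy(dtype=int),
        )
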