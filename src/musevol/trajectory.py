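"""Generation-indexed model trajectories, mappable to calendar years."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["TimeMap", "TrajectoryState", "Trajectory"]


@dataclass(frozen=True)
class TimeMap:
    """Affine map from generation index to calendar year."""

    start_year: float
    years_per_generation: float

    def __post_init__(self) -> None:
        if self.years_per_generation <= 0:
            raise InvalidParameterError("years_per_generation must be positive")

    def year(self, generation: int) -> float:
        return self.start_year + generation * self.years_per_generation


@dataclass(frozen=True)
class TrajectoryState:
    """One generation of a model orbit: parameters plus moment view."""

    generation: int
    params: object  # BetaParams or LogNormalParams
    mu: float
    sigma: float

    @property
    def ratio(self) -> float:
        return self.sigma / self.mu


@dataclass
class Trajectory:
    """An orbit of a generational map.

    ``terminated`` flags an orbit that left the representable region
    before completing the requested number of generations; the states
    recorded up to the failure are kept and ``termination_reason``
    explains why iteration stopped.
    """

    states: list[TrajectoryState] = field(default_factory=list)
    model: str = "sce"
    time_map: Optional[TimeMap] = None
    terminated: bool = False
    termination_reason: Optional[str] = None

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i) -> TrajectoryState:
        return self.states[i]

    @property
    def generations(self) -> np.ndarray:
        return np.array([s.generation for s in self.states])

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mu for s in self.states])

    @property
    def sds(self) -> np.ndarray:
        return np.array([s.sigma for s in self.states])

    @property
    def ratios(self) -> np.ndarray:
        return self.sds / self.means

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: generation, shape params, mu, sigma, ratio, year."""
        rows = []
        for s in self.states:
            row = {"generation": s.generation, "model": self.model}
            d = s.params.to_dict()
            row.update(d)
            row.update({"mu": s.mu, "sigma": s.sigma, "ratio": s.sigma / s.mu})
            if self.time_map is not None:
                row["year"] = self.time_map.year(s.generation)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def series(self) -> pd.DataFrame:
        """Window-series-shaped view (mean/sd columns) for model fitting."""
        df = pd.DataFrame({"mean": self.means, "sd": self.sds})
        if self.time_map is not None:
            df.insert(0, "window_start", [self.time_map.year(g) for g in self.generations])
        return df
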