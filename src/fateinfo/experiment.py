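"""Core containers: one cell's record and a whole time-kill experiment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from fateinfo.config import SimulationConfig

#: Columns of the long-form cell table, in canonical order.
CELL_TABLE_COLUMNS = (
    "cell_id",
    "position_id",
    "initial_fluorescence",
    "initial_size",
    "growth_rate",
    "death_time_min",
    "censored",
)

COVARIATE_FIELDS = ("initial_fluorescence", "initial_size", "growth_rate")


class ValidationError(ValueError):
    """Raised when cell records violate the experiment contract."""


@dataclass(frozen=True)
class CellRecord:
    """One cell: initial covariates plus its (possibly censored) death time.

    ``death_time`` is in minutes from antibiotic addition and lies on
    the frame grid; ``None`` means the cell was still alive at the last
    frame (right-censored at movie end).
    """

    cell_id: str
    position_id: str
    initial_fluorescence: float
    death_time: float | None
    initial_size: float
    growth_rate: float

    @property
    def censored(self) -> bool:
        return self.death_time is None


@dataclass(frozen=True)
class Experiment:
    """A set of cells observed on a common frame grid.

    ``time_grid`` runs from 0 to the movie end in steps of the frame
    interval.  ``config`` is the generating :class:`SimulationConfig`
    for synthetic data and ``None`` for imported real data.
    """

    cells: tuple[CellRecord, ...]
    time_grid: np.ndarray
    config: SimulationConfig | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        grid = np.asarray(self.time_grid, dtype=float)
        object.__setattr__(self, "time_grid", grid)
        self.validate()

    def validate(self) -> None:
        if len(self.cells) == 0:
            raise ValidationError("experiment contains no cells")
        grid = self.time_grid
        if grid.ndim != 1 or len(grid) < 2 or not np.all(np.diff(grid) > 0):
            raise ValidationError("time_grid must be a strictly increasing 1-D grid")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate cell_id values: {dupes[:5]}")
        grid_set = set(np.round(grid, 9))
        for c in self.cells:
            if c.death_time is not None:
                if c.death_time <= 0:
                    raise ValidationError(
                        f"cell {c.cell_id}: death_time must be > 0, got {c.death_time}"
                    )
                if round(float(c.death_time), 9) not in grid_set:
                    raise ValidationError(
                        f"cell {c.cell_id}: death_time {c.death_time} not on the frame grid"
                    )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    @property
    def position_ids(self) -> list[str]:
        return [c.position_id for c in self.cells]

    def covariate(self, name: str) -> np.ndarray:
        """Per-cell values of a named initial covariate, in cell order."""
        if name not in COVARIATE_FIELDS:
            raise ValidationError(
                f"unknown covariate {name!r}; expected one of {COVARIATE_FIELDS}"
            )
        return np.array([getattr(c, name) for c in self.cells], dtype=float)

    def death_times(self) -> np.ndarray:
        """Death times in minutes; NaN for censored (never-dying) cells."""
        return np.array(
            [np.nan if c.death_time is None else c.death_time for c in self.cells],
            dtype=float,
        )

    def death_state_matrix(self) -> np.ndarray:
        """Boolean (n_cells, n_frames) matrix: is cell i dead at frame t.

        Death exactly at frame t counts as dead at t (closed boundary);
        censored cells are alive through the final frame.
        """
        dt = self.death_times()[:, None]
        with np.errstate(invalid="ignore"):
            dead = dt <= self.time_grid[None, :] + 1e-9
        dead[np.isnan(dt[:, 0])] = False
        return dead

    def to_frame(self) -> pd.DataFrame:
        """Long-form cell table as a DataFrame (one row per cell)."""
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "position_id": self.position_ids,
                "initial_fluorescence": self.covariate("initial_fluorescence"),
                "initial_size": self.covariate("initial_size"),
                "growth_rate": self.covariate("growth_rate"),
                "death_time_min": self.death_times(),
                "censored": np.array([int(c.censored) for c in self.cells]),
            }
        )
        return df[list(CELL_TABLE_COLUMNS)]

    @classmethod
    def from_records(
        cls,
        cells: Iterable[CellRecord],
        time_grid: Sequence[float] | np.ndarray,
        config: SimulationConfig | None = None,
        provenance: str = "",
    ) -> "Experiment":
        return cls(
            cells=tuple(cells),
            time_grid=np.asarray(time_grid, dtype=float),
            config=config,
            provenance=provenance,
        )


def make_time_grid(movie_length: float, frame_interval: float) -> np.ndarray:
    """Frame grid 0, dt, 2*dt, ..., movie_length (inclusive)."""
    n = int(round(movie_length / frame_interval))
    return np.arange(n + 1, dtype=float) * float(frame_interval)
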