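"""Reading and writing the long-form cell table (CSV).

One row per cell with columns ``cell_id, position_id,
initial_fluorescence, initial_size, growth_rate, death_time_min,
censored``.  Censored cells (alive at movie end) carry an empty
``death_time_min`` field and ``censored = 1``.  UTF-8, '.' decimal
separator, mandatory header.  The round trip write -> read -> write is
lossless and byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from fateinfo.config import SimulationConfig
from fateinfo.experiment import (
    CELL_TABLE_COLUMNS,
    CellRecord,
    Experiment,
    ValidationError,
    make_time_grid,
)


class ParseError(ValueError):
    """Raised when a cell table cannot be parsed; names the offending line."""


def write_cell_table(experiment: Experiment, path: str | Path) -> Path:
    """Write the experiment's cell table to ``path`` as CSV."""
    path = Path(path)
    df = experiment.to_frame()
    # repr-based float formatting: shortest round-trip representation
    df.to_csv(path, index=False, na_rep="")
    return path


def read_cell_table(
    path: str | Path,
    frame_interval: float | None = None,
    movie_length: float | None = None,
    config: SimulationConfig | None = None,
) -> Experiment:
    """Read a cell table CSV into an :class:`Experiment`.

    The CSV stores no frame-grid metadata, so the grid is supplied via
    ``frame_interval`` / ``movie_length`` (or a ``config`` carrying
    both).  When omitted, the interval defaults to 5 min and the movie
    length to the largest observed death time rounded up to a multiple
    of the interval (at least 300 min).
    """
    path = Path(path)
    if config is not None:
        frame_interval = config.frame_interval
        movie_length = config.movie_length
    try:
        df = pd.read_csv(
            path,
            dtype={"cell_id": str, "position_id": str},
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(CELL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()
        raise ValidationError(f"{path}: duplicate cell_id values: {list(dupes[:5])}")

    cells: list[CellRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is header
        censored = row.censored
        if censored not in (0, 1):
            raise ParseError(f"{path} line {i}: censored must be 0 or 1, got {censored!r}")
        death = row.death_time_min
        if censored == 1:
            if not (isinstance(death, float) and np.isnan(death)):
                raise ParseError(
                    f"{path} line {i}: censored cell must have empty death_time_min"
                )
            death_val = None
        else:
            if death is None or (isinstance(death, float) and np.isnan(death)):
                raise ParseError(
                    f"{path} line {i}: non-censored cell lacks death_time_min"
                )
            death_val = float(death)
        try:
            cells.append(
                CellRecord(
                    cell_id=str(row.cell_id),
                    position_id=str(row.position_id),
                    initial_fluorescence=float(row.initial_fluorescence),
                    death_time=death_val,
                    initial_size=float(row.initial_size),
                    growth_rate=float(row.growth_rate),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc

    if frame_interval is None:
        frame_interval = 5.0
    if movie_length is None:
        deaths = [c.death_time for c in cells if c.death_time is not None]
        longest = max(deaths, default=0.0)
        movie_length = max(300.0, np.ceil(longest / frame_interval) * frame_interval)

    return Experiment.from_records(
        cells,
        make_time_grid(movie_length, frame_interval),
        config=config,
        provenance=f"read from {path.name}",
    )
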