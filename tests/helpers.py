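"""Small constructors for hand-built experiments used across tests."""

from __future__ import annotations

import numpy as np

from fateinfo.experiment import CellRecord, Experiment, make_time_grid


def build_experiment(
    death_times: list[float | None],
    fluorescence: list[float] | None = None,
    frame_interval: float = 5.0,
    movie_length: float | None = None,
    position_ids: list[str] | None = None,
    sizes: list[float] | None = None,
    growth_rates: list[float] | None = None,
) -> Experiment:
    """Experiment from explicit death times (None = censored).

    Fluorescence defaults to 1, 2, 3, ... so cell order is also
    fluorescence rank order.
    """
    n = len(death_times)
    if fluorescence is None:
        fluorescence = [float(i + 1) for i in range(n)]
    if movie_length is None:
        observed = [t for t in death_times if t is not None]
        longest = max(observed, default=frame_interval)
        movie_length = np.ceil(longest / frame_interval) * frame_interval
    if position_ids is None:
        position_ids = ["pos00"] * n
    if sizes is None:
        sizes = [3.0] * n
    if growth_rates is None:
        growth_rates = [0.02] * n
    cells = [
        CellRecord(
            cell_id=f"c{i:04d}",
            position_id=position_ids[i],
            initial_fluorescence=float(fluorescence[i]),
            death_time=death_times[i],
            initial_size=float(sizes[i]),
            growth_rate=float(growth_rates[i]),
        )
        for i in range(n)
    ]
    return Experiment.from_records(cells, make_time_grid(movie_length, frame_interval))


def rank_order_experiment(
    n: int = 100, frame_interval: float = 5.0
) -> Experiment:
    """Cells die one per frame in exact fluorescence-rank order."""
    deaths = [frame_interval * (i + 1) for i in range(n)]
    return build_experiment(deaths, frame_interval=frame_interval)
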