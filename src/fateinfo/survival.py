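"""Population killing curves and per-bin cumulative-death heatmaps."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fateinfo.binning import BinAssignment
from fateinfo.experiment import Experiment, ValidationError


@dataclass(frozen=True)
class KillingCurve:
    """Cumulative dead fraction of the population at every frame.

    ``by_position`` holds one curve per replicate microscopy position;
    ``sd_across_positions`` is the pointwise population SD across those
    replicate curves (zero when there is a single position).
    """

    time_grid: np.ndarray
    dead_fraction: np.ndarray
    by_position: dict[str, np.ndarray]
    sd_across_positions: np.ndarray

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            {
                "time_min": self.time_grid,
                "dead_fraction": self.dead_fraction,
                "sd_across_positions": self.sd_across_positions,
            }
        )
        df.to_csv(path, sep="\t", index=False)
        return path


@dataclass(frozen=True)
class FateMatrix:
    """Per-bin cumulative dead fraction over time (the decile heatmap).

    Row i is the killing curve of covariate bin i (low to high); every
    row is non-decreasing in time and bounded in [0, 1].
    """

    values: np.ndarray  # (n_bins, n_frames)
    time_grid: np.ndarray
    bin_sizes: np.ndarray
    covariate_name: str

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            self.values, columns=[f"{t:g}" for t in self.time_grid]
        )
        df.insert(0, "bin_index", np.arange(self.n_bins))
        df.to_csv(path, sep="\t", index=False)
        return path


def _cumulative_dead_fraction(experiment: Experiment, mask: np.ndarray) -> np.ndarray:
    """Dead fraction over the frame grid among cells selected by ``mask``."""
    dead = experiment.death_state_matrix()[mask]
    return dead.mean(axis=0)


def killing_curve(experiment: Experiment) -> KillingCurve:
    """Population killing curve: fraction of cells dead at each frame.

    Censored cells count as alive at every frame.  Per-position curves
    and their pointwise SD quantify replicate-to-replicate variation.
    """
    n = experiment.n_cells
    dead = experiment.death_state_matrix()
    overall = dead.mean(axis=0)

    positions = np.asarray(experiment.position_ids)
    by_position: dict[str, np.ndarray] = {}
    for pos in dict.fromkeys(positions):  # preserve order
        by_position[pos] = dead[positions == pos].mean(axis=0)

    if len(by_position) > 1:
        sd = np.std(np.stack(list(by_position.values())), axis=0, ddof=0)
    else:
        sd = np.zeros_like(overall)

    return KillingCurve(
        time_grid=experiment.time_grid,
        dead_fraction=overall,
        by_position=by_position,
        sd_across_positions=sd,
    )


def fate_matrix(experiment: Experiment, bins: BinAssignment) -> FateMatrix:
    """Per-bin cumulative dead fractions: the Fig.-style decile heatmap.

    Row i, column t is the fraction of bin-i cells dead at frame t.
    The bin-size-weighted mean of the rows reproduces the overall
    killing curve exactly (conservation).
    """
    bin_idx = bins.indices_for(experiment)
    sizes = np.bincount(bin_idx, minlength=bins.n_bins)
    if np.any(sizes == 0):
        empty = np.flatnonzero(sizes == 0)
        raise ValidationError(f"empty bins: {empty.tolist()}")

    dead = experiment.death_state_matrix()
    n_frames = dead.shape[1]
    counts = np.zeros((bins.n_bins, n_frames))
    np.add.at(counts, bin_idx, dead.astype(float))
    values = counts / sizes[:, None]
    return FateMatrix(
        values=values,
        time_grid=experiment.time_grid,
        bin_sizes=sizes,
        covariate_name=bins.covariate_name,
    )
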