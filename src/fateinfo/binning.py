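"""Equal-frequency (decile) binning of cells by an initial covariate.

Cells are ranked by the covariate from low to high and split so each
bin holds the same number of cells (10% per bin for deciles).  A random
regrouping with the same bin sizes provides the permutation-null
counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fateinfo.experiment import Experiment, ValidationError


@dataclass(frozen=True)
class BinAssignment:
    """Mapping from cells to equal-frequency bins.

    Bin 0 holds the lowest covariate values; sizes differ by at most
    one, with remainder cells placed in the lowest-index bins.
    """

    n_bins: int
    bin_of: dict[str, int]
    covariate_name: str

    def sizes(self) -> np.ndarray:
        counts = np.zeros(self.n_bins, dtype=int)
        for b in self.bin_of.values():
            counts[b] += 1
        return counts

    def indices_for(self, experiment: Experiment) -> np.ndarray:
        """Per-cell bin index aligned with the experiment's cell order."""
        try:
            return np.array([self.bin_of[cid] for cid in experiment.cell_ids])
        except KeyError as exc:
            raise ValidationError(f"bin assignment missing cell {exc.args[0]!r}") from exc

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"cell_id": list(self.bin_of), "bin_index": list(self.bin_of.values())}
        ).to_csv(path, index=False)
        return path


def _bin_sizes(n_cells: int, n_bins: int) -> np.ndarray:
    """Equal-frequency sizes; remainder goes to the lowest-index bins."""
    base, rem = divmod(n_cells, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    return sizes


def _check(n_cells: int, n_bins: int) -> None:
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    if n_bins > n_cells:
        raise ValidationError(f"n_bins ({n_bins}) exceeds number of cells ({n_cells})")


def rank_and_bin(
    experiment: Experiment, covariate: str = "initial_fluorescence", n_bins: int = 10
) -> BinAssignment:
    """Rank cells by a covariate (low to high) and split into equal-count bins.

    Positions are pooled before binning.  Ties in the covariate are
    broken by the cells' stable input order, so the assignment is
    deterministic.  The result depends on the covariate only through
    its ranks: any strictly increasing transform yields the same bins.
    """
    values = experiment.covariate(covariate)
    if not np.all(np.isfinite(values)):
        bad = [experiment.cell_ids[i] for i in np.flatnonzero(~np.isfinite(values))[:5]]
        raise ValidationError(f"non-finite {covariate} for cells {bad}")
    _check(len(values), n_bins)

    order = np.argsort(values, kind="stable")
    sizes = _bin_sizes(len(values), n_bins)
    bin_by_rank = np.repeat(np.arange(n_bins), sizes)
    bin_of_cell = np.empty(len(values), dtype=int)
    bin_of_cell[order] = bin_by_rank
    ids = experiment.cell_ids
    return BinAssignment(
        n_bins=n_bins,
        bin_of={ids[i]: int(bin_of_cell[i]) for i in range(len(ids))},
        covariate_name=covariate,
    )


def random_grouping(
    experiment: Experiment,
    n_bins: int = 10,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> BinAssignment:
    """Uniformly random partition of cells into the same bin sizes.

    This is the permutation-null counterpart of :func:`rank_and_bin`:
    bin sizes are identical, but membership is independent of every
    covariate.  Fixing the seed fixes the assignment.
    """
    n = experiment.n_cells
    _check(n, n_bins)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = _bin_sizes(n, n_bins)
    bin_by_slot = np.repeat(np.arange(n_bins), sizes)
    bin_of_cell = np.empty(n, dtype=int)
    bin_of_cell[perm] = bin_by_slot
    ids = experiment.cell_ids
    return BinAssignment(
        n_bins=n_bins,
        bin_of={ids[i]: int(bin_of_cell[i]) for i in range(n)},
        covariate_name="random",
    )
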