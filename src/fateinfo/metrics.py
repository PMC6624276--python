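"""Killing-time summaries and cross-promoter statistics.

Time to 50% killing per decile, its Savitzky-Golay-smoothed max-min
spread, promoter strength/noise statistics (mean and coefficient of
variation of initial fluorescence), and correlations of peak
information with those statistics across a promoter panel.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

from fateinfo.experiment import Experiment
from fateinfo.survival import FateMatrix, KillingCurve

logger = logging.getLogger(__name__)


class _Unreached:
    """Sentinel: a killing curve that never attains the target fraction."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNREACHED"


UNREACHED = _Unreached()


def time_to_fraction_dead(
    curve: KillingCurve | np.ndarray,
    fraction: float = 0.5,
    time_grid: np.ndarray | None = None,
):
    """First frame (minutes) at which the dead fraction reaches ``fraction``.

    Accepts a :class:`KillingCurve` or a raw dead-fraction array with
    an explicit ``time_grid``.  Returns :data:`UNREACHED` when the
    curve never attains the fraction (e.g., all cells censored).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if isinstance(curve, KillingCurve):
        values, grid = curve.dead_fraction, curve.time_grid
    else:
        values = np.asarray(curve, dtype=float)
        if time_grid is None:
            raise ValueError("time_grid required when passing a raw array")
        grid = np.asarray(time_grid, dtype=float)
    hits = np.flatnonzero(values >= fraction - 1e-12)
    if hits.size == 0:
        return UNREACHED
    return float(grid[hits[0]])


@dataclass(frozen=True)
class DecileSpread:
    """Per-bin time to 50% killing and its smoothed max-min spread.

    ``time_to_half_by_bin`` is NaN for bins that never reach the target
    fraction; those bins are excluded from smoothing and spread.
    """

    time_to_half_by_bin: np.ndarray
    smoothed: np.ndarray
    spread: float
    window: int
    polyorder: int
    fraction: float

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {
                "bin_index": np.arange(len(self.time_to_half_by_bin)),
                "time_to_half_min": self.time_to_half_by_bin,
                "smoothed_min": self.smoothed,
            }
        ).to_csv(path, sep="\t", index=False, na_rep="")
        return path

    def summary_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "spread_min": self.spread,
            "window": self.window,
            "polyorder": self.polyorder,
            "fraction": self.fraction,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def decile_spread(
    matrix: FateMatrix,
    window: int = 5,
    polyorder: int = 2,
    fraction: float = 0.5,
) -> DecileSpread:
    """Spread in time-to-50%-killing between the fastest and slowest bins.

    Per-bin first-crossing times are smoothed across bin index with a
    Savitzky-Golay filter (window 5, order 2 by default) before taking
    max minus min, so a single outlier decile does not dominate the
    spread.  ``window`` must be odd and greater than ``polyorder``;
    window 1 with order 0 is the identity filter.  Bins that never
    reach the target fraction are excluded with a logged warning.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"window must be odd and > polyorder, got window={window}, polyorder={polyorder}"
        )
    crossing = np.empty(matrix.n_bins)
    for i, row in enumerate(matrix.values):
        t = time_to_fraction_dead(row, fraction, matrix.time_grid)
        crossing[i] = np.nan if t is UNREACHED else t
    valid = ~np.isnan(crossing)
    if np.sum(valid) == 0:
        raise ValueError("no bin reaches the target dead fraction")
    if not np.all(valid):
        skipped = np.flatnonzero(~valid).tolist()
        logger.warning(
            "bins %s never reach %.0f%% death; excluded from spread", skipped, 100 * fraction
        )
    if np.sum(valid) < window:
        raise ValueError(
            f"only {int(np.sum(valid))} bins reach the target fraction; "
            f"need at least window={window}"
        )
    smoothed_valid = savgol_filter(crossing[valid], window, polyorder)
    smoothed = np.full_like(crossing, np.nan)
    smoothed[valid] = smoothed_valid
    return DecileSpread(
        time_to_half_by_bin=crossing,
        smoothed=smoothed,
        spread=float(np.nanmax(smoothed) - np.nanmin(smoothed)),
        window=window,
        polyorder=polyorder,
        fraction=fraction,
    )


@dataclass(frozen=True)
class PromoterStats:
    """Promoter strength (mean fluorescence) and noise (CV)."""

    mean_fluorescence: float
    cv: float


def promoter_statistics(experiment: Experiment, ddof: int = 0) -> PromoterStats:
    """Mean and coefficient of variation of initial fluorescence.

    CV uses the population (ddof=0) standard deviation by default.
    For a log-normal promoter with log-SD sigma, CV converges to
    sqrt(exp(sigma^2) - 1) at large N.
    """
    f = experiment.covariate("initial_fluorescence")
    mean = float(f.mean())
    return PromoterStats(mean_fluorescence=mean, cv=float(f.std(ddof=ddof) / mean))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson and Spearman coefficients (NaN when undefined)."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def cross_promoter_correlation(
    peaks: Sequence[float], values: Sequence[float]
) -> CorrelationResult:
    """Correlate per-promoter peak information with a promoter statistic.

    Both Pearson and Spearman coefficients are reported.  Constant
    inputs make the correlation undefined; the coefficients are then
    NaN rather than an error.  Requires at least 3 promoters.
    """
    peaks = np.asarray(peaks, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(peaks) != len(values):
        raise ValueError("peaks and values must have the same length")
    if len(peaks) < 3:
        raise ValueError(f"need at least 3 promoters, got {len(peaks)}")
    if np.ptp(peaks) == 0 or np.ptp(values) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pr = stats.pearsonr(peaks, values)
        sr = stats.spearmanr(peaks, values)
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )
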