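"""Sub-batch resampling: the empirical counterpart of the model.

Random sub-batches are drawn (without replacement) from a full batch of
samples and the union gap-site count of each is recorded.  A loess fit of
count against sub-batch size gives the empirical saturation curve; its
terminal slope is the basal observation rate (*gbr*) — the roughly
constant number of new gap-sites contributed by each added sample once the
batch is large, dominated in practice by uniquely observed sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .junction_io import SampleJunctions
from .model import PredictionCurve, predict_curve

__all__ = [
    "SubsampleResult",
    "SmoothedCurve",
    "UniqueEventStats",
    "draw_subbatches",
    "smooth_curve",
    "terminal_slope",
    "unique_event_stats",
    "median_relative_deviation",
    "fit_virtual_multiplicity",
]


@dataclass(frozen=True)
class SubsampleResult:
    """One resampling draw: sub-batch size and its union gap-site count."""

    replicate: int
    nu: int
    observed: int
    sample_ids: tuple[str, ...]


@dataclass(frozen=True)
class SmoothedCurve:
    """Loess-smoothed mean observed count per sub-batch size.

    Defined only on the range of sizes actually resampled; no
    extrapolation.
    """

    nu: np.ndarray
    mean_observed: np.ndarray
    span: float

    def __post_init__(self):
        object.__setattr__(self, "nu", np.asarray(self.nu, dtype=int))
        object.__setattr__(
            self, "mean_observed", np.asarray(self.mean_observed, dtype=float)
        )


@dataclass(frozen=True)
class UniqueEventStats:
    """Summary of uniquely observed (multiplicity-1) gap-sites."""

    total_unique: int
    per_sample_mean: float
    per_sample_sd: float
    fraction_of_gbr: Optional[float] = None


def _presence_matrix(samples: Sequence[SampleJunctions]) -> np.ndarray:
    """Boolean site x sample presence matrix over the union of all sites."""
    index: dict = {}
    for s in samples:
        for key in s.sites:
            if key not in index:
                index[key] = len(index)
    mat = np.zeros((len(index), len(samples)), dtype=bool)
    for col, s in enumerate(samples):
        rows = [index[key] for key in s.sites]
        mat[rows, col] = True
    return mat


def draw_subbatches(
    samples: Sequence[SampleJunctions],
    n_reps: int = 200,
    size_range: Optional[tuple[int, int]] = None,
    seed: int = 0,
) -> list[SubsampleResult]:
    """Draw random sub-batches and count their union gap-sites.

    For each of ``n_reps`` replicates a size ``nu`` is drawn uniformly from
    ``size_range`` (inclusive; default ``(2, n-1)``) and ``nu`` samples are
    drawn uniformly without replacement.  One deterministic single-sample
    (``nu=1``) result per sample is appended afterwards, so the smallest
    batch size is always represented.  Fully reproducible given ``seed``.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to subsample")
    if size_range is None:
        size_range = (2, n - 1)
    lo, hi = size_range
    if not 1 <= lo <= hi <= n:
        raise ValueError(f"size_range {size_range} outside 1..{n}")
    rng = np.random.default_rng(seed)
    mat = _presence_matrix(samples)
    ids = np.array([s.sample_id for s in samples])
    results: list[SubsampleResult] = []
    for rep in range(n_reps):
        nu = int(rng.integers(lo, hi + 1))
        cols = rng.choice(n, size=nu, replace=False)
        observed = int(mat[:, cols].any(axis=1).sum())
        results.append(
            SubsampleResult(rep, nu, observed, tuple(sorted(ids[cols])))
        )
    for k, s in enumerate(samples):
        results.append(
            SubsampleResult(n_reps + k, 1, len(s.sites), (s.sample_id,))
        )
    return results


def smooth_curve(results: Sequence[SubsampleResult], span: float = 0.75) -> SmoothedCurve:
    """Loess regression of observed count on sub-batch size.

    Locally weighted linear regression with tricube weights and one
    robustness iteration, evaluated at each integer size present in
    ``results``.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    nu = np.array([r.nu for r in results], dtype=float)
    obs = np.array([r.observed for r in results], dtype=float)
    grid = np.unique(nu)
    if len(results) < 10 or grid.size < 3:
        raise ValueError("need >= 10 results spanning >= 3 distinct sizes")
    fitted = lowess(obs, nu, frac=span, it=1, xvals=grid)
    return SmoothedCurve(nu=grid, mean_observed=fitted, span=span)


def terminal_slope(curve: SmoothedCurve, window_start: Optional[int] = None) -> float:
    """Basal observation rate: OLS slope of the curve's terminal window.

    The window runs from ``window_start`` to the largest evaluated size.
    By default it starts at 40 when the curve reaches size >= 50
    (appropriate for batches of ~54), otherwise at the top quarter of the
    evaluated range.
    """
    nu_max = int(curve.nu.max())
    if window_start is None:
        window_start = 40 if nu_max >= 50 else int(np.ceil(nu_max * 0.75))
    mask = curve.nu >= window_start
    if mask.sum() < 3:
        raise ValueError(
            f"terminal window [{window_start}, {nu_max}] has <3 points"
        )
    slope, _ = np.polyfit(curve.nu[mask], curve.mean_observed[mask], 1)
    return float(slope)


def unique_event_stats(
    samples: Sequence[SampleJunctions], gbr: Optional[float] = None
) -> UniqueEventStats:
    """Count uniquely observed gap-sites and summarise them per sample.

    A site is *unique* iff its whole-batch multiplicity is 1.  Per-sample
    unique counts are summarised by mean and sample standard deviation;
    when a basal rate ``gbr`` is supplied, the mean is also expressed as a
    fraction of it.
    """
    if len(samples) < 2:
        raise ValueError("uniqueness is degenerate for a single sample")
    counts: dict = {}
    for s in samples:
        for key in s.sites:
            counts[key] = counts.get(key, 0) + 1
    unique = {key for key, c in counts.items() if c == 1}
    per_sample = np.array([len(s.sites & unique) for s in samples], dtype=float)
    mean = float(per_sample.mean())
    sd = float(per_sample.std(ddof=1))
    frac = mean / gbr if gbr else None
    return UniqueEventStats(len(unique), mean, sd, frac)


def median_relative_deviation(
    predicted: PredictionCurve, smoothed: SmoothedCurve
) -> float:
    """Median relative gap between model and empirical curves, in percent.

    Computed over the batch sizes both curves evaluate:
    ``median(100 * |predicted - smoothed| / smoothed)``.
    """
    shared, ip, is_ = np.intersect1d(predicted.nu, smoothed.nu, return_indices=True)
    if shared.size == 0:
        raise ValueError("curves share no evaluation points")
    pred = predicted.expected[ip]
    smo = smoothed.mean_observed[is_]
    return float(np.median(100.0 * np.abs(pred - smo) / smo))


def fit_virtual_multiplicity(
    spectrum,
    smoothed: SmoothedCurve,
    grid: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Grid-search the virtual multiplicity against an empirical curve.

    The virtual count is always calibrated so the corrected prediction
    recovers the full-batch total; ``mu_v`` is then the one free shape
    parameter.  This picks the grid value minimising the median relative
    deviation from ``smoothed`` and returns ``(mu_v, deviation_pct)``.
    """
    if grid is None:
        grid = np.arange(0.05, 1.0, 0.05)
    best = None
    nu_values = [int(v) for v in smoothed.nu]
    for mu_v in grid:
        curve = predict_curve(spectrum, nu_values, corrected=True, mu_v=float(mu_v))
        dev = median_relative_deviation(curve, smoothed)
        if best is None or dev < best[1]:
            best = (float(mu_v), dev)
    return best
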