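"""Permutation point-of-stability analysis with a corridor of stability.

Given one observation per subject, the question is: how many subjects are
needed before the subsample mean settles?  For each subsample size s from
1 to N, draw many random subsamples, and record the spread (band) of their
means.  A *corridor of stability* is an interval around the full-sample
estimate; the *point of stability* (POS) is the smallest s at which
subsample means enter the corridor and do not leave it at any larger size.

Because the corridor construction and the stability criterion both admit
several readings, each is explicit configuration:

corridor_method
    ``sample_percentile`` — the (5th, 95th) percentiles of the raw values
    (linear interpolation between closest ranks).  Note this corridor is
    wide: it contains ~90% of single observations, so subsample-mean bands
    tend to sit inside it from very small sizes.
    ``mean_relative_width`` — ``mean * (1 -/+ w)``, a +/- w relative band
    around the full-sample mean (default w = 0.05).  This is the reading
    that produces POS values of the several-tens magnitude on cohorts with
    a coefficient of variation near 0.2.
    ``mean_ci`` — ``mean -/+ z * sd / sqrt(N)``, the normal-theory CI of
    the full-sample mean.

criterion
    ``band_within_corridor`` — at each size, draw ``reps_per_size``
    independent subsamples; POS is the smallest s whose (5th, 95th)
    percentile band of subsample means lies inside the corridor for all
    sizes >= s.
    ``trajectory_quantile`` — draw ``reps_per_size`` accumulation
    trajectories (one growing subsample each); each trajectory has its own
    POS (smallest s with the running mean inside the corridor from s on),
    and the reported POS is a quantile (default 95th) of the per-trajectory
    values.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StabilityConfig",
    "StabilityResult",
    "subsample_means",
    "build_corridor",
    "subsample_band_table",
    "pos_from_band_table",
    "point_of_stability",
    "analytic_pos_gaussian",
]

_TRAJECTORY_STREAM = 0  # sizes start at 1, so spawn key 0 is free


@dataclass(frozen=True)
class StabilityConfig:
    """Configuration of one point-of-stability analysis."""

    reps_per_size: int = 10_000
    min_size: int = 1
    max_size: int | None = None  # None = N
    sampling: str = "without_replacement"
    corridor_method: str = "sample_percentile"
    corridor_percentiles: tuple[float, float] = (5.0, 95.0)
    relative_width: float = 0.05
    ci_level: float = 0.95
    criterion: str = "band_within_corridor"
    band_percentiles: tuple[float, float] = (5.0, 95.0)
    trajectory_quantile: float = 95.0
    seed: int = 0

    def validate(self, n_values: int) -> None:
        if self.reps_per_size < 1:
            raise ValueError("reps_per_size must be >= 1")
        max_size = self.max_size if self.max_size is not None else n_values
        if not 1 <= self.min_size <= max_size:
            raise ValueError(
                f"need 1 <= min_size <= max_size, got ({self.min_size}, {max_size})"
            )
        if self.sampling == "without_replacement" and max_size > n_values:
            raise ValueError(
                f"max_size {max_size} exceeds N = {n_values} for sampling without replacement"
            )
        if self.sampling not in ("without_replacement", "with_replacement"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.corridor_method not in ("sample_percentile", "mean_relative_width", "mean_ci"):
            raise ValueError(f"unknown corridor method {self.corridor_method!r}")
        if self.criterion not in ("band_within_corridor", "trajectory_quantile"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        for lo, hi in (self.corridor_percentiles, self.band_percentiles):
            if not 0 <= lo < hi <= 100:
                raise ValueError(f"percentile bounds must be ordered in [0, 100], got ({lo}, {hi})")
        if not 0 < self.relative_width:
            raise ValueError("relative_width must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class StabilityResult:
    """Corridor bounds, the per-size subsample-mean table, and the POS.

    ``table`` columns: size, mean_of_means, band_lo, band_hi,
    inside_corridor.  ``pos`` is None when stability is never reached
    within [min_size, max_size] (``reached`` False).
    """

    corridor: tuple[float, float]
    table: pd.DataFrame
    pos: int | None
    reached: bool
    config: StabilityConfig

    @property
    def percentile_definition(self) -> str:
        return "linear interpolation between closest ranks (numpy default)"


def subsample_means(
    values: Sequence[float],
    size: int,
    reps: int,
    sampling: str = "without_replacement",
    seed: int = 0,
) -> np.ndarray:
    """Means of ``reps`` random subsamples of ``size`` observations.

    Deterministic given ``seed``: the random stream is derived from
    (seed, size), so results do not depend on the order in which sizes
    are evaluated.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if size < 1:
        raise ValueError("size must be >= 1")
    if sampling == "without_replacement" and size > n:
        raise ValueError(f"subsample size {size} exceeds N = {n} without replacement")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(size,)))
    if sampling == "without_replacement":
        if size == n:
            return np.full(reps, vals.mean())
        u = rng.random((reps, n))
        idx = np.argpartition(u, size - 1, axis=1)[:, :size]
    elif sampling == "with_replacement":
        idx = rng.integers(0, n, size=(reps, size))
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    return vals[idx].mean(axis=1)


def build_corridor(values: Sequence[float], config: StabilityConfig) -> tuple[float, float]:
    """Corridor of stability for the given observations under ``config``."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError(f"need >= 2 values to build a corridor, got {vals.size}")
    if config.corridor_method == "sample_percentile":
        lo, hi = np.percentile(vals, config.corridor_percentiles)
    elif config.corridor_method == "mean_relative_width":
        mean = vals.mean()
        w = config.relative_width
        lo, hi = mean * (1.0 - w), mean * (1.0 + w)
    else:  # mean_ci
        mean = vals.mean()
        z = stats.norm.ppf(0.5 + config.ci_level / 2.0)
        half = z * vals.std(ddof=1) / np.sqrt(vals.size)
        lo, hi = mean - half, mean + half
    if lo == hi and np.ptp(vals) > 0:
        raise ValueError(
            "degenerate (zero-width) corridor on non-constant data; widen the corridor"
        )
    return float(lo), float(hi)


def _sizes(config: StabilityConfig, n: int) -> np.ndarray:
    max_size = config.max_size if config.max_size is not None else n
    return np.arange(config.min_size, max_size + 1)


def subsample_band_table(values: Sequence[float], config: StabilityConfig) -> pd.DataFrame:
    """Per-size subsample-mean summaries for the band criterion.

    Columns: size, mean_of_means, band_lo, band_hi.  One independent
    random stream per size, derived from ``config.seed``.
    """
    vals = np.asarray(values, dtype=float)
    config.validate(vals.size)
    rows = []
    for size in _sizes(config, vals.size):
        means = subsample_means(
            vals, int(size), config.reps_per_size, config.sampling, config.seed
        )
        lo, hi = np.percentile(means, config.band_percentiles)
        rows.append((int(size), float(means.mean()), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["size", "mean_of_means", "band_lo", "band_hi"])


def _corridor_tol(lo: float, hi: float) -> float:
    # closed-boundary comparisons up to float roundoff, so that e.g. the
    # mean of k identical values tests as inside a zero-width corridor
    return 1e-12 * max(abs(lo), abs(hi), 1.0)


def pos_from_band_table(table: pd.DataFrame, corridor: tuple[float, float]) -> int | None:
    """Smallest size whose band lies inside the corridor at every size >= it."""
    lo, hi = corridor
    tol = _corridor_tol(lo, hi)
    inside = (table["band_lo"].to_numpy() >= lo - tol) & (
        table["band_hi"].to_numpy() <= hi + tol
    )
    stable_from = np.flip(np.logical_and.accumulate(np.flip(inside)))
    if not stable_from.any():
        return None
    return int(table["size"].to_numpy()[np.argmax(stable_from)])


def _trajectory_running_means(
    vals: np.ndarray, config: StabilityConfig
) -> np.ndarray:
    """(reps, n_sizes) running means of growing random subsamples."""
    n = vals.size
    reps = config.reps_per_size
    max_size = config.max_size if config.max_size is not None else n
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_TRAJECTORY_STREAM,))
    )
    if config.sampling == "without_replacement":
        u = rng.random((reps, n))
        order = np.argsort(u, axis=1)[:, :max_size]
        draws = vals[order]
    else:
        draws = vals[rng.integers(0, n, size=(reps, max_size))]
    running = np.cumsum(draws, axis=1) / np.arange(1, max_size + 1)
    return running[:, config.min_size - 1 :]


def point_of_stability(values: Sequence[float], config: StabilityConfig) -> StabilityResult:
    """Run the full analysis: corridor, per-size table, and POS."""
    vals = np.asarray(values, dtype=float)
    config.validate(vals.size)
    corridor = build_corridor(vals, config)
    lo, hi = corridor
    sizes = _sizes(config, vals.size)

    if config.criterion == "band_within_corridor":
        table = subsample_band_table(vals, config)
        pos = pos_from_band_table(table, corridor)
    else:  # trajectory_quantile
        running = _trajectory_running_means(vals, config)
        tol = _corridor_tol(lo, hi)
        inside = (running >= lo - tol) & (running <= hi + tol)
        stable_from = np.flip(np.logical_and.accumulate(np.flip(inside, axis=1), axis=1), axis=1)
        # per-trajectory POS (inf = never stable within the size range)
        first = np.where(
            stable_from.any(axis=1), stable_from.argmax(axis=1), running.shape[1]
        )
        traj_pos = np.where(
            first < running.shape[1], sizes[np.minimum(first, len(sizes) - 1)], np.inf
        ).astype(float)
        q = float(np.quantile(traj_pos, config.trajectory_quantile / 100.0, method="higher"))
        pos = None if not np.isfinite(q) else int(q)
        band = np.percentile(running, config.band_percentiles, axis=0)
        table = pd.DataFrame(
            {
                "size": sizes,
                "mean_of_means": running.mean(axis=0),
                "band_lo": band[0],
                "band_hi": band[1],
            }
        )

    tol = _corridor_tol(lo, hi)
    table = table.assign(
        inside_corridor=(table["band_lo"] >= lo - tol) & (table["band_hi"] <= hi + tol)
    )
    return StabilityResult(
        corridor=corridor,
        table=table,
        pos=pos,
        reached=pos is not None,
        config=config,
    )


def analytic_pos_gaussian(
    n: int, mean: float, sd: float, relative_width: float, band_upper_pct: float = 95.0
) -> int | None:
    """Closed-form Gaussian approximation to the band-criterion POS for the
    mean_relative_width corridor under sampling without replacement.

    The subsample mean at size s has SD ~ sd * sqrt((n - s) / (n * s))
    (finite-population correction), so the band half-width is
    z * sd * sqrt((n - s)/(n * s)); the POS is the smallest s at which it
    fits inside the +/- w * mean corridor.
    """
    z = stats.norm.ppf(band_upper_pct / 100.0)
    for s in range(1, n + 1):
        if z * sd * np.sqrt((n - s) / (n * s)) <= relative_width * mean:
            return s
    return None
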