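"""Spike trains, spike-density estimation and saccade-related burst statistics.

Spike trains are sequences of event times at 1 ms resolution.  A spike
density function is the train of delta pulses convolved with a unit-area
Gaussian kernel (default sigma = 5 ms), expressed in spk/s, so its time
integral equals the number of spikes.

Burst statistics are measured in a window running from 20 ms before
saccade onset to 20 ms before saccade offset (a fixed 20 ms efferent
lead time), half-open ``[onset-lead, offset-lead)``:

* ``N_s``   - number of spikes in the window,
* ``F_m``   - mean firing rate, N_s divided by saccade duration (spk/s),
* ``F_p``   - peak of the spike density within the window (spk/s),
* ``T_p``   - time of that peak relative to saccade onset (ms; negative
  means the burst peaks before the eye starts moving),
* ``gamma1`` - skewness of the distribution of spike times in the window
  relative to saccade onset, the normalized third population moment
  ``gamma1 = (1/N) * sum(((t - mu)/sigma)^3)``; positive = right tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "DensityFunction",
    "BurstStats",
    "spike_density",
    "average_density",
    "burst_window",
    "skewness",
    "burst_stats",
]

#: padding (ms) added beyond the burst window when building density grids,
#: so F_p / T_p are not biased by kernel truncation at the window edges
GRID_PAD_MS = 50.0


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered sequence of spike times in ms on the trial clock."""

    spike_times: np.ndarray

    def __init__(self, spike_times) -> None:
        t = np.asarray(spike_times, dtype=float).ravel()
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("spike times must be finite")
        if t.size and np.any(np.diff(t) < 0):
            t = np.sort(t)
        object.__setattr__(self, "spike_times", t)

    def __len__(self) -> int:
        return self.spike_times.size

    def in_window(self, t_start: float, t_end: float) -> np.ndarray:
        """Spike times falling in the half-open window [t_start, t_end)."""
        t = self.spike_times
        return t[(t >= t_start) & (t < t_end)]


@dataclass(frozen=True)
class DensityFunction:
    """Spike density sampled on a regular 1 ms grid, in spk/s."""

    t_grid: np.ndarray
    values: np.ndarray
    kernel_sigma: float

    def __post_init__(self) -> None:
        if self.t_grid.shape != self.values.shape:
            raise ValueError("t_grid and values must have equal shape")

    @property
    def dt(self) -> float:
        return float(self.t_grid[1] - self.t_grid[0]) if self.t_grid.size > 1 else 1.0

    def integral(self) -> float:
        """Time integral in seconds; equals the spike count for a wide grid."""
        return float(np.sum(self.values) * self.dt * 1e-3)

    def slice(self, t_start: float, t_end: float) -> "DensityFunction":
        m = (self.t_grid >= t_start) & (self.t_grid < t_end)
        return DensityFunction(self.t_grid[m], self.values[m], self.kernel_sigma)


@dataclass(frozen=True)
class BurstStats:
    """Burst parameters for a single saccade window (see module docstring)."""

    N_s: int
    F_m: float
    F_p: float
    T_p: float | None
    gamma1: float | None
    window: tuple[float, float]
    #: True when gamma1 (N_s < 3 or zero spread) or T_p (no spikes) is undefined
    undefined: bool = field(default=False)


def spike_density(
    train: SpikeTrain,
    kernel_sigma: float = 5.0,
    t_grid: np.ndarray | None = None,
) -> DensityFunction:
    """Convolve a spike train with a unit-area Gaussian kernel.

    Parameters
    ----------
    train : SpikeTrain
    kernel_sigma : float
        Kernel width in ms (> 0).  The kernel has unit area in seconds,
        so a single spike peaks at ``1/(sigma_s * sqrt(2*pi))`` spk/s.
    t_grid : array, optional
        Evaluation grid in ms (1 ms steps).  Defaults to a grid covering
        the train +- 5 sigma.

    Returns
    -------
    DensityFunction
        Nonnegative, linear in the train, integral equal to the count
        when the grid covers the full support.
    """
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    if t_grid is None:
        if len(train):
            lo = math.floor(train.spike_times.min() - 5 * kernel_sigma)
            hi = math.ceil(train.spike_times.max() + 5 * kernel_sigma)
        else:
            lo, hi = 0.0, 1.0
        t_grid = np.arange(lo, hi + 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("evaluation grid is empty")
    values = np.zeros_like(t_grid)
    if len(train):
        # truncate the kernel 5 sigma past the grid; contributions beyond
        # that are < 3e-7 of a spike
        lo, hi = t_grid[0] - 5 * kernel_sigma, t_grid[-1] + 5 * kernel_sigma
        ts = train.spike_times[(train.spike_times >= lo) & (train.spike_times <= hi)]
        if ts.size:
            z = (t_grid[:, None] - ts[None, :]) / kernel_sigma
            sigma_s = kernel_sigma * 1e-3
            values = np.exp(-0.5 * z * z).sum(axis=1) / (sigma_s * math.sqrt(2 * math.pi))
    return DensityFunction(t_grid, values, kernel_sigma)


def average_density(
    trains: list[SpikeTrain],
    align_times: list[float],
    kernel_sigma: float = 5.0,
    t_grid: np.ndarray | None = None,
) -> DensityFunction:
    """Average spike density across trials after aligning each on its own event.

    ``align_times[i]`` (typically saccade onset) becomes t = 0 of trial i.
    """
    if len(trains) != len(align_times):
        raise ValueError("one alignment time per train required")
    if not trains:
        raise ValueError("at least one train required")
    if t_grid is None:
        t_grid = np.arange(-200.0, 401.0)
    acc = np.zeros_like(np.asarray(t_grid, dtype=float))
    for train, t0 in zip(trains, align_times):
        shifted = SpikeTrain(train.spike_times - t0)
        acc += spike_density(shifted, kernel_sigma, t_grid).values
    return DensityFunction(np.asarray(t_grid, dtype=float), acc / len(trains), kernel_sigma)


def burst_window(onset: float, offset: float, lead: float = 20.0) -> tuple[float, float]:
    """Spike-count window [onset-lead, offset-lead) for a saccade.

    The 20 ms default lead matches the typical latency of saccades evoked
    by SC microstimulation: spikes fired up to 20 ms before the eye moves
    still contribute to the movement.
    """
    if offset <= onset:
        raise ValueError(f"saccade offset ({offset}) must exceed onset ({onset})")
    return (onset - lead, offset - lead)


def skewness(spike_times_rel_onset) -> float:
    """Normalized third population moment of spike times (Eq.-style gamma1).

    Requires at least 3 spikes and nonzero spread; raises ValueError
    otherwise (callers flag the burst instead of asserting).
    """
    t = np.asarray(spike_times_rel_onset, dtype=float)
    if t.size < 3:
        raise ValueError("skewness requires at least 3 spikes")
    mu = t.mean()
    sigma = t.std()  # population SD (divide by N)
    if sigma == 0:
        raise ValueError("skewness undefined for zero spread")
    return float(np.mean(((t - mu) / sigma) ** 3))


def burst_stats(
    train: SpikeTrain,
    onset: float,
    offset: float,
    kernel_sigma: float = 5.0,
    lead: float = 20.0,
    density: DensityFunction | None = None,
) -> BurstStats:
    """Compute all burst parameters of one trial.

    ``density``, when given, must be aligned on saccade onset (t = 0);
    this lets callers substitute a trial-averaged density for the F_p /
    T_p estimates, as done for movement-field-center responses.
    """
    t_start, t_end = burst_window(onset, offset, lead)
    spikes = train.in_window(t_start, t_end)
    n_s = int(spikes.size)
    duration_s = (offset - onset) * 1e-3
    f_m = n_s / duration_s

    if density is None:
        grid = np.arange(math.floor(t_start - GRID_PAD_MS), math.ceil(t_end + GRID_PAD_MS) + 1.0)
        density = spike_density(SpikeTrain(train.spike_times - onset), kernel_sigma, grid - onset)
    win = density.slice(t_start - onset, t_end - onset)

    undefined = False
    if n_s == 0 or win.values.size == 0 or win.values.max() == 0.0:
        f_p, t_p = 0.0, None
        undefined = True
    else:
        i = int(np.argmax(win.values))
        f_p = float(win.values[i])
        t_p = float(win.t_grid[i])

    try:
        g1 = skewness(spikes - onset)
    except ValueError:
        g1 = None
        undefined = True

    return BurstStats(n_s, f_m, f_p, t_p, g1, (t_start, t_end), undefined)
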