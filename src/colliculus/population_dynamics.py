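"""Population activity over the motor map, burst synchrony, and gradients.

Three analyses live here:

* **Population profiles.**  For a chosen target saccade, each cell's
  trials whose (rotated) saccade vectors land within 0.3 mm of the
  target's map point are averaged with Gaussian distance weights
  (sigma_d = 0.15 mm).  The per-cell averages are then pooled over the
  rostral-caudal axis with a spatial Gaussian kernel (sigma = 0.25 mm,
  0.2 mm grid), giving the population activity as a function of map
  location u and time relative to saccade onset.

* **Cross-correlation synchrony.**  The center burst profile is shifted
  in time and correlated with the profile at another site over a window
  from 20 ms before saccade onset to saccade offset, normalized so the
  autocorrelation at lag zero equals 1.  The lag of the correlation peak
  measures the relative burst timing; positive delays mean the other
  site bursts later than the center.

* **Gradient regressions.**  Burst parameters at the preferred vector
  are regressed on preferred amplitude R_pref (the rostral-caudal index
  of a cell's map position), summarizing the topographic organization of
  N_s, F_m, F_p, T_p, gamma1 and Cv.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .bursts import DensityFunction, SpikeTrain, spike_density
from .motor_map import (
    DEFAULT_MAP,
    MapParams,
    SaccadeVector,
    afferent_map,
    map_distance,
    rotate_to_horizontal,
)

__all__ = [
    "PopulationProfile",
    "CrossCorrResult",
    "CellDensity",
    "weighted_trial_average",
    "population_profile",
    "cross_correlate",
    "gradient_regressions",
    "significance_stars",
]

#: Gaussian width (mm) of the trial-matching weights; half the 0.3 mm cutoff
TRIAL_WEIGHT_SIGMA = 0.15
#: map-distance cutoff (mm) for a trial to qualify as matching the target
TRIAL_MATCH_CUTOFF = 0.3
#: width (mm) of the spatial pooling kernel along u
SPATIAL_SIGMA = 0.25
#: rostral-caudal extent (mm) of the analysis around the population center
POPULATION_EXTENT = 1.25
#: minimum burst size relative to the cell's own preferred response
MIN_RELATIVE_ACTIVITY = 0.05


@dataclass(frozen=True)
class CellDensity:
    """One cell's target-matched average burst, placed on the map.

    u_c is the cell's rostral-caudal coordinate along the horizontal
    meridian (after rotating its preferred vector onto it); n_spikes is
    the mean in-window spike count of the contributing trials.
    """

    u_c: float
    density: DensityFunction
    n_spikes: float
    N_pref: float


@dataclass(frozen=True)
class PopulationProfile:
    """Population activity (spk/s) on a (u, t) grid for one target vector."""

    u_grid: np.ndarray
    t_grid: np.ndarray
    activity: np.ndarray  # shape (len(u_grid), len(t_grid))
    target_vec: SaccadeVector
    u_center: float
    empty_nodes: np.ndarray  # boolean mask over u_grid

    def at(self, u: float) -> DensityFunction:
        i = int(np.argmin(np.abs(self.u_grid - u)))
        return DensityFunction(self.t_grid, self.activity[i], math.nan)


@dataclass(frozen=True)
class CrossCorrResult:
    lags: np.ndarray
    r_of_tau: np.ndarray
    r0: float
    optimal_delay: float
    r_opt: float


def weighted_trial_average(
    trials: list[tuple[SaccadeVector, SpikeTrain, float]],
    target_vec: SaccadeVector,
    phi_pref: float | None = None,
    kernel_sigma: float = 5.0,
    t_grid: np.ndarray | None = None,
    p: MapParams = DEFAULT_MAP,
) -> DensityFunction | None:
    """Average a cell's onset-aligned spike densities, weighted by vector match.

    Each trial is ``(saccade_vector, spike_train, saccade_onset_ms)``.
    When ``phi_pref`` is given, saccade vectors are first rotated so the
    preferred direction lies on the horizontal meridian (cross-cell
    pooling frame).  Trials whose map distance d to the target is >= 0.3
    mm are excluded; the rest get weights exp(-d^2 / (2*0.15^2)),
    normalized.  Returns None when no trial qualifies.
    """
    if t_grid is None:
        t_grid = np.arange(-200.0, 401.0)
    target_pt = afferent_map(target_vec, p)
    acc = np.zeros_like(np.asarray(t_grid, dtype=float))
    wsum = 0.0
    for vec, train, onset in trials:
        if phi_pref is not None:
            vec = rotate_to_horizontal(vec, phi_pref)
        d = map_distance(afferent_map(vec, p), target_pt)
        if d >= TRIAL_MATCH_CUTOFF:
            continue
        w = math.exp(-(d**2) / (2.0 * TRIAL_WEIGHT_SIGMA**2))
        dens = spike_density(SpikeTrain(train.spike_times - onset), kernel_sigma, t_grid)
        acc += w * dens.values
        wsum += w
    if wsum == 0.0:
        return None
    return DensityFunction(np.asarray(t_grid, dtype=float), acc / wsum, kernel_sigma)


def population_profile(
    cells: list[CellDensity],
    target_vec: SaccadeVector,
    p: MapParams = DEFAULT_MAP,
    u_step: float = 0.2,
    extent: float = POPULATION_EXTENT,
    spatial_sigma: float = SPATIAL_SIGMA,
) -> PopulationProfile:
    """Pool per-cell average bursts into map-location-resolved activity.

    Cells must burst appreciably (N_s > 0.05 * N_pref) and lie within
    1.25 mm of the population center (the target's map point); activity
    at each u node is the Gaussian-weighted mean over qualifying cells.
    Nodes with no cell within the pooling reach are flagged empty.
    """
    u_center = afferent_map(target_vec, p).u
    included = [
        c for c in cells
        if c.n_spikes > MIN_RELATIVE_ACTIVITY * c.N_pref
        and abs(c.u_c - u_center) <= extent
    ]
    n_nodes = int(round(2 * extent / u_step)) + 1
    u_grid = u_center + (np.arange(n_nodes) - n_nodes // 2) * u_step
    if not included:
        t_grid = np.arange(-200.0, 401.0)
        return PopulationProfile(u_grid, t_grid, np.zeros((n_nodes, t_grid.size)),
                                 target_vec, u_center, np.ones(n_nodes, dtype=bool))
    t_grid = included[0].density.t_grid
    dens = np.stack([c.density.values for c in included])
    u_c = np.array([c.u_c for c in included])
    w = np.exp(-((u_grid[:, None] - u_c[None, :]) ** 2) / (2.0 * spatial_sigma**2))
    empty = w.sum(axis=1) <= 0
    wsum = np.where(w.sum(axis=1) > 0, w.sum(axis=1), 1.0)
    activity = (w @ dens) / wsum[:, None]
    return PopulationProfile(u_grid, t_grid, activity, target_vec, u_center, empty)


def cross_correlate(
    f_center: DensityFunction,
    f_other: DensityFunction,
    window: tuple[float, float],
    max_lag: float = 50.0,
) -> CrossCorrResult:
    """Normalized temporal cross-correlation of two burst profiles.

    ``r(tau) = sum_t fc(t) fx(t + tau) / sqrt(sum_t fc^2 * sum_t fx^2)``
    with t running over ``window`` (typically 20 ms before saccade onset
    to saccade offset).  Values of ``f_other`` outside its sampled
    support count as zero.  The optimal delay is the argmax of r over
    lags in [-50, 50] ms, ties broken toward zero lag; positive delay
    means ``f_other`` lags the center.
    """
    if not np.array_equal(np.diff(f_center.t_grid), np.diff(f_other.t_grid)) and (
        f_center.dt != f_other.dt
    ):
        raise ValueError("profiles must share the same sampling step")
    t0, t1 = window
    m = (f_center.t_grid >= t0) & (f_center.t_grid <= t1)
    t_win = f_center.t_grid[m]
    fc = f_center.values[m]
    fx_win = np.interp(t_win, f_other.t_grid, f_other.values, left=0.0, right=0.0)
    denom = math.sqrt(float(fc @ fc) * float(fx_win @ fx_win))
    if denom == 0.0:
        raise ValueError("zero-energy profile in the correlation window")

    lags = np.arange(-max_lag, max_lag + 1.0)
    r = np.empty_like(lags)
    for i, tau in enumerate(lags):
        fx = np.interp(t_win + tau, f_other.t_grid, f_other.values, left=0.0, right=0.0)
        r[i] = float(fc @ fx) / denom
    # ties toward zero lag
    order = np.lexsort((np.abs(lags), -r))
    i_opt = order[0]
    i0 = int(np.argmin(np.abs(lags)))
    return CrossCorrResult(lags, r, float(r[i0]), float(lags[i_opt]), float(r[i_opt]))


def significance_stars(p: float) -> str:
    if p < 1e-6:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "n.s."


def gradient_regressions(table: pd.DataFrame) -> pd.DataFrame:
    """Regress per-cell burst parameters on preferred amplitude.

    ``table`` needs a column ``R_pref`` (deg) plus any of ``N_s``,
    ``F_m``, ``F_p``, ``T_p``, ``gamma1``, ``Cv``.  Returns one row per
    parameter with mean, SD, OLS slope +- SE, intercept +- SE, Pearson r,
    two-tailed p and significance stars.  Cells with an undefined value
    for a parameter (NaN) are dropped for that parameter only.
    """
    if "R_pref" not in table.columns:
        raise ValueError("table must contain an R_pref column")
    r_all = table["R_pref"].to_numpy(dtype=float)
    if len(table) < 10 or (np.ptp(r_all) < 10.0 if len(table) else True):
        warnings.warn(
            "fewer than 10 cells or eccentricity span < 10 deg; "
            "gradient estimates may be unreliable",
            stacklevel=2,
        )
    rows = []
    for param in ["N_s", "F_m", "F_p", "T_p", "gamma1", "Cv"]:
        if param not in table.columns:
            continue
        y = table[param].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(r_all)
        x, y = r_all[ok], y[ok]
        row = {"param": param, "n": int(ok.sum()),
               "mean": float(y.mean()) if y.size else math.nan,
               "sd": float(y.std(ddof=1)) if y.size > 1 else math.nan}
        if y.size > 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
            fit = linregress(x, y)
            row.update(slope=float(fit.slope), slope_se=float(fit.stderr),
                       intercept=float(fit.intercept),
                       intercept_se=float(fit.intercept_stderr),
                       r=float(fit.rvalue), p=float(fit.pvalue),
                       stars=significance_stars(float(fit.pvalue)))
        else:
            row.update(slope=0.0 if y.size else math.nan, slope_se=math.nan,
                       intercept=float(y.mean()) if y.size else math.nan,
                       intercept_se=math.nan, r=math.nan, p=math.nan,
                       stars="n.s.")
        rows.append(row)
    return pd.DataFrame(rows).set_index("param")
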