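"""Synthetic SC populations, spike trains, and decoded saccades.

The generator produces data with the statistical structure the analyses
assume, so the whole pipeline runs without any recordings:

* cells on a jittered grid over the motor map (u in [0, 4] mm, v in
  [-2, 2] mm), each with a Gaussian movement field of width sigma_mf =
  0.5 mm and peak count N0 = 18 spikes;
* per trial, each recruited cell draws a multiplicative gain from a
  gamma distribution (mean 1, SD = Cv = 0.30) and an additive Poisson
  count (mean 0.5 spikes), giving signal-dependent plus
  signal-independent count noise;
* spike times are drawn i.i.d. from a single gamma-density template
  shared by all recruited cells (bursts are synchronized, scaled copies
  of each other); the template spans the spike-count window of a saccade
  of duration D(R) = d0 + d1*R, its shape parameter k(R) falls
  log-linearly from k(5 deg) = 8 to k(30 deg) = 3 (skewness grows with
  amplitude), and its peak is pinned at T_p = -1 ms relative to the
  nominal saccade onset;
* the eye movement itself is produced by running the spike-vector
  decoder and linear brainstem model on the generated population spikes;
  onset/offset and the realized saccade vector are detected from the
  simulated trace, so decoded kinematics feed back into every stored
  trial.

Count-then-times construction: the spike count is fixed first (rounded
noisy expectation), then times are sampled from the template - an
inhomogeneous-Poisson-profile conditioned on its count, the simplest
process consistent with count-level noise analysis.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .bursts import SpikeTrain
from .dataset_io import (
    CELL_COLUMNS,
    FORMAT_VERSION,
    Dataset,
    SaccadeTrial,
    TRIAL_COLUMNS,
    SPIKE_COLUMNS,
)
from .ensemble_decoder import (
    BrainstemConfig,
    DecoderConfig,
    EyeTrace,
    brainstem_feedback,
    decode_trajectory,
)
from .motor_map import (
    DEFAULT_MAP,
    MapParams,
    MapPoint,
    SaccadeVector,
    afferent_map,
    efferent_map,
    map_distance,
)
from .movement_fields import MovementField

__all__ = [
    "SyntheticConfig",
    "SyntheticCell",
    "TrialResult",
    "burst_duration",
    "gamma_shape",
    "burst_template",
    "make_map_population",
    "decoder_config",
    "simulate_trial",
    "mf_scan_targets",
    "rose_scan_targets",
    "generate_dataset",
]

#: nominal saccade onset on the trial clock (ms); spikes start 20 ms earlier
NOMINAL_ONSET = 70.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the generator (see module docstring)."""

    n_cells: int = 100
    u_range: tuple[float, float] = (0.0, 4.0)   # mm
    v_range: tuple[float, float] = (-2.0, 2.0)  # mm
    N0: float = 18.0          # spikes at the preferred vector
    sigma0: float = 0.5       # mm, width of the recruited population
    sigma_mf: float = 0.5     # mm, movement-field width
    cv: float = 0.30          # multiplicative gain SD (gamma, mean 1)
    additive_rate: float = 0.5  # spikes, Poisson mean
    d0: float = 20.0          # ms, duration intercept
    d1: float = 1.8           # ms/deg, duration slope
    k_small: tuple[float, float] = (5.0, 8.0)   # (R deg, gamma shape)
    k_large: tuple[float, float] = (30.0, 3.0)
    T_p: float = -1.0         # ms, template peak relative to saccade onset
    endpoint_jitter: float = 0.5  # deg, isotropic target scatter
    shared_gain: bool = False     # add one gain draw common to all cells
    recruit_radius_sigma: float = 3.0  # cells beyond this many sigma0 stay silent
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.N0, self.sigma0, self.sigma_mf, self.cv,
               self.d0, self.d1) <= 0:
            raise ValueError("generator parameters must be positive")
        if self.k_small[1] < 2 or self.k_large[1] < 2:
            raise ValueError("gamma shape anchors must be >= 2")


@dataclass(frozen=True)
class SyntheticCell:
    cell_id: int
    site: MapPoint
    field: MovementField
    pref_vec: SaccadeVector


@dataclass
class TrialResult:
    """All per-cell spike trains of one simulated trial, plus the eye trace.

    ``trial`` is None when the decoded movement never crossed the
    detection threshold (flagged trial).
    """

    trains: dict[int, SpikeTrain]
    trace: EyeTrace
    trial: SaccadeTrial | None
    intended: SaccadeVector


def burst_duration(R: float, cfg: SyntheticConfig) -> float:
    """Saccade (and spike-window) duration D(R) = d0 + d1*R, in ms."""
    return cfg.d0 + cfg.d1 * R


def gamma_shape(R: float, cfg: SyntheticConfig) -> float:
    """Template shape k(R), log-linear between the two anchors, clamped >= 2."""
    (r0, k0), (r1, k1) = cfg.k_small, cfg.k_large
    logk = math.log(k0) + (R - r0) * (math.log(k1) - math.log(k0)) / (r1 - r0)
    return max(2.0, math.exp(logk))


def burst_template(
    R: float,
    cfg: SyntheticConfig,
    onset: float = NOMINAL_ONSET,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete burst-time distribution on the spike-count window.

    Returns (bin_times_ms, probabilities) over the 1 ms bins of
    ``[onset-20, onset-20+D)``.  A gamma density with shape k(R) is laid
    on the window with its mode pinned at ``onset + T_p`` and its
    central 98% interval (1%..99% quantiles) scaled to D, so the burst
    genuinely fills the count window and its peak rate falls as ~1/D
    with amplitude; mass falling outside the window is clipped and the
    remainder renormalized, so every sampled spike lands inside the
    count window.
    """
    D = burst_duration(R, cfg)
    k = gamma_shape(R, cfg)
    bins = np.arange(math.floor(onset) - 20.0, math.floor(onset) - 20.0 + round(D))
    x_lo, x_hi = gamma_dist.ppf([0.01, 0.99], k)
    s = D / (x_hi - x_lo)  # ms per unit of the gamma's dimensionless time
    mode = k - 1.0
    x = mode + (bins - (onset + cfg.T_p)) / s
    probs = gamma_dist.pdf(np.clip(x, 0.0, None), k)
    total = probs.sum()
    if total <= 0:
        probs = np.full(bins.size, 1.0 / bins.size)
    else:
        probs = probs / total
    return bins, probs


def make_map_population(
    cfg: SyntheticConfig,
    map_params: MapParams = DEFAULT_MAP,
) -> list[SyntheticCell]:
    """Place cells on a jittered grid over the map extent (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    u_lo, u_hi = cfg.u_range
    v_lo, v_hi = cfg.v_range
    n_u = max(1, round(math.sqrt(cfg.n_cells * (u_hi - u_lo) / (v_hi - v_lo))))
    n_v = max(1, math.ceil(cfg.n_cells / n_u))
    du, dv = (u_hi - u_lo) / n_u, (v_hi - v_lo) / n_v
    cells = []
    cid = 0
    for i in range(n_u):
        for j in range(n_v):
            if cid >= cfg.n_cells:
                break
            u = u_lo + (i + 0.5) * du + rng.uniform(-0.3, 0.3) * du
            v = v_lo + (j + 0.5) * dv + rng.uniform(-0.3, 0.3) * dv
            u = min(max(u, u_lo), u_hi)
            v = min(max(v, v_lo), v_hi)
            site = MapPoint(u, v)
            field = MovementField(u, v, cfg.sigma_mf, cfg.N0)
            cells.append(SyntheticCell(cid, site, field, efferent_map(site, map_params)))
            cid += 1
    cells.sort(key=lambda c: c.site.u)
    return [SyntheticCell(i, c.site, c.field, c.pref_vec) for i, c in enumerate(cells)]


def decoder_config(
    cfg: SyntheticConfig,
    map_params: MapParams = DEFAULT_MAP,
) -> DecoderConfig:
    """Decoder matched to the generator: rho = n_cells / map area."""
    area = (cfg.u_range[1] - cfg.u_range[0]) * (cfg.v_range[1] - cfg.v_range[0])
    return DecoderConfig(rho=cfg.n_cells / area, N0=cfg.N0, sigma0=cfg.sigma0,
                         map=map_params)


def simulate_trial(
    target: SaccadeVector,
    population: list[SyntheticCell],
    cfg: SyntheticConfig,
    dec_cfg: DecoderConfig | None = None,
    bs_cfg: BrainstemConfig | None = None,
    rng: np.random.Generator | int | None = None,
    map_params: MapParams = DEFAULT_MAP,
    jitter_target: bool = True,
    noise: bool = True,
) -> TrialResult:
    """Generate one trial: population spikes, decoded eye trace, saccade.

    All recruited cells share the burst template of the (jittered)
    target amplitude, so their bursts are synchronized, scaled versions
    of each other; per-cell counts carry independent multiplicative
    (SD = Cv) plus additive Poisson noise.

    ``noise=False`` gives the deterministic skeleton of the model: no
    target jitter, expected spike counts, and spike times placed at
    template quantiles - useful for characterizing the emergent
    kinematics without Monte-Carlo scatter.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    dec_cfg = dec_cfg or decoder_config(cfg, map_params)
    bs_cfg = bs_cfg or BrainstemConfig()

    if noise and jitter_target and cfg.endpoint_jitter > 0:
        x, y = target.xy
        x += rng.normal(0.0, cfg.endpoint_jitter)
        y += rng.normal(0.0, cfg.endpoint_jitter)
        intended = SaccadeVector(math.hypot(x, y), math.degrees(math.atan2(y, x)))
    else:
        intended = target

    center = afferent_map(intended, map_params)
    bins, probs = burst_template(intended.R, cfg)
    g_common = float(rng.gamma(1.0 / cfg.cv**2, cfg.cv**2)) if cfg.shared_gain else 1.0

    trains: dict[int, SpikeTrain] = {}
    for cell in population:
        d = map_distance(cell.site, center)
        if d > cfg.recruit_radius_sigma * cfg.sigma0:
            trains[cell.cell_id] = SpikeTrain([])
            continue
        gain = float(rng.gamma(1.0 / cfg.cv**2, cfg.cv**2)) * g_common if noise else 1.0
        expected = gain * cfg.N0 * math.exp(-(d**2) / (2.0 * cfg.sigma0**2))
        n = int(round(expected)) + (int(rng.poisson(cfg.additive_rate)) if noise else 0)
        if n <= 0:
            trains[cell.cell_id] = SpikeTrain([])
            continue
        if noise:
            times = rng.choice(bins, size=n, p=probs)
        else:
            # stratified placement at template quantiles
            cdf = np.cumsum(probs)
            q = (np.arange(n) + 0.5) / n
            times = bins[np.searchsorted(cdf, q)]
        trains[cell.cell_id] = SpikeTrain(np.sort(times))

    t_grid = np.arange(0.0, bins[-1] + 2.0)
    sites = [(c.site, trains[c.cell_id]) for c in population if len(trains[c.cell_id])]
    t_grid, delta_e = decode_trajectory(sites, dec_cfg, t_grid)
    trace = brainstem_feedback(t_grid, delta_e, bs_cfg)

    if trace.onset is None or trace.offset <= trace.onset:
        return TrialResult(trains, trace, None, intended)
    i0 = int(np.searchsorted(trace.t, trace.onset))
    i1 = int(np.searchsorted(trace.t, trace.offset))
    disp = trace.position[i1] - trace.position[i0]
    R = float(np.hypot(*disp))
    Phi = math.degrees(math.atan2(disp[1], disp[0]))
    trial = SaccadeTrial(-1, -1, trace.onset, trace.offset, R, Phi,
                         target.R, target.Phi)
    return TrialResult(trains, trace, trial, intended)


def mf_scan_targets(
    pref_vec: SaccadeVector,
    sigma_mf: float = 0.5,
    offsets: tuple[float, ...] = (-1.2, -0.6, -0.2, 0.0, 0.2, 0.6, 1.2),
    map_params: MapParams = DEFAULT_MAP,
) -> list[SaccadeVector]:
    """Movement-field scan: a map-space grid of targets around a preferred vector.

    Offsets are in units of sigma_mf along both map axes (7 x 7 grid by
    default), mirroring a scan of saccades inside and around a cell's
    response field; the grid is denser near the center so that enough
    responses land within the 0.5*sigma_mf center-selection radius.
    """
    center = afferent_map(pref_vec, map_params)
    targets = []
    for du in offsets:
        for dv in offsets:
            u = max(0.0, center.u + du * sigma_mf)
            targets.append(efferent_map(MapPoint(u, center.v + dv * sigma_mf),
                                        map_params))
    return targets


def rose_scan_targets(
    amplitudes: tuple[float, ...] = (2, 5, 9, 14, 20, 27, 35),
    directions: tuple[float, ...] = (0, 30, 60, 90, -30, -60, -90),
) -> list[SaccadeVector]:
    """Fixed series of targets across the (contralateral) visual field."""
    return [SaccadeVector(r, phi) for r in amplitudes for phi in directions]


def generate_dataset(
    cfg: SyntheticConfig,
    targets: list[SaccadeVector] | None = None,
    n_reps: int = 2,
    seed: int | None = None,
    map_params: MapParams = DEFAULT_MAP,
    bs_cfg: BrainstemConfig | None = None,
) -> Dataset:
    """Simulate one single-unit session per cell and assemble a Dataset.

    For each cell the target list (default: its movement-field scan) is
    presented ``n_reps`` times; each presentation simulates the whole
    population and the decoded eye movement, but stores only the
    recorded cell's spike train - as in single-electrode recordings.
    Trials whose movement stayed below the detection threshold are
    dropped (and counted in the manifest).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    population = make_map_population(cfg, map_params)
    dec_cfg = decoder_config(cfg, map_params)

    cell_rows, trial_rows, spike_rows = [], [], []
    n_flagged = 0
    trial_id = 0
    for cell in population:
        cell_rows.append({"cell_id": cell.cell_id, "animal_id": "synthetic",
                          "note": f"u={cell.site.u:.3f}mm v={cell.site.v:.3f}mm"})
        cell_targets = targets or mf_scan_targets(cell.pref_vec, cfg.sigma_mf,
                                                  map_params=map_params)
        for _ in range(n_reps):
            for tgt in cell_targets:
                res = simulate_trial(tgt, population, cfg, dec_cfg, bs_cfg,
                                     rng=rng, map_params=map_params)
                if res.trial is None:
                    n_flagged += 1
                    continue
                t = res.trial
                trial_rows.append({
                    "trial_id": trial_id, "cell_id": cell.cell_id,
                    "onset_ms": t.onset, "offset_ms": t.offset,
                    "R_deg": t.R, "Phi_deg": t.Phi,
                    "target_R_deg": tgt.R, "target_Phi_deg": tgt.Phi,
                })
                for ts in res.trains[cell.cell_id].spike_times:
                    spike_rows.append({"trial_id": trial_id, "spike_time_ms": float(ts)})
                trial_id += 1

    manifest = {
        "format_version": FORMAT_VERSION,
        "generator": asdict(cfg),
        "seed": seed,
        "n_reps": n_reps,
        "n_flagged_trials": n_flagged,
        "map_params": {"A": map_params.A, "B_u": map_params.B_u, "B_v": map_params.B_v},
    }
    return Dataset(
        cells=pd.DataFrame(cell_rows, columns=CELL_COLUMNS),
        trials=pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS),
        spikes=pd.DataFrame(spike_rows, columns=SPIKE_COLUMNS),
        manifest=manifest,
    )
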