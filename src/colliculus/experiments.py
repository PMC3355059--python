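"""End-to-end experiments exercising the generator -> analysis -> decoder loop.

Each function runs one self-contained study at desk scale and returns a
dict of plain numbers.  They are used by the verification suite and by
``scripts/acceptance.py``; problem sizes are chosen so the whole set
runs in a few minutes on one core (the methods note discusses the
choices).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import linregress

from .bursts import SpikeTrain, average_density, burst_window, skewness, spike_density
from .ensemble_decoder import kinematics
from .motor_map import (
    DEFAULT_MAP,
    MapPoint,
    SaccadeVector,
    afferent_map,
    efferent_map,
)
from .movement_fields import MovementField, fit_movement_field, mf_predict
from .noise_analysis import cluster_responses, cv_regression
from .population_dynamics import CellDensity, cross_correlate, population_profile
from .synthetic_data import (
    SyntheticConfig,
    generate_dataset,
    make_map_population,
    simulate_trial,
)
from .dataset_io import run_pipeline

__all__ = [
    "map_roundtrip_error",
    "brute_force_skewness",
    "skewness_oracle",
    "autocorrelation_contract",
    "movement_field_recovery",
    "cv_recovery",
    "pipeline_gradients",
    "emergent_kinematics",
    "oblique_stretching",
    "burst_synchrony",
    "endpoint_variance",
]


def map_roundtrip_error(n_r: int = 20, n_phi: int = 20) -> float:
    """Max relative error of efferent(afferent(.)) over an R x Phi grid."""
    worst = 0.0
    for R in np.linspace(0.5, 40.0, n_r):
        for Phi in np.linspace(-80.0, 80.0, n_phi):
            x = SaccadeVector(float(R), float(Phi))
            y = efferent_map(afferent_map(x))
            err = abs(y.R - x.R) / x.R + abs(y.Phi - x.Phi) / 360.0
            worst = max(worst, err)
    return worst


def brute_force_skewness(times) -> float:
    """Independent oracle: normalized third moment via explicit sums."""
    ts = [float(t) for t in times]
    n = len(ts)
    mu = math.fsum(ts) / n
    var = math.fsum((t - mu) ** 2 for t in ts) / n
    sd = math.sqrt(var)
    return math.fsum(((t - mu) / sd) ** 3 for t in ts) / n


def skewness_oracle(n_trains: int = 1000, seed: int = 0) -> dict:
    """Compare the burst-skewness statistic with the brute-force oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trains):
        n = int(rng.integers(3, 40))
        ts = rng.integers(-50, 150, size=n).astype(float)
        if np.std(ts) == 0:
            continue
        worst = max(worst, abs(skewness(ts) - brute_force_skewness(ts)))
    return {
        "max_abs_error": worst,
        "worked_value": skewness([0.0, 0.0, 0.0, 30.0]),
    }


def autocorrelation_contract(n_profiles: int = 20, seed: int = 0) -> float:
    """Worst |r0 - 1| of a burst profile autocorrelated with itself."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_profiles):
        n = int(rng.integers(5, 60))
        train = SpikeTrain(np.sort(rng.uniform(0.0, 80.0, n)))
        dens = spike_density(train, 5.0, np.arange(-40.0, 121.0))
        # window spans the full support so the autocorrelation peak sits at 0
        xc = cross_correlate(dens, dens, (-40.0, 120.0))
        worst = max(worst, abs(xc.r0 - 1.0), abs(xc.optimal_delay))
    return worst


def _field_responses(
    field: MovementField,
    n_trials: int,
    rng: np.random.Generator,
    cv: float = 0.30,
    additive_rate: float = 0.0,
    spread_sigma: float = 1.25,
) -> list[tuple[SaccadeVector, float]]:
    """Saccade responses scattered over a movement field with count noise."""
    out = []
    for _ in range(n_trials):
        du = rng.uniform(-spread_sigma, spread_sigma) * field.sigma_mf
        dv = rng.uniform(-spread_sigma, spread_sigma) * field.sigma_mf
        pt = MapPoint(max(0.0, field.u_pref + du), field.v_pref + dv)
        vec = efferent_map(pt)
        gain = rng.gamma(1.0 / cv**2, cv**2)
        n = gain * mf_predict(field, vec)
        if additive_rate > 0:
            n = round(n) + rng.poisson(additive_rate)
        out.append((vec, float(n)))
    return out


def movement_field_recovery(
    n_seeds: int = 100,
    n_trials: int = 50,
    cv: float = 0.30,
    seed: int = 0,
) -> dict:
    """Monte-Carlo parameter recovery of the Gaussian movement-field fit.

    A known field (u=2.0 mm, v=0.3 mm, sigma_mf=0.5 mm, N_pref=18) is
    sampled with multiplicative count noise; medians of the absolute
    center errors and of the sigma ratio are reported over seeds.
    """
    truth = MovementField(2.0, 0.3, 0.5, 18.0)
    rng = np.random.default_rng(seed)
    du, dv, sig_ratio = [], [], []
    for k in range(n_seeds):
        responses = _field_responses(truth, n_trials, rng, cv=cv)
        fit = fit_movement_field(responses, seed=k)
        assert fit.field is not None
        du.append(abs(fit.field.u_pref - truth.u_pref))
        dv.append(abs(fit.field.v_pref - truth.v_pref))
        sig_ratio.append(fit.field.sigma_mf / truth.sigma_mf)
    return {
        "median_u_error_mm": float(np.median(du)),
        "median_v_error_mm": float(np.median(dv)),
        "median_sigma_ratio": float(np.median(sig_ratio)),
        "n_seeds": n_seeds,
    }


def cv_recovery(
    n_seeds: int = 100,
    n_clusters: int = 15,
    trials_per_cluster: int = 10,
    cv: float = 0.30,
    additive_rate: float = 0.5,
    seed: int = 0,
) -> dict:
    """Monte-Carlo recovery of the coefficient of variation.

    Responses form tight clusters over a known movement field; counts
    carry multiplicative gain noise (SD = cv) plus additive Poisson
    noise.  The full method (field fit -> clustering -> corrected
    SD-vs-mean regression) is applied per seed; medians of the slope,
    its SE and the intercept are reported.
    """
    truth = MovementField(2.0, 0.0, 0.5, 18.0)
    rng = np.random.default_rng(seed)
    slopes, ses, intercepts, int_ses = [], [], [], []
    for k in range(n_seeds):
        responses = []
        for _ in range(n_clusters):
            cu = truth.u_pref + rng.uniform(-1.2, 1.2) * truth.sigma_mf
            cvv = truth.v_pref + rng.uniform(-1.2, 1.2) * truth.sigma_mf
            for _ in range(trials_per_cluster):
                pt = MapPoint(cu + rng.normal(0, 0.03), cvv + rng.normal(0, 0.03))
                vec = efferent_map(pt)
                gain = rng.gamma(1.0 / cv**2, cv**2)
                n = round(gain * mf_predict(truth, vec)) + rng.poisson(additive_rate)
                responses.append((vec, float(n)))
        fit = fit_movement_field(responses, seed=k)
        assert fit.field is not None
        clusters = cluster_responses(responses, fit.field)
        nf = cv_regression(clusters, fit.field, corrected=True)
        if nf is None:
            continue
        slopes.append(nf.Cv)
        ses.append(nf.Cv_se)
        intercepts.append(nf.intercept)
        int_ses.append(nf.intercept_se)
    return {
        "median_slope": float(np.median(slopes)),
        "median_slope_se": float(np.median(ses)),
        "median_intercept": float(np.median(intercepts)),
        "median_intercept_se": float(np.median(int_ses)),
        "n_fits": len(slopes),
    }


def pipeline_gradients(seed: int = 11, n_cells: int = 100, n_reps: int = 2) -> dict:
    """Generate a full synthetic dataset and run every analysis stage.

    Returns the topographic-gradient regressions (slope and p per burst
    parameter) plus the population noise summary.
    """
    cfg = SyntheticConfig(n_cells=n_cells, seed=seed)
    ds = generate_dataset(cfg, n_reps=n_reps, seed=seed)
    res = run_pipeline(ds, seed=0)
    g = res.gradient_table
    out = {"n_cells_fitted": int(len(res.cell_table))}
    for param in ["N_s", "F_m", "F_p", "gamma1", "Cv"]:
        out[f"{param}_slope"] = float(g.loc[param, "slope"])
        out[f"{param}_p"] = float(g.loc[param, "p"])
        out[f"{param}_mean"] = float(g.loc[param, "mean"])
    s = res.noise_summary
    out.update(
        cv_mean=s["Cv_mean"], cv_sem=s["Cv_sem"],
        intercept_mean=s["intercept_mean"],
        intercept_pct_of_peak=s["intercept_pct_of_peak_mean"],
        n_noise_cells=s["n_cells"],
    )
    return out


def emergent_kinematics(
    amplitudes=(5, 10, 15, 20, 25, 30),
    n_cells: int = 6400,
    seed: int = 1,
) -> dict:
    """Main-sequence metrics of saccades decoded from ideal dense populations.

    Deterministic mode (expected counts, quantile spike times) isolates
    the structural property from Monte-Carlo scatter.
    """
    cfg = SyntheticConfig(n_cells=n_cells, seed=seed)
    pop = make_map_population(cfg)
    durs, vpks, skews, amps = [], [], [], []
    for R in amplitudes:
        res = simulate_trial(SaccadeVector(float(R), 0.0), pop, cfg, noise=False)
        k = kinematics(res.trace)
        amps.append(k["amplitude"])
        durs.append(k["duration"])
        vpks.append(k["peak_velocity"])
        skews.append(k["velocity_skewness"])
    return {
        "amplitudes": list(amplitudes),
        "decoded_amplitudes": amps,
        "durations_ms": durs,
        "peak_velocities": vpks,
        "velocity_skewness": skews,
    }


def oblique_stretching(
    R: float = 20.0,
    directions=(30.0, 45.0, 60.0),
    n_cells: int = 6400,
    seed: int = 1,
) -> dict:
    """Straightness and H/V component stretching of oblique saccades."""
    cfg = SyntheticConfig(n_cells=n_cells, seed=seed)
    pop = make_map_population(cfg)
    straight, hv_r0 = [], []
    for phi in directions:
        res = simulate_trial(SaccadeVector(R, float(phi)), pop, cfg, noise=False)
        k = kinematics(res.trace)
        tr = res.trace
        m = (tr.t >= tr.onset) & (tr.t <= tr.offset)
        vx, vy = tr.velocity[m, 0], tr.velocity[m, 1]
        r0 = float(vx @ vy / math.sqrt((vx @ vx) * (vy @ vy)))
        straight.append(k["straightness"])
        hv_r0.append(r0)
    return {
        "directions": list(directions),
        "straightness": straight,
        "hv_velocity_r0": hv_r0,
    }


def burst_synchrony(
    target_R: float = 14.0,
    n_trials: int = 60,
    n_cells: int = 100,
    seed: int = 2,
) -> dict:
    """Cross-correlation delays of recruited cells vs the population center.

    Simulates ``n_trials`` saccades to one target, averages every
    recruited cell's onset-aligned burst, and measures each cell's
    optimal delay against the pooled center profile, plus the
    delay-vs-rostral-caudal-location regression.
    """
    cfg = SyntheticConfig(n_cells=n_cells, seed=seed)
    pop = make_map_population(cfg)
    rng = np.random.default_rng(seed)
    target = SaccadeVector(target_R, 0.0)
    trials = [
        simulate_trial(target, pop, cfg, rng=rng, jitter_target=False)
        for _ in range(n_trials)
    ]
    trials = [t for t in trials if t.trial is not None]
    u_center = afferent_map(target).u
    t_grid = np.arange(-150.0, 301.0)

    cds = []
    for c in pop:
        u_c = afferent_map(SaccadeVector(c.pref_vec.R, 0.0)).u
        if abs(u_c - u_center) > 1.25:
            continue
        trains = [res.trains[c.cell_id] for res in trials]
        onsets = [res.trial.onset for res in trials]
        counts = [
            res.trains[c.cell_id].in_window(
                *burst_window(res.trial.onset, res.trial.offset)
            ).size
            for res in trials
        ]
        cds.append(CellDensity(u_c, average_density(trains, onsets, 5.0, t_grid),
                               float(np.mean(counts)), cfg.N0))
    mean_dur = float(np.mean([r.trial.offset - r.trial.onset for r in trials]))
    profile = population_profile(cds, target)
    center_profile = profile.at(u_center)

    delays, dists = [], []
    for cd in cds:
        if not cd.n_spikes > 0.05 * cd.N_pref:
            continue
        xc = cross_correlate(center_profile, cd.density, (-20.0, mean_dur))
        delays.append(xc.optimal_delay)
        dists.append(cd.u_c - u_center)
    fit = linregress(dists, delays)
    return {
        "n_recruited": len(delays),
        "max_abs_delay_ms": float(np.max(np.abs(delays))),
        "delay_slope": float(fit.slope),
        "delay_slope_se": float(fit.stderr),
        "delays": delays,
        "distances_mm": dists,
    }


def endpoint_variance(
    amplitudes=(5, 10, 15, 20, 25, 30),
    n_trials: int = 200,
    n_cells: int = 100,
    seed: int = 2,
) -> dict:
    """Linearity of endpoint scatter with eccentricity under constant Cv.

    For each amplitude, decodes ``n_trials`` noisy trials and measures
    the total endpoint SD; reports the SD-vs-R linear fit.
    """
    cfg = SyntheticConfig(n_cells=n_cells, seed=seed)
    pop = make_map_population(cfg)
    rng = np.random.default_rng(seed)
    sds = []
    for R in amplitudes:
        pts = []
        for _ in range(n_trials):
            res = simulate_trial(SaccadeVector(float(R), 0.0), pop, cfg,
                                 rng=rng, jitter_target=False)
            if res.trial is None:
                continue
            phi = math.radians(res.trial.Phi)
            pts.append((res.trial.R * math.cos(phi), res.trial.R * math.sin(phi)))
        pts = np.asarray(pts)
        sds.append(math.sqrt(float(np.var(pts[:, 0]) + np.var(pts[:, 1]))))
    fit = linregress(amplitudes, sds)
    return {
        "amplitudes": list(amplitudes),
        "endpoint_sd_deg": sds,
        "r_squared": float(fit.rvalue**2),
        "sd_slope_per_deg": float(fit.slope),
    }
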