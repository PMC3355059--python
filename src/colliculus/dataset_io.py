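"""Dataset container, delimited-text readers/writers, and the analysis pipeline.

A dataset is three comma-separated tables plus a JSON manifest:

* ``cells.csv``   - one row per recorded cell (cell_id, animal_id, note),
* ``trials.csv``  - one row per saccade trial (trial_id, cell_id,
  onset_ms, offset_ms, R_deg, Phi_deg, target_R_deg, target_Phi_deg),
* ``spikes.csv``  - one row per spike (trial_id, spike_time_ms),
* ``manifest.json`` - generator/config parameters, seed, format version.

All times are ms on the trial clock (integers at 1 ms resolution);
angles are degrees.  Saccade-relative alignment is always computed on
the fly, never stored.

``run_pipeline`` chains the analysis stages in the order of the original
protocol: movement-field fit -> center-trial selection -> burst
statistics -> response clustering and Cv regression -> gradient
regressions -> population noise summary.  Per-cell failures are isolated
and logged; the run continues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .bursts import SpikeTrain, average_density, burst_stats, burst_window, skewness
from .motor_map import DEFAULT_MAP, MapParams, SaccadeVector
from .movement_fields import FitResult, fit_movement_field, select_center_trials
from .noise_analysis import (
    NoiseFit,
    cluster_responses,
    cv_regression,
    population_noise_summary,
)
from .population_dynamics import (
    CellDensity,
    PopulationProfile,
    cross_correlate,
    gradient_regressions,
    population_profile,
    weighted_trial_average,
)

__all__ = [
    "FORMAT_VERSION",
    "SaccadeTrial",
    "CellRecord",
    "Dataset",
    "DatasetError",
    "load_dataset",
    "save_dataset",
    "PipelineResult",
    "run_pipeline",
    "population_analysis",
]

FORMAT_VERSION = "1"

TRIAL_COLUMNS = [
    "trial_id", "cell_id", "onset_ms", "offset_ms",
    "R_deg", "Phi_deg", "target_R_deg", "target_Phi_deg",
]
CELL_COLUMNS = ["cell_id", "animal_id", "note"]
SPIKE_COLUMNS = ["trial_id", "spike_time_ms"]


class DatasetError(ValueError):
    """Raised when a dataset violates the format or its invariants."""


@dataclass(frozen=True)
class SaccadeTrial:
    """One saccade: detected onset/offset (ms) and its vector (R deg, Phi deg)."""

    trial_id: int
    cell_id: int
    onset: float
    offset: float
    R: float
    Phi: float
    target_R: float = math.nan
    target_Phi: float = math.nan

    @property
    def vector(self) -> SaccadeVector:
        return SaccadeVector(self.R, self.Phi)


@dataclass
class CellRecord:
    """A cell's trials and spike trains - the unit fed to every analysis."""

    cell_id: int
    animal_id: str
    trials: list[SaccadeTrial]
    spike_trains: dict[int, SpikeTrain]  # keyed by trial_id
    note: str = ""


@dataclass
class Dataset:
    cells: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    manifest: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        for name, df, cols in [
            ("cells", self.cells, CELL_COLUMNS),
            ("trials", self.trials, TRIAL_COLUMNS),
            ("spikes", self.spikes, SPIKE_COLUMNS),
        ]:
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise DatasetError(f"{name} table is missing columns {missing}")
        version = str(self.manifest.get("format_version", FORMAT_VERSION))
        if version != FORMAT_VERSION:
            raise DatasetError(
                f"format version mismatch: file has {version}, reader expects {FORMAT_VERSION}"
            )
        cell_ids = set(self.cells["cell_id"].astype(int))
        for row, t in self.trials.iterrows():
            if int(t["cell_id"]) not in cell_ids:
                raise DatasetError(
                    f"trials row {row}: cell_id {int(t['cell_id'])} not in cells table"
                )
            if not t["offset_ms"] > t["onset_ms"]:
                raise DatasetError(
                    f"trials row {row}: offset ({t['offset_ms']}) must exceed "
                    f"onset ({t['onset_ms']})"
                )
            if t["onset_ms"] < 0:
                raise DatasetError(f"trials row {row}: negative onset time")
        trial_ids = set(self.trials["trial_id"].astype(int))
        for row, s in self.spikes.iterrows():
            if int(s["trial_id"]) not in trial_ids:
                raise DatasetError(
                    f"spikes row {row}: trial_id {int(s['trial_id'])} not in trials table"
                )
            if s["spike_time_ms"] < 0:
                raise DatasetError(f"spikes row {row}: negative spike time")

    def cell_records(self) -> list[CellRecord]:
        spikes_by_trial = {
            int(tid): SpikeTrain(grp["spike_time_ms"].to_numpy())
            for tid, grp in self.spikes.groupby("trial_id")
        }
        records = []
        for _, c in self.cells.iterrows():
            cid = int(c["cell_id"])
            sub = self.trials[self.trials["cell_id"] == cid]
            trials = [
                SaccadeTrial(
                    int(t["trial_id"]), cid, float(t["onset_ms"]), float(t["offset_ms"]),
                    float(t["R_deg"]), float(t["Phi_deg"]),
                    float(t["target_R_deg"]), float(t["target_Phi_deg"]),
                )
                for _, t in sub.iterrows()
            ]
            trains = {
                t.trial_id: spikes_by_trial.get(t.trial_id, SpikeTrain([]))
                for t in trials
            }
            records.append(CellRecord(cid, str(c["animal_id"]), trials, trains,
                                      str(c.get("note", ""))))
        return records


def save_dataset(ds: Dataset, path: str | Path) -> Path:
    """Write the three CSV tables and the manifest into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ds.cells.to_csv(path / "cells.csv", index=False)
    ds.trials.to_csv(path / "trials.csv", index=False)
    ds.spikes.to_csv(path / "spikes.csv", index=False)
    manifest = dict(ds.manifest)
    manifest.setdefault("format_version", FORMAT_VERSION)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_dataset(path: str | Path) -> Dataset:
    """Read and validate a dataset directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    manifest = {}
    mf = path / "manifest.json"
    if mf.exists():
        manifest = json.loads(mf.read_text())
    ds = Dataset(
        cells=pd.read_csv(path / "cells.csv"),
        trials=pd.read_csv(path / "trials.csv"),
        spikes=pd.read_csv(path / "spikes.csv"),
        manifest=manifest,
    )
    ds.validate()
    return ds


@dataclass
class PipelineResult:
    """Per-cell table, Table-1-style gradient regressions, noise summary, log."""

    cell_table: pd.DataFrame
    gradient_table: pd.DataFrame
    noise_summary: dict | None
    noise_fits: dict[int, NoiseFit]
    fields: dict[int, FitResult]
    exclusions: list[str]


def _preferred_burst_stats(
    record: CellRecord,
    center_idx: list[int],
    kernel_sigma: float,
) -> dict:
    """Burst parameters for saccades into the movement-field center.

    N_s, F_m and gamma1 come from the raw spike counts/times (gamma1 from
    the spikes of all center trials pooled relative to saccade onset);
    F_p and T_p come from the trial-averaged spike density function.
    """
    trials = [record.trials[i] for i in center_idx]
    trains = [record.spike_trains[t.trial_id] for t in trials]
    counts, f_ms, pooled = [], [], []
    for t, train in zip(trials, trains):
        w = burst_window(t.onset, t.offset)
        spikes = train.in_window(*w)
        counts.append(spikes.size)
        f_ms.append(spikes.size / ((t.offset - t.onset) * 1e-3))
        pooled.extend((spikes - t.onset).tolist())
    try:
        g1 = skewness(pooled)
    except ValueError:
        g1 = math.nan

    mean_dur = float(np.mean([t.offset - t.onset for t in trials]))
    grid = np.arange(-120.0, mean_dur + 120.0)
    avg = average_density(trains, [t.onset for t in trials], kernel_sigma, grid)
    win = avg.slice(-20.0, mean_dur - 20.0)
    if win.values.size and win.values.max() > 0:
        i = int(np.argmax(win.values))
        f_p, t_p = float(win.values[i]), float(win.t_grid[i])
    else:
        f_p, t_p = 0.0, math.nan
    return {
        "N_s": float(np.mean(counts)),
        "F_m": float(np.mean(f_ms)),
        "F_p": f_p,
        "T_p": t_p,
        "gamma1": g1,
        "n_center_trials": len(trials),
    }


def run_pipeline(
    dataset: Dataset,
    kernel_sigma: float = 5.0,
    seed: int = 0,
    corrected: bool = True,
    map_params: MapParams = DEFAULT_MAP,
    log=None,
) -> PipelineResult:
    """Run every analysis stage over all cells of a dataset.

    Deterministic given dataset, parameters and seed.  ``log``, when
    given, is called with one message per exclusion/flag.
    """
    exclusions: list[str] = []
    noise_fits: dict[int, NoiseFit] = {}
    fields: dict[int, FitResult] = {}
    rows = []

    def note(msg: str) -> None:
        exclusions.append(msg)
        if log is not None:
            log(msg)

    for record in dataset.cell_records():
        cid = record.cell_id
        responses = []
        for t in record.trials:
            w = burst_window(t.onset, t.offset)
            n_s = record.spike_trains[t.trial_id].in_window(*w).size
            responses.append((t.vector, float(n_s)))
        fit = fit_movement_field(responses, map_params, seed=seed)
        fields[cid] = fit
        if fit.field is None:
            note(f"cell {cid}: movement-field fit failed ({fit.message})")
            continue
        pref = fit.field.preferred_vector(map_params)

        row = {
            "cell_id": cid,
            "R_pref": pref.R, "Phi_pref": pref.Phi,
            "u_pref": fit.field.u_pref, "v_pref": fit.field.v_pref,
            "sigma_mf": fit.field.sigma_mf, "N_pref": fit.field.N_pref,
            "sse": fit.sse, "n_trials": len(record.trials),
            "N_s": math.nan, "F_m": math.nan, "F_p": math.nan,
            "T_p": math.nan, "gamma1": math.nan, "Cv": math.nan,
        }

        sel = select_center_trials([v for v, _ in responses], fit.field, map_params)
        if sel is None:
            note(
                f"cell {cid}: fewer than 5 saccades within 0.5*sigma_mf of the "
                "movement-field center; excluded from center-response analyses"
            )
        else:
            idx, radius = sel
            row.update(_preferred_burst_stats(record, idx, kernel_sigma))
            row["center_radius_mm"] = radius

        clusters = cluster_responses(responses, fit.field, map_params)
        nf = cv_regression(clusters, fit.field, corrected=corrected)
        if nf is None:
            note(
                f"cell {cid}: fewer than 5 response clusters or mean-count span "
                "below 0.3*N_pref; excluded from noise analysis"
            )
        else:
            noise_fits[cid] = nf
            row["Cv"] = nf.Cv
            row["Cv_p"] = nf.p
        rows.append(row)

    cell_table = pd.DataFrame(rows)
    if len(cell_table):
        gradient_table = gradient_regressions(cell_table)
    else:
        gradient_table = pd.DataFrame()
    summary = population_noise_summary(list(noise_fits.values())) if noise_fits else None
    return PipelineResult(cell_table, gradient_table, summary, noise_fits, fields, exclusions)


def population_analysis(
    dataset: Dataset,
    result: PipelineResult,
    target_R: float,
    kernel_sigma: float = 5.0,
    map_params: MapParams = DEFAULT_MAP,
) -> tuple[PopulationProfile, pd.DataFrame]:
    """Population profile and burst-synchrony table for one target amplitude.

    Every fitted cell's preferred vector is rotated onto the horizontal
    meridian; trials matching the target ``(R, 0 deg)`` within 0.3 mm on
    the map are averaged per cell (Gaussian distance weights), pooled
    into a rostral-caudal population profile, and each cell's average
    burst is cross-correlated with the profile at the population center.
    Returns the profile and a per-cell table of (u_c, distance from
    center, r0, optimal_delay, r_opt).
    """
    from .motor_map import afferent_map as _aff

    target_vec = SaccadeVector(target_R, 0.0)
    u_center = _aff(target_vec, map_params).u
    records = {r.cell_id: r for r in dataset.cell_records()}

    cell_densities: list[tuple[int, CellDensity]] = []
    durations = []
    for _, row in result.cell_table.iterrows():
        cid = int(row["cell_id"])
        rec = records[cid]
        trials = [
            (t.vector, rec.spike_trains[t.trial_id], t.onset) for t in rec.trials
        ]
        dens = weighted_trial_average(trials, target_vec, phi_pref=row["Phi_pref"],
                                      kernel_sigma=kernel_sigma, p=map_params)
        if dens is None:
            continue
        # mean in-window count of the matched trials, for the 5%-of-peak gate
        from .motor_map import rotate_to_horizontal as _rot
        from .motor_map import map_distance as _dist
        counts = []
        for t in rec.trials:
            d = _dist(_aff(_rot(t.vector, row["Phi_pref"]), map_params),
                      _aff(target_vec, map_params))
            if d < 0.3:
                w = burst_window(t.onset, t.offset)
                counts.append(rec.spike_trains[t.trial_id].in_window(*w).size)
                durations.append(t.offset - t.onset)
        u_c = _aff(SaccadeVector(row["R_pref"], 0.0), map_params).u
        cell_densities.append(
            (cid, CellDensity(u_c, dens, float(np.mean(counts)), float(row["N_pref"])))
        )

    profile = population_profile([cd for _, cd in cell_densities], target_vec,
                                 map_params)
    mean_dur = float(np.mean(durations)) if durations else 50.0
    window = (-20.0, mean_dur)
    center = profile.at(u_center)
    rows = []
    if center.values.max() > 0:
        for cid, cd in cell_densities:
            if not (cd.n_spikes > 0.05 * cd.N_pref
                    and abs(cd.u_c - u_center) <= 1.25):
                continue
            try:
                xc = cross_correlate(center, cd.density, window)
            except ValueError:
                continue
            rows.append({"cell_id": cid, "u_c": cd.u_c,
                         "distance_mm": cd.u_c - u_center,
                         "r0": xc.r0, "optimal_delay_ms": xc.optimal_delay,
                         "r_opt": xc.r_opt})
    return profile, pd.DataFrame(rows)
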