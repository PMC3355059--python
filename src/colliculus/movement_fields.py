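"""Gaussian movement-field model on the motor map, fitting and trial selection.

An SC neuron fires for a range of saccade vectors, its movement field.
On the motor map this field is well described by a circular Gaussian:
the expected number of spikes for a saccade mapping to ``(u, v)`` is::

    N(u, v) = N_pref * exp( -((u - u_pref)^2 + (v - v_pref)^2) / (2*sigma_mf^2) )

Map coordinates (rather than visual coordinates) absorb the strong
amplitude asymmetry of movement fields in visual space.  The four free
parameters are estimated by nonlinear least squares with the Nelder-Mead
simplex; sigma_mf and N_pref are optimized in log space so the simplex
stays in the valid region without explicit bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .motor_map import (
    DEFAULT_MAP,
    MapParams,
    MapPoint,
    SaccadeVector,
    afferent_map,
    efferent_map,
    map_distance,
)

__all__ = [
    "MovementField",
    "FitResult",
    "mf_predict",
    "fit_movement_field",
    "select_center_trials",
]


@dataclass(frozen=True)
class MovementField:
    """Fitted Gaussian tuning of one cell on the motor map."""

    u_pref: float
    v_pref: float
    sigma_mf: float
    N_pref: float

    def __post_init__(self) -> None:
        if self.sigma_mf <= 0:
            raise ValueError("sigma_mf must be positive")
        if self.N_pref <= 0:
            raise ValueError("N_pref must be positive")

    @property
    def center(self) -> MapPoint:
        return MapPoint(self.u_pref, self.v_pref)

    def preferred_vector(self, p: MapParams = DEFAULT_MAP) -> SaccadeVector:
        """The saccade vector imaged at the field center (R_pref, Phi_pref)."""
        return efferent_map(self.center, p)


@dataclass(frozen=True)
class FitResult:
    field: MovementField | None
    sse: float
    residual_variance: float  # mean squared residual per response
    n_responses: int
    converged: bool
    message: str = ""


def mf_predict(
    field: MovementField,
    vec: SaccadeVector,
    p: MapParams = DEFAULT_MAP,
) -> float:
    """Expected spike count of a cell for a given saccade vector."""
    pt = afferent_map(vec, p)
    d2 = (pt.u - field.u_pref) ** 2 + (pt.v - field.v_pref) ** 2
    return field.N_pref * math.exp(-d2 / (2.0 * field.sigma_mf**2))


def _sse(theta: np.ndarray, uv: np.ndarray, counts: np.ndarray) -> float:
    u0, v0, log_sigma, log_npref = theta
    sigma2 = math.exp(2.0 * log_sigma)
    d2 = (uv[:, 0] - u0) ** 2 + (uv[:, 1] - v0) ** 2
    pred = math.exp(log_npref) * np.exp(-d2 / (2.0 * sigma2))
    r = counts - pred
    return float(r @ r)


def fit_movement_field(
    responses: list[tuple[SaccadeVector, float]],
    p: MapParams = DEFAULT_MAP,
    n_restarts: int = 5,
    seed: int = 0,
    sigma_init: float = 0.5,
    extrapolation_limit: float = 1.0,
    sigma_limit: float = 3.0,
) -> FitResult:
    """Least-squares fit of the Gaussian movement field to (vector, count) pairs.

    Initialization: (u_pref, v_pref) at the count-weighted centroid of the
    mapped responses, sigma_mf = ``sigma_init`` (0.5 mm is typical of SC
    movement fields), N_pref = max observed count.  ``n_restarts`` extra
    Nelder-Mead runs start from seeded perturbations; the best SSE wins.

    When the responses sample only one flank of the field the Gaussian is
    unidentifiable (the optimizer walks the center off to infinity while
    inflating N_pref).  Such fits are flagged as failures: the fitted
    center must lie within ``extrapolation_limit`` mm of a sampled map
    point, sigma_mf below ``sigma_limit`` mm, and N_pref below ten times
    the largest observed count.
    """
    if len(responses) < 8:
        return FitResult(None, math.inf, math.inf, len(responses), False,
                         "need at least 8 responses")
    uv = np.array([(afferent_map(v, p).u, afferent_map(v, p).v) for v, _ in responses])
    counts = np.array([float(n) for _, n in responses])
    if np.allclose(uv, uv[0], atol=1e-12):
        return FitResult(None, math.inf, math.inf, len(responses), False,
                         "degenerate: all responses at one map location")
    if counts.max() <= 0:
        return FitResult(None, math.inf, math.inf, len(responses), False,
                         "no spikes in any response")

    w = np.clip(counts, 0.0, None)
    centroid = (uv * w[:, None]).sum(axis=0) / w.sum() if w.sum() > 0 else uv.mean(axis=0)
    theta0 = np.array([centroid[0], centroid[1],
                       math.log(sigma_init), math.log(counts.max())])

    rng = np.random.default_rng(seed)
    best = None
    starts = [theta0] + [
        theta0 + rng.normal(0.0, [0.2, 0.2, 0.3, 0.3]) for _ in range(n_restarts)
    ]
    for start in starts:
        res = minimize(_sse, start, args=(uv, counts), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    u0, v0, log_sigma, log_npref = best.x
    field = MovementField(u0, v0, math.exp(log_sigma), math.exp(log_npref))
    resid_var = best.fun / len(responses)

    d_nearest = float(np.sqrt(((uv - [u0, v0]) ** 2).sum(axis=1)).min())
    if d_nearest > extrapolation_limit:
        return FitResult(None, float(best.fun), float(resid_var), len(responses),
                         False, "unidentifiable: center outside the sampled region")
    if field.sigma_mf > sigma_limit or field.N_pref > 10.0 * counts.max():
        return FitResult(None, float(best.fun), float(resid_var), len(responses),
                         False, "unidentifiable: responses sample a single flank")
    return FitResult(field, float(best.fun), float(resid_var), len(responses),
                     bool(best.success), best.message)


def select_center_trials(
    saccades: list[SaccadeVector],
    field: MovementField,
    p: MapParams = DEFAULT_MAP,
    min_trials: int = 5,
    r_start: float = 0.2,
    r_stop: float = 0.5,
    r_step: float = 0.01,
) -> tuple[list[int], float] | None:
    """Select the trials whose saccades land closest to the field center.

    Starting at radius 0.2*sigma_mf (map distance), the criterion widens
    in 0.01*sigma_mf steps until at least 5 trials qualify or the radius
    exceeds 0.5*sigma_mf.  Returns ``(trial_indices, radius_mm)`` for the
    smallest qualifying radius, or None when the cell must be excluded
    (fewer than 5 saccades within 0.5*sigma_mf of the center).
    """
    d = np.array([map_distance(afferent_map(s, p), field.center) for s in saccades])
    n_steps = int(round((r_stop - r_start) / r_step))
    for k in range(n_steps + 1):
        r = (r_start + k * r_step) * field.sigma_mf
        idx = np.flatnonzero(d <= r + 1e-9)  # tolerate fp error at the rim
        if idx.size >= min_trials:
            return list(idx), float(r)
    return None
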