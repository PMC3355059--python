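"""Signal-dependent and signal-independent spike-count noise.

Optimal-control theories of saccades assume multiplicative noise: the SD
of the motor command grows in proportion to its mean.  At the single-cell
level this is tested by clustering a cell's saccade responses into
non-overlapping groups of closely matching vectors (map distance between
any two members < 1*sigma_mf, at least five members), computing the mean
and SD of the spike count in each cluster, and regressing SD on mean.
The slope of that line is the coefficient of variation Cv; the intercept
estimates signal-independent (additive) noise in spikes.

Because saccade scatter within a cluster samples the movement-field
gradient, the raw SD overestimates intrinsic noise where the field is
steep.  The corrected variant replaces the spike-count variance with the
residual variance around the fitted movement-field prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from .motor_map import DEFAULT_MAP, MapParams, MapPoint, SaccadeVector, afferent_map
from .movement_fields import MovementField, mf_predict

__all__ = [
    "ResponseCluster",
    "NoiseFit",
    "cluster_responses",
    "cv_regression",
    "population_noise_summary",
]


@dataclass(frozen=True)
class ResponseCluster:
    """A group of >= 5 closely matching saccade responses of one cell."""

    trial_ids: tuple[int, ...]
    mean_Ns: float
    sd_Ns: float
    resid_sd_Ns: float
    centroid: MapPoint


@dataclass(frozen=True)
class NoiseFit:
    """Cv regression for one cell: SD (or residual SD) vs mean spike count."""

    Cv: float
    Cv_se: float
    intercept: float
    intercept_se: float
    r: float
    p: float
    n_clusters: int
    N_pref: float


def cluster_responses(
    responses: list[tuple[SaccadeVector, float]],
    field: MovementField,
    p: MapParams = DEFAULT_MAP,
    min_size: int = 5,
    max_diameter_sigma: float = 1.0,
) -> list[ResponseCluster]:
    """Partition a cell's responses into tight, non-overlapping clusters.

    Complete-linkage agglomerative clustering in map coordinates, cut at
    1*sigma_mf, guarantees every within-cluster pairwise distance is
    below the cut; clusters with fewer than ``min_size`` members are
    discarded.  Deterministic given input order.
    """
    if len(responses) < min_size:
        return []
    uv = np.array([(afferent_map(v, p).u, afferent_map(v, p).v) for v, _ in responses])
    counts = np.array([float(n) for _, n in responses])
    cut = max_diameter_sigma * field.sigma_mf

    if len(responses) == 1 or np.allclose(pdist(uv), 0.0):
        labels = np.ones(len(responses), dtype=int)
    else:
        Z = linkage(uv, method="complete")
        labels = fcluster(Z, t=cut, criterion="distance")

    clusters: list[ResponseCluster] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_size:
            continue
        ns = counts[idx]
        resid = ns - np.array(
            [mf_predict(field, responses[i][0], p) for i in idx]
        )
        clusters.append(
            ResponseCluster(
                trial_ids=tuple(int(i) for i in idx),
                mean_Ns=float(ns.mean()),
                sd_Ns=float(ns.std(ddof=1)),
                resid_sd_Ns=float(np.sqrt(np.mean(resid**2))),
                centroid=MapPoint(*uv[idx].mean(axis=0)),
            )
        )
    # stable order: by first trial index
    clusters.sort(key=lambda c: c.trial_ids[0])
    return clusters


def cv_regression(
    clusters: list[ResponseCluster],
    field: MovementField,
    corrected: bool = True,
    min_clusters: int = 5,
    min_span_frac: float = 0.3,
) -> NoiseFit | None:
    """OLS of cluster spike-count SD on cluster mean; slope = Cv.

    Requires at least five clusters whose mean counts span at least 30%
    of the cell's peak activity N_pref; returns None (cell excluded)
    otherwise.  ``corrected=True`` regresses the movement-field residual
    SD instead of the raw SD.
    """
    if len(clusters) < min_clusters:
        return None
    means = np.array([c.mean_Ns for c in clusters])
    if means.max() - means.min() <= min_span_frac * field.N_pref:
        return None
    sds = np.array([c.resid_sd_Ns if corrected else c.sd_Ns for c in clusters])
    fit = linregress(means, sds)
    return NoiseFit(
        Cv=float(fit.slope),
        Cv_se=float(fit.stderr),
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n_clusters=len(clusters),
        N_pref=float(field.N_pref),
    )


def population_noise_summary(fits: list[NoiseFit], alpha: float = 0.05) -> dict:
    """Mean +- SEM of Cv and intercept across cells, plus significance stats.

    The intercept is also expressed as a percentage of the cells' peak
    response N_pref (signal-independent noise relative to peak drive).
    """
    if not fits:
        raise ValueError("at least one valid fit required")
    cv = np.array([f.Cv for f in fits])
    ic = np.array([f.intercept for f in fits])
    icp = np.array([100.0 * f.intercept / f.N_pref for f in fits])
    n = len(fits)
    sem = (lambda x: float(x.std(ddof=1) / math.sqrt(n))) if n > 1 else (lambda x: math.nan)
    return {
        "n_cells": n,
        "Cv_mean": float(cv.mean()),
        "Cv_sem": sem(cv),
        "intercept_mean": float(ic.mean()),
        "intercept_sem": sem(ic),
        "intercept_pct_of_peak_mean": float(icp.mean()),
        "intercept_pct_of_peak_sem": sem(icp),
        "frac_significant_slope": float(np.mean([f.p < alpha for f in fits])),
    }
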