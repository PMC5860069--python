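"""Rain refinement: relabel ambiguous droplets between clusters as Rain.

"Rain" is the colloquial name for droplets of intermediate fluorescence
lying between the main clusters — typically partially amplified targets —
which should be excluded from Poisson counting. Two refinement passes are
provided:

* :func:`sd_rain` — axis-aligned per-channel bounds: a droplet further than
  ``n_sd`` sample standard deviations from its cluster mean in either
  channel becomes Rain;
* :func:`mahalanobis_rain` — elliptical bounds: a droplet whose squared
  Mahalanobis distance to its cluster exceeds the cluster's radius ``m_c``
  becomes Rain. Because the covariance enters, the ellipses follow cluster
  rotation ("lean"/"lift" artefacts), which axis-aligned bounds cannot.

The squared Mahalanobis distance used here is the standard
``(x − μ_c)ᵀ Σ_c⁻¹ (x − μ_c)`` with the *inverse* covariance. ``m_c``
bounds the squared distance: for a bivariate Gaussian cluster it is a χ²
quantile with 2 degrees of freedom (m_c = 30 keeps essentially every true
member; m_c ≈ 12 keeps 99.75%). The default is deliberately generous and
is expected to be adjusted manually per assay.

Both passes compute cluster statistics once from the incoming labels and
only ever change labels from {NN, NP, PN, PP} to Rain.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .classification import ClusterStats, cluster_stats
from .errors import NumericalError
from .model import CLUSTER_LABELS, DropletTable

DEFAULT_N_SD = 5.0
DEFAULT_MAX_DISTANCE = 30.0
#: Relative condition-number limit beyond which a cluster covariance is
#: treated as singular (error rather than silent regularisation).
COV_CONDITION_LIMIT = 1e10


def sd_rain(table: DropletTable, n_sd: float = DEFAULT_N_SD) -> DropletTable:
    """Relabel as Rain droplets beyond ``n_sd`` standard deviations of their cluster.

    Per cluster, the per-channel sample mean and standard deviation are
    computed; a droplet is relabelled iff its deviation exceeds
    ``n_sd · sd`` in either channel. Clusters with fewer than 2 droplets
    (no defined sd) are left untouched.
    """
    if not n_sd > 0:
        raise ValueError(f"n_sd must be positive, got {n_sd}")
    labels = table.labels.copy()
    X = table.amplitudes
    for lab in CLUSTER_LABELS:
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            continue
        pts = X[idx]
        mean = pts.mean(axis=0)
        sd = pts.std(axis=0, ddof=1)
        outlying = (np.abs(pts - mean) > n_sd * sd).any(axis=1)
        labels[idx[outlying]] = "Rain"
    return table.with_labels(labels)


def _checked_covariance(stats: ClusterStats) -> np.ndarray:
    cov = np.asarray(stats.covariance, dtype=np.float64)
    if not np.isfinite(cov).all() or np.linalg.cond(cov) > COV_CONDITION_LIMIT:
        raise NumericalError(
            f"covariance for cluster {stats.label} is singular or "
            f"ill-conditioned; fall back to threshold or sd-based gating"
        )
    return cov


def mahalanobis_sq(point, stats: ClusterStats) -> float:
    """Squared Mahalanobis distance (x − μ_c)ᵀ Σ_c⁻¹ (x − μ_c) of a point to a cluster."""
    cov = _checked_covariance(stats)
    diff = np.asarray(point, dtype=np.float64) - stats.mean
    return float(diff @ np.linalg.solve(cov, diff))


def _mahalanobis_sq_many(X: np.ndarray, stats: ClusterStats) -> np.ndarray:
    cov = _checked_covariance(stats)
    diff = X - stats.mean
    return np.einsum("ij,ji->i", diff, np.linalg.solve(cov, diff.T))


def mahalanobis_rain(
    table: DropletTable,
    max_distance: Mapping[str, float] | None = None,
    default_max_distance: float = DEFAULT_MAX_DISTANCE,
) -> DropletTable:
    """Relabel as Rain droplets outside their cluster's Mahalanobis ellipse.

    Per class ``c``, the sample mean and covariance are estimated from the
    incoming labels and droplets with squared Mahalanobis distance above
    ``m_c`` become Rain. ``max_distance`` maps class labels to their ``m_c``;
    classes absent from the mapping use ``default_max_distance``. Classes
    with fewer than 3 droplets (no invertible sample covariance) are left
    untouched.
    """
    max_distance = dict(max_distance or {})
    for lab, m in list(max_distance.items()) + [("default", default_max_distance)]:
        if not m > 0:
            raise ValueError(f"max distance for {lab} must be positive, got {m}")
    labels = table.labels.copy()
    X = table.amplitudes
    for stats in cluster_stats(table):
        if stats.count < 3:
            continue
        m_c = float(max_distance.get(stats.label, default_max_distance))
        idx = np.flatnonzero(labels == stats.label)
        d2 = _mahalanobis_sq_many(X[idx], stats)
        labels[idx[d2 > m_c]] = "Rain"
    return table.with_labels(labels)
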