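"""Droplet gating: linear thresholds, four-centre k-means, and k-NN.

Three classifiers assign each droplet to NN/NP/PN/PP:

* :func:`threshold_classify` — independent linear gates per channel, the
  manual-gating baseline;
* :func:`kmeans_classify` — Lloyd's algorithm with four candidate groups,
  effective when clusters do not fall into four axis-aligned quadrants;
* :func:`knn_classify` — majority vote among the k nearest droplets of a
  labelled training well.

k-means runs on raw (unstandardised) amplitudes by default so that cluster
geometry matches what is seen on an amplitude scatter plot; per-channel
standardisation is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .errors import ClassificationError
from .model import CLUSTER_LABELS, DropletTable, Plate


class Thresholds(NamedTuple):
    """Per-channel linear gates (fluorescence units)."""

    ch1: float
    ch2: float


#: Worked-example manual gates for the KRAS duplex assay geometry.
DEFAULT_THRESHOLDS = Thresholds(6789.0, 3000.0)

DEFAULT_KMEANS_MAX_ITER = 100
DEFAULT_KMEANS_TOL = 1e-6  # amplitude units; far below fluorescence noise
DEFAULT_KNN_K = 1
DEFAULT_MIN_VOTE_FRACTION = 0.51


@dataclass(frozen=True)
class ClusterStats:
    """Per-class sample mean vector, covariance matrix and droplet count."""

    label: str
    mean: np.ndarray
    covariance: np.ndarray
    count: int
    singleton: bool = False  # covariance undefined (n == 1), reported as zeros


def threshold_classify(
    table: DropletTable, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> DropletTable:
    """Gate droplets with one linear threshold per channel.

    A droplet is positive in a channel iff its amplitude is ≥ that channel's
    threshold (a boundary droplet counts as positive). No droplet is labelled
    Rain by this operation.
    """
    th = Thresholds(float(thresholds[0]), float(thresholds[1]))
    if not (np.isfinite(th.ch1) and np.isfinite(th.ch2)):
        raise ValueError("thresholds must be finite")
    pos1 = table.ch1 >= th.ch1
    pos2 = table.ch2 >= th.ch2
    labels = np.empty(len(table), dtype="U12")
    labels[~pos1 & ~pos2] = "NN"
    labels[~pos1 & pos2] = "NP"
    labels[pos1 & ~pos2] = "PN"
    labels[pos1 & pos2] = "PP"
    return table.with_labels(labels)


def _as_centres(centres) -> np.ndarray:
    C = np.asarray(centres, dtype=np.float64)
    if C.shape != (4, 2):
        raise ClassificationError(f"expected 4 two-dimensional centres, got shape {C.shape}")
    if not np.isfinite(C).all():
        raise ClassificationError("centres must be finite")
    for i in range(4):
        for j in range(i + 1, 4):
            if np.array_equal(C[i], C[j]):
                raise ClassificationError(f"centres {i} and {j} are identical: {C[i]}")
    return C


def assign_centres_to_classes(centres) -> dict[int, str]:
    """Name four cluster centres NN/NP/PN/PP by their geometry.

    NN is the centre with the smallest rank sum over the two coordinates and
    PP the largest; of the remaining two, the centre with larger Channel 1
    amplitude is PN and the other NP. The mapping is a bijection and is
    invariant under permutation of the input.
    """
    C = _as_centres(centres)
    ranksum = rankdata(C[:, 0]) + rankdata(C[:, 1])
    coordsum = C.sum(axis=1)

    def extreme(sign: float) -> int:
        keys = list(zip(sign * ranksum, sign * coordsum))
        best = min(range(4), key=lambda i: keys[i])
        ties = [i for i in range(4) if keys[i] == keys[best]]
        if len(ties) > 1:
            raise ClassificationError(
                "ambiguous centre geometry (tied rank sums); map centres to "
                "classes manually"
            )
        return best

    nn = extreme(+1.0)
    pp = extreme(-1.0)
    rest = [i for i in range(4) if i not in (nn, pp)]
    a, b = rest
    if C[a, 0] > C[b, 0]:
        pn, np_ = a, b
    elif C[b, 0] > C[a, 0]:
        pn, np_ = b, a
    elif C[a, 1] > C[b, 1]:  # equal Channel 1: larger Channel 2 is NP
        pn, np_ = b, a
    elif C[b, 1] > C[a, 1]:
        pn, np_ = a, b
    else:  # unreachable for distinct centres, kept as a guard
        raise ClassificationError(
            "ambiguous centre geometry (exact coordinate ties); map centres "
            "to classes manually"
        )
    return {nn: "NN", np_: "NP", pn: "PN", pp: "PP"}


@dataclass(frozen=True)
class LloydResult:
    assignments: np.ndarray  # (n,) centre indices
    centres: np.ndarray  # (4, 2) final centres
    n_iter: int
    converged: bool
    wcss: tuple[float, ...]  # within-cluster sum of squares per assignment step


def lloyd(
    X: np.ndarray,
    initial_centres: np.ndarray,
    max_iter: int = DEFAULT_KMEANS_MAX_ITER,
    tol: float = DEFAULT_KMEANS_TOL,
) -> LloydResult:
    """Standard Lloyd iteration with an absolute centre-movement stopping rule.

    Droplets are assigned to the nearest centre by Euclidean distance (ties
    to the lowest centre index), centres are recomputed as cluster means, and
    iteration stops when the largest absolute centre coordinate movement
    falls below ``tol`` or after ``max_iter`` updates; a final assignment is
    made against the final centres. An empty cluster raises
    :class:`~dropgate.errors.ClassificationError` naming the offending
    initial centre.
    """
    X = np.asarray(X, dtype=np.float64)
    init = np.asarray(initial_centres, dtype=np.float64)
    C = init.copy()
    wcss: list[float] = []
    converged = False
    n_iter = 0
    rows = np.arange(X.shape[0])
    for n_iter in range(1, max_iter + 1):
        d2 = cdist(X, C, metric="sqeuclidean")
        assign = d2.argmin(axis=1)
        wcss.append(float(d2[rows, assign].sum()))
        new = np.empty_like(C)
        for j in range(C.shape[0]):
            member = assign == j
            if not member.any():
                raise ClassificationError(
                    f"k-means produced an empty cluster for initial centre "
                    f"{j} at {tuple(init[j])}; re-seed with different centres"
                )
            new[j] = X[member].mean(axis=0)
        shift = float(np.abs(new - C).max())
        C = new
        if shift < tol:
            converged = True
            break
    d2 = cdist(X, C, metric="sqeuclidean")
    assign = d2.argmin(axis=1)
    wcss.append(float(d2[rows, assign].sum()))
    return LloydResult(assign, C, n_iter, converged, tuple(wcss))


def default_initial_centres(table: DropletTable) -> np.ndarray:
    """Deterministic seeding: corner points of per-channel 10th/90th percentiles.

    Suited to wells where all four clusters are populated; for designs where
    one class is rare (e.g. low-fraction mutant wells) supply centres
    explicitly, e.g. from a control well.
    """
    lo1, hi1 = np.quantile(table.ch1, [0.1, 0.9])
    lo2, hi2 = np.quantile(table.ch2, [0.1, 0.9])
    return np.array([[lo1, lo2], [lo1, hi2], [hi1, lo2], [hi1, hi2]])


def kmeans_classify(
    table: DropletTable,
    initial_centres=None,
    max_iter: int = DEFAULT_KMEANS_MAX_ITER,
    tol: float = DEFAULT_KMEANS_TOL,
    standardize: bool = False,
) -> tuple[DropletTable, list[ClusterStats]]:
    """Classify droplets into four candidate groups by k-means.

    Returns the labelled table and per-cluster statistics. Centres default
    to :func:`default_initial_centres`. With ``standardize`` the Lloyd
    iteration runs on per-channel unit-variance amplitudes (centres are
    reported in raw units either way).
    """
    if len(table) < 4:
        raise ClassificationError(f"k-means needs at least 4 droplets, got {len(table)}")
    X = table.amplitudes
    if (X == X[0]).all():
        raise ClassificationError("degenerate well: all droplet amplitudes identical")
    C = _as_centres(default_initial_centres(table) if initial_centres is None else initial_centres)
    if standardize:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        result = lloyd(X / scale, C / scale, max_iter=max_iter, tol=tol)
        centres = result.centres * scale
    else:
        result = lloyd(X, C, max_iter=max_iter, tol=tol)
        centres = result.centres
    mapping = assign_centres_to_classes(centres)
    labels = np.array([mapping[j] for j in range(4)], dtype="U12")[result.assignments]
    labelled = table.with_labels(labels)
    return labelled, cluster_stats(labelled)


def kmeans_classify_plate(
    plate: Plate, initial_centres=None, **kwargs
) -> tuple[Plate, list[ClusterStats]]:
    """k-means over all wells pooled, then labels split back per well.

    Pooling lets sparsely populated wells (e.g. low-input samples with almost
    no double-positive droplets) borrow cluster geometry from the rest of
    the plate.
    """
    pooled = plate.pooled()
    labelled, stats = kmeans_classify(pooled, initial_centres=initial_centres, **kwargs)
    return plate.with_pooled_labels(labelled.labels), stats


def knn_classify(
    table: DropletTable,
    train: DropletTable,
    k: int = DEFAULT_KNN_K,
    min_vote_fraction: float = DEFAULT_MIN_VOTE_FRACTION,
) -> DropletTable:
    """Classify droplets by majority vote among the k nearest training droplets.

    Distances are Euclidean; ties in distance are broken by training-row
    order. If the winning vote fraction is below ``min_vote_fraction`` the
    droplet is labelled ``Unclassified``. ``min_vote_fraction`` must exceed
    0.5, so a winning vote is always unique.
    """
    if len(train) == 0:
        raise ClassificationError("k-NN training table is empty")
    bad = set(train.labels.tolist()) - set(CLUSTER_LABELS)
    if bad:
        raise ClassificationError(
            f"k-NN training labels must be one of {CLUSTER_LABELS}; found {sorted(bad)}"
        )
    if not 1 <= k <= len(train):
        raise ClassificationError(f"k must be in [1, {len(train)}], got {k}")
    if not 0.5 < min_vote_fraction <= 1.0:
        raise ClassificationError(
            f"min_vote_fraction must be in (0.5, 1], got {min_vote_fraction}"
        )
    if len(table) == 0:
        return table.with_labels(table.labels)
    d = cdist(table.amplitudes, train.amplitudes)
    neighbours = np.argsort(d, axis=1, kind="stable")[:, :k]
    code = {lab: i for i, lab in enumerate(CLUSTER_LABELS)}
    train_codes = np.array([code[l] for l in train.labels])
    votes = np.zeros((len(table), 4), dtype=np.int64)
    rows = np.repeat(np.arange(len(table)), k)
    np.add.at(votes, (rows, train_codes[neighbours].ravel()), 1)
    top = votes.max(axis=1)
    winner = votes.argmax(axis=1)
    labels = np.where(
        top / k >= min_vote_fraction,
        np.array(CLUSTER_LABELS, dtype="U12")[winner],
        np.array("Unclassified", dtype="U12"),
    )
    return table.with_labels(labels)


def cluster_stats(table: DropletTable) -> list[ClusterStats]:
    """Sample mean and covariance (denominator n−1) per NN/NP/PN/PP class.

    Classes without droplets are omitted; singleton classes get a zero
    covariance and are flagged. Rain and Unclassified droplets are excluded.
    """
    X = table.amplitudes
    out: list[ClusterStats] = []
    for lab in CLUSTER_LABELS:
        member = table.labels == lab
        n = int(member.sum())
        if n == 0:
            continue
        pts = X[member]
        mean = pts.mean(axis=0)
        if n == 1:
            cov = np.zeros((2, 2))
        else:
            cov = np.cov(pts.T, ddof=1)
        out.append(ClusterStats(lab, mean, cov, n, singleton=(n == 1)))
    return out
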