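"""Deliberately naive reference implementations used as independent oracles.

Everything here is written with explicit Python loops and no shared code
with the package, so that agreement with the vectorised implementations is
a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_lloyd(X, initial_centres, max_iter=100, tol=1e-6):
    """Loop-based Lloyd k-means: returns (assignments, centres).

    Same conventions as the implementation under test: nearest centre by
    Euclidean distance with ties to the lowest index, stop when the largest
    absolute centre coordinate movement is below ``tol``, final assignment
    against the final centres.
    """
    X = [tuple(map(float, row)) for row in np.asarray(X)]
    C = [tuple(map(float, row)) for row in np.asarray(initial_centres)]
    k = len(C)

    def nearest(point):
        best, best_d = 0, math.inf
        for j in range(k):
            d = (point[0] - C[j][0]) ** 2 + (point[1] - C[j][1]) ** 2
            if d < best_d:
                best, best_d = j, d
        return best

    for _ in range(max_iter):
        assign = [nearest(x) for x in X]
        new = []
        for j in range(k):
            members = [X[i] for i in range(len(X)) if assign[i] == j]
            if not members:
                raise ValueError(f"empty cluster {j}")
            new.append(
                (
                    sum(m[0] for m in members) / len(members),
                    sum(m[1] for m in members) / len(members),
                )
            )
        shift = max(
            max(abs(new[j][0] - C[j][0]), abs(new[j][1] - C[j][1])) for j in range(k)
        )
        C = new
        if shift < tol:
            break
    assign = [nearest(x) for x in X]
    return np.array(assign), np.array(C)


def brute_force_knn(X, train_X, train_labels, k, min_vote_fraction):
    """Loop-based k-NN with training-row-order tie-breaks on distance."""
    out = []
    train = [tuple(map(float, row)) for row in np.asarray(train_X)]
    for x in np.asarray(X, dtype=float):
        dists = [
            ((x[0] - t[0]) ** 2 + (x[1] - t[1]) ** 2, i) for i, t in enumerate(train)
        ]
        dists.sort()  # ties broken by training row index
        votes: dict[str, int] = {}
        for _, i in dists[:k]:
            votes[train_labels[i]] = votes.get(train_labels[i], 0) + 1
        label, count = max(votes.items(), key=lambda kv: kv[1])
        out.append(label if count / k >= min_vote_fraction else "Unclassified")
    return np.array(out, dtype="U12")


def brute_force_mahalanobis_sq(X, points_in_cluster):
    """Per-point squared Mahalanobis distances via explicit matrix inverse."""
    pts = np.asarray(points_in_cluster, dtype=float)
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    inv = np.linalg.inv(cov)
    out = []
    for x in np.asarray(X, dtype=float):
        d = x - mean
        out.append(float(d @ inv @ d))
    return np.array(out)
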