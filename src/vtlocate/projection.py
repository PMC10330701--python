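"""Projection of a predicted site onto a triangle centroid of the mesh.

A regression-predicted site generally lies off the endocardial surface;
the method reports one of the mesh's triangle centroids instead.  Two
rules are implemented:

* **SA (smallest angle)** — the element whose centroid direction from the
  LV cavity center makes the smallest angle with the predicted site's
  direction.  Scale-free in the radial coordinate, which on a prolate
  (non-spherical) ventricle can select a geometrically distant element —
  the projection error the 1-NN rule was introduced to remove.
* **KNN (1-nearest neighbor)** — the element with the nearest centroid in
  Euclidean distance, K fixed at 1.

Ties are broken toward the lowest element id.  ``knn_oracle`` is a plain
exhaustive scan kept as the reference any accelerated nearest-neighbor
implementation must match exactly, tie-breaks included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh import TriMesh, UndefinedDirectionError
from .model import PredictedSite

__all__ = [
    "ProjectionResult",
    "project_sa",
    "project_knn",
    "knn_oracle",
    "project_batch",
]

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class ProjectionResult:
    """Winning element (1-based id), its score, and the method tag.

    ``score`` is the smallest angle in radians for SA, or the shortest
    Euclidean distance in mm for KNN.  ``tie_count`` counts co-optimal
    elements (score within a 1e-9 relative band of the winner).
    """

    element: int
    score: float
    method: str
    tie_count: int = 1


def _as_point(site: PredictedSite | np.ndarray) -> np.ndarray:
    if isinstance(site, PredictedSite):
        return site.point
    return np.asarray(site, dtype=float).reshape(3)


def _tie_count(scores: np.ndarray, best: float) -> int:
    return int(np.sum(scores <= best + _TIE_RTOL * max(best, 1.0)))


def project_sa(mesh: TriMesh, site: PredictedSite | np.ndarray) -> ProjectionResult:
    """Smallest-angle projection.

    For every element t, theta_t = arccos(A_t . B / (|A_t| |B|)) with A_t
    the cavity-center-to-centroid vector and B the cavity-center-to-site
    vector; the cosine is clamped to [-1, 1] before arccos.  Returns the
    element minimizing theta_t (lowest id on ties).
    """
    b = _as_point(site) - mesh.cavity_center
    nb = np.linalg.norm(b)
    if nb == 0:
        raise UndefinedDirectionError(
            "site coincides with the cavity center; direction undefined"
        )
    a = mesh.centroids - mesh.cavity_center
    na = np.linalg.norm(a, axis=1)
    if np.any(na == 0):
        raise UndefinedDirectionError(
            "a centroid coincides with the cavity center"
        )
    theta = np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0))
    best = int(np.argmin(theta))  # argmin returns the first = lowest id
    return ProjectionResult(
        element=best + 1,
        score=float(theta[best]),
        method="sa",
        tie_count=_tie_count(theta, float(theta[best])),
    )


def project_knn(
    mesh: TriMesh, site: PredictedSite | np.ndarray, k: int = 1
) -> ProjectionResult:
    """1-nearest-neighbor projection onto the element centroids.

    Only K = 1 is supported: with a single labelled point per class, a
    majority vote over K > 1 neighbors is not defined, so larger K is
    rejected rather than guessed at.
    """
    if k != 1:
        raise ValueError(f"only k=1 is supported, got k={k}")
    if mesh.n_faces == 0:
        raise ValueError("empty mesh")
    p = _as_point(site)
    d = mesh.centroids - p
    dist2 = (d**2).sum(axis=1)
    best = int(np.argmin(dist2))
    score = math.sqrt(float(dist2[best]))
    ties = int(np.sum(np.sqrt(dist2) <= score + _TIE_RTOL * max(score, 1.0)))
    return ProjectionResult(element=best + 1, score=score, method="knn", tie_count=ties)


def project_batch(mesh: TriMesh, points: np.ndarray, method: str) -> np.ndarray:
    """Project many sites at once; returns 1-based element ids.

    Semantically identical to looping :func:`project_sa` /
    :func:`project_knn` (same argmin tie-break toward the lowest id); the
    batch path exists because the bootstrap protocol projects hundreds of
    thousands of sites.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if method == "knn":
        d = pts[:, None, :] - mesh.centroids[None, :, :]
        return np.argmin((d**2).sum(axis=-1), axis=1) + 1
    if method == "sa":
        a = mesh.centroids - mesh.cavity_center
        b = pts - mesh.cavity_center
        nb = np.linalg.norm(b, axis=1)
        if np.any(nb == 0):
            raise UndefinedDirectionError(
                "a site coincides with the cavity center"
            )
        cosm = (b @ a.T) / (nb[:, None] * np.linalg.norm(a, axis=1)[None, :])
        return np.argmin(np.arccos(np.clip(cosm, -1.0, 1.0)), axis=1) + 1
    raise ValueError(f"unknown projection method '{method}'")


def knn_oracle(mesh: TriMesh, site: PredictedSite | np.ndarray) -> int:
    """Reference nearest-centroid scan: plain loop, strict-less keeps the
    lowest element id on exact ties.  Returns a 1-based element id."""
    px, py, pz = (float(v) for v in _as_point(site))
    best_id, best_d2 = -1, math.inf
    for i, (cx, cy, cz) in enumerate(mesh.centroids.tolist()):
        dx, dy, dz = cx - px, cy - py, cz - pz
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < best_d2:
            best_id, best_d2 = i, d2
    return best_id + 1
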