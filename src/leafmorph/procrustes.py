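"""Generalized Procrustes analysis of landmark configurations.

Superimposition removes translation (centering), size (unit centroid size),
rotation, and optionally reflection, placing all configurations in a common
shape space.  The generalized fit iterates rotation-to-the-mean until the mean
shape stabilises.  The solution is defined only up to a global rotation; for
reproducibility the final mean is anchored to the first input configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import LandmarkConfig, LeafCollection
from .errors import DegenerateShapeError, ValidationError


@dataclass(frozen=True)
class GPAResult:
    aligned: tuple[LandmarkConfig, ...]
    mean_shape: LandmarkConfig
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool


def center_and_scale(config: LandmarkConfig) -> tuple[LandmarkConfig, float]:
    """Center a configuration at the origin and scale it to unit centroid size.

    Returns the normalized configuration and the original centroid size
    (root of summed squared distances of landmarks to their centroid).
    """
    pts = config.points
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size < 1e-12:
        raise DegenerateShapeError("all landmarks coincide; centroid size is zero")
    return LandmarkConfig(centered / size), size


def _optimal_rotation(A: np.ndarray, B: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Orthogonal R (applied to B as B @ R.T) minimising ||A - B R^T||_F."""
    M = B.T @ A  # 2x2
    U, _, Vt = np.linalg.svd(M)
    R = (U @ Vt).T
    if not allow_reflection and np.linalg.det(R) < 0:
        D = np.diag([1.0, -1.0])
        R = (U @ D @ Vt).T
    return R


def optimal_superimposition(
    A: LandmarkConfig, B: LandmarkConfig, allow_reflection: bool = True
) -> tuple[np.ndarray, float]:
    """Best orthogonal map of B onto A (both centered, unit size).

    Returns ``(R, residual)`` where ``R`` is the 2x2 orthogonal matrix applied
    to B's points as ``B @ R.T`` and ``residual`` is the root summed squared
    distance after superimposition, minimal over the permitted transform set
    (rotations, plus reflections when allowed).
    """
    a, b = A.points, B.points
    if a.shape != b.shape:
        raise ValidationError("configurations must have the same landmark count")
    R = _optimal_rotation(a, b, allow_reflection)
    resid = float(np.sqrt(((a - b @ R.T) ** 2).sum()))
    return R, resid


def procrustes_distance(A: LandmarkConfig, B: LandmarkConfig, allow_reflection: bool = True) -> float:
    """Partial Procrustes distance: superimposition residual after centering
    and unit-size scaling.  Symmetric; zero for similarity-equivalent shapes."""
    a, _ = center_and_scale(A)
    b, _ = center_and_scale(B)
    _, resid = optimal_superimposition(a, b, allow_reflection=allow_reflection)
    return resid


def gpa(
    configs,
    allow_reflection: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes analysis of two or more configurations.

    Iteratively rotates every unit-size configuration onto the evolving mean
    until the mean moves less than ``tol`` (root summed squares) between
    iterations.  The objective (summed squared distance of aligned
    configurations to the mean) is non-increasing across iterations.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValidationError("GPA needs at least 2 configurations")
    normed = []
    sizes = []
    for cfg in configs:
        c, s = center_and_scale(cfg)
        normed.append(c.points)
        sizes.append(s)
    shapes = np.array(normed)  # (n, k, 2)

    def renorm(m: np.ndarray) -> np.ndarray:
        m = m - m.mean(axis=0)
        return m / np.sqrt((m**2).sum())

    mean = renorm(shapes[0].copy())
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(shapes)):
            R = _optimal_rotation(mean, shapes[i], allow_reflection)
            shapes[i] = shapes[i] @ R.T
        new_mean = renorm(shapes.mean(axis=0))
        delta = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if delta < tol:
            converged = True
            break

    # anchor the global rotation: align the mean to the first input
    first, _ = center_and_scale(configs[0])
    R = _optimal_rotation(first.points, mean, allow_reflection=False)
    mean = mean @ R.T
    shapes = shapes @ R.T

    mean_of_aligned = shapes.mean(axis=0)
    return GPAResult(
        aligned=tuple(LandmarkConfig(s) for s in shapes),
        mean_shape=LandmarkConfig(mean_of_aligned),
        centroid_sizes=np.array(sizes),
        iterations=iterations,
        converged=converged,
    )


def align_collection(collection: LeafCollection, allow_reflection: bool = True) -> tuple[LeafCollection, GPAResult]:
    """Run GPA over every landmark-bearing record of a collection.

    Returns a copy of the collection with aligned landmark configurations (in
    the original record order) plus the full :class:`GPAResult`.
    """
    from dataclasses import replace

    idx = [i for i, r in enumerate(collection.records) if r.landmarks is not None]
    if len(idx) < 2:
        raise ValidationError("collection has fewer than 2 landmark configurations")
    result = gpa(
        [collection.records[i].landmarks for i in idx],
        allow_reflection=allow_reflection,
    )
    records = list(collection.records)
    for j, i in enumerate(idx):
        records[i] = replace(records[i], landmarks=result.aligned[j])
    return LeafCollection(records=tuple(records), numbering=collection.numbering), result


def node_mean_shapes(collection: LeafCollection) -> dict[int, LandmarkConfig]:
    """Coordinate-wise mean aligned configuration per heteroblastic node.

    Assumes the collection is already aligned and base-first numbered.  Nodes
    with no landmark-bearing leaves are absent from the result.
    """
    groups: dict[int, list[np.ndarray]] = {}
    for rec in collection.records:
        if rec.landmarks is not None:
            groups.setdefault(rec.node, []).append(rec.landmarks.points)
    return {
        node: LandmarkConfig(np.mean(pts, axis=0)) for node, pts in sorted(groups.items())
    }
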