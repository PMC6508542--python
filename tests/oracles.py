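"""Independent oracles used by the tests.

Each oracle takes a route through the problem that is deliberately different
from the package implementation: brute-force grids, complex-arithmetic
Procrustes, generic numerical quadrature, Monte-Carlo geometry, and naive
agglomeration.  They are slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.integrate import quad


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------


def grid_rotation_residual(
    A: np.ndarray, B: np.ndarray, allow_reflection: bool = True, step: float = 0.001
) -> float:
    """Brute-force minimum superimposition residual over a dense rotation
    grid, trying both determinant signs."""
    angles = np.arange(0.0, 2 * np.pi, step)
    cos, sin = np.cos(angles), np.sin(angles)
    rots = np.stack([np.stack([cos, -sin], -1), np.stack([sin, cos], -1)], -2)
    candidates = [rots]
    if allow_reflection:
        flip = np.diag([1.0, -1.0])
        candidates.append(rots @ flip)
    best = np.inf
    for cand in candidates:
        transformed = np.einsum("kij,nj->kni", cand, B)
        resid = np.sqrt(((A[None] - transformed) ** 2).sum(axis=(1, 2)))
        best = min(best, float(resid.min()))
    return best


def _unit_complex(pts: np.ndarray) -> np.ndarray:
    z = pts[:, 0] + 1j * pts[:, 1]
    z = z - z.mean()
    return z / np.linalg.norm(z)


def gpa_complex_oracle(
    configs, allow_reflection: bool = True, tol: float = 1e-12, max_iter: int = 5000
):
    """Alternating-minimization GPA in complex arithmetic.

    Shapes are unit complex vectors; the optimal rotation of z onto the mean
    m is multiplication by the phase of <m, z>; with reflection allowed, the
    conjugated shape competes as a candidate.  Returns (mean, aligned) as
    real (k, 2) arrays; the mean is anchored by rotating it onto the first
    input configuration.
    """
    zs = [_unit_complex(np.asarray(c, dtype=float)) for c in configs]
    mean = zs[0].copy()
    for _ in range(max_iter):
        new = []
        for z in zs:
            cands = [z, np.conj(z)] if allow_reflection else [z]
            best, score = None, -np.inf
            for c in cands:
                ip = np.vdot(c, mean)  # sum(conj(c) * mean)
                if abs(ip) > score:
                    score, best = abs(ip), c * (ip / abs(ip))
            new.append(best)
        zs = new
        m = np.mean(zs, axis=0)
        m = m - m.mean()
        m = m / np.linalg.norm(m)
        if np.linalg.norm(m - mean) < tol:
            mean = m
            break
        mean = m
    # anchor the global rotation to the first input (rotation only)
    first = _unit_complex(np.asarray(configs[0], dtype=float))
    ip = np.vdot(mean, first)
    phase = ip / abs(ip)
    mean = mean * phase
    zs = [z * phase for z in zs]
    to_real = lambda z: np.column_stack([z.real, z.imag])  # noqa: E731
    return to_real(np.mean(zs, axis=0)), [to_real(z) for z in zs]


def pairwise_procrustes_oracle(configs, allow_reflection: bool = True, step: float = 0.001):
    """Distance matrix from the brute-force rotation grid."""
    normed = []
    for c in configs:
        p = np.asarray(c, dtype=float)
        p = p - p.mean(axis=0)
        normed.append(p / np.sqrt((p**2).sum()))
    n = len(normed)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = grid_rotation_residual(
                normed[i], normed[j], allow_reflection, step
            )
    return D


# ---------------------------------------------------------------------------
# elliptic Fourier quadrature
# ---------------------------------------------------------------------------


def efd_quadrature(points: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Kuhl-Giardina coefficients of a closed polyline by generic numerical
    quadrature of the defining integrals, segment by segment."""
    pts = np.asarray(points, dtype=float)
    deltas = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    seg_len = np.hypot(deltas[:, 0], deltas[:, 1])
    t_knots = np.concatenate([[0.0], np.cumsum(seg_len)])
    T = t_knots[-1]

    def coord(t: float, axis: int) -> float:
        i = min(np.searchsorted(t_knots, t, side="right") - 1, len(seg_len) - 1)
        frac = (t - t_knots[i]) / seg_len[i]
        return pts[i, axis] + frac * deltas[i, axis]

    out = np.zeros((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        w = 2 * np.pi * n / T
        for col, (axis, trig) in enumerate(
            [(0, np.cos), (0, np.sin), (1, np.cos), (1, np.sin)]
        ):
            total = 0.0
            for i in range(len(seg_len)):
                val, _ = quad(
                    lambda t: coord(t, axis) * trig(w * t),
                    t_knots[i],
                    t_knots[i + 1],
                    epsabs=1e-13,
                    limit=200,
                )
                total += val
            out[n - 1, col] = 2.0 / T * total
    return out


def ellipse_arc_length_d1(a: float = 2.0, b: float = 1.0, n: int = 400_000) -> float:
    """Analytic (to quadrature accuracy) normalized d1 of an ellipse under
    arc-length parameterization — the parameterization chain-code EFDs use."""
    u = np.linspace(0, 2 * np.pi, n + 1)
    x, y = a * np.cos(u), b * np.sin(u)
    s = np.concatenate([[0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    L = s[-1]
    su = np.linspace(0, L, n, endpoint=False)
    xu, yu = np.interp(su, s, x), np.interp(su, s, y)
    ang = 2 * np.pi * su / L
    a1 = np.hypot(2 * np.mean(xu * np.cos(ang)), 2 * np.mean(xu * np.sin(ang)))
    d1 = np.hypot(2 * np.mean(yu * np.cos(ang)), 2 * np.mean(yu * np.sin(ang)))
    return float(d1 / a1)


# ---------------------------------------------------------------------------
# geometry and clustering
# ---------------------------------------------------------------------------


def mc_polygon_area(points: np.ndarray, n: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo point-in-polygon area estimate."""
    pts = np.asarray(points, dtype=float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n, 2))
    inside = MplPath(pts).contains_points(samples)
    box = np.prod(hi - lo)
    return float(box * inside.mean())


def brute_force_merge_heights(X: np.ndarray, method: str = "complete") -> list[float]:
    """Naive agglomerative clustering; returns the sequence of merge heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []

    def dist(ci, cj):
        ds = [np.linalg.norm(X[a] - X[b]) for a in ci for b in cj]
        return max(ds) if method == "complete" else min(ds)

    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights
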