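"""Elliptical Fourier analysis of closed leaf outlines.

The pipeline mirrors the classic chain-code route: a binary mask is traced to
an 8-connected Freeman chain code, the chain (or any closed polyline) is
treated as a piecewise-linear parameterisation of the contour, and the
Kuhl-Giardina elliptic Fourier coefficients are computed in closed form per
harmonic.  First-harmonic normalization removes size, rotation and starting
point so that coefficients are comparable across leaves; the truncated series
can be inverted to reconstruct (and average) outlines.

Coordinates are mathematical: x right, y up, counter-clockwise contours have
positive signed area.  Masks are numpy arrays indexed (row, col); rows are
flipped into y-up space during tracing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .data_model import EFDCoefficients, Outline, signed_area
from .errors import DegenerateShapeError, ValidationError

# Freeman codes in y-up coordinates: 0 = +x, then counter-clockwise by 45 deg.
_CODE_STEPS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
)


@dataclass(frozen=True)
class ChainCode:
    """8-connected boundary chain: a start pixel and a sequence of moves."""

    start: tuple[int, int]  # (x, y), y up
    codes: np.ndarray  # integers 0..7
    closed: bool = True

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        if codes.size < 8:
            raise DegenerateShapeError(
                f"chain must have >= 8 moves, got {codes.size}"
            )
        if codes.min() < 0 or codes.max() > 7:
            raise ValidationError("chain codes must be in 0..7")
        if self.closed:
            net = _CODE_STEPS[codes].sum(axis=0)
            if net[0] != 0 or net[1] != 0:
                raise ValidationError(
                    f"closed chain must return to start; net displacement {tuple(net)}"
                )
        object.__setattr__(self, "codes", codes)

    def points(self) -> np.ndarray:
        """Vertices of the chain polyline, starting at ``start`` (closed:
        final vertex equals the start and is omitted)."""
        steps = _CODE_STEPS[self.codes]
        pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)]) + np.asarray(self.start)
        return pts[:-1] if self.closed else pts


# ---------------------------------------------------------------------------
# boundary tracing
# ---------------------------------------------------------------------------

# Moore neighborhood in (row, col), clockwise starting west.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_contour(mask: np.ndarray) -> ChainCode:
    """Trace the boundary of a single-object binary mask to a chain code.

    The trace starts at the left-most pixel of the top-most foreground row and
    runs counter-clockwise (in y-up coordinates).  Raises for empty masks,
    multiple 8-connected components, and degenerate (too small) objects.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if not m.any():
        raise ValidationError("mask is empty")
    n_comp = int(measure.label(m, connectivity=2).max())
    if n_comp != 1:
        raise ValidationError(f"mask has {n_comp} components; expected exactly 1")

    rows, cols = np.nonzero(m)
    i0 = np.lexsort((cols, rows))[0]
    start = (int(rows[i0]), int(cols[i0]))

    padded = np.zeros((m.shape[0] + 2, m.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = m
    s = (start[0] + 1, start[1] + 1)

    def moore_next(p, b):
        """First foreground neighbor of p, clockwise from backtrack b."""
        k0 = _MOORE.index((b[0] - p[0], b[1] - p[1]))
        prev = b
        for j in range(1, 9):
            off = _MOORE[(k0 + j) % 8]
            q = (p[0] + off[0], p[1] + off[1])
            if padded[q]:
                return q, prev
            prev = q
        return None, None

    boundary = [s]
    b0 = (s[0], s[1] - 1)  # pixel scanned just before the start: background
    p, b = s, b0
    first_move = None
    while True:
        q, newb = moore_next(p, b)
        if q is None:  # isolated pixel
            break
        if first_move is None:
            first_move = q
        elif p == s and q == first_move:
            boundary.pop()  # s was appended again before detecting the stop
            break
        boundary.append(q)
        p, b = q, newb
        if len(boundary) > 4 * padded.size:  # defensive; cannot loop forever
            raise RuntimeError("boundary trace failed to terminate")

    if len(boundary) < 8:
        raise DegenerateShapeError(
            f"object boundary has only {len(boundary)} pixels; too small to trace"
        )

    h = m.shape[0]
    xy = np.array([(c - 1, h - 1 - (r - 1)) for r, c in boundary])  # y-up
    if signed_area(xy) < 0:
        xy = np.vstack([xy[:1], xy[1:][::-1]])  # reverse, keep the start pixel
    deltas = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    lookup = {tuple(step): code for code, step in enumerate(_CODE_STEPS)}
    codes = np.array([lookup[tuple(d)] for d in deltas])
    return ChainCode(start=(int(xy[0, 0]), int(xy[0, 1])), codes=codes, closed=True)


# ---------------------------------------------------------------------------
# Kuhl-Giardina coefficients
# ---------------------------------------------------------------------------


def _efd_from_deltas(deltas: np.ndarray, start: np.ndarray, n_harmonics: int) -> EFDCoefficients:
    """Closed-form elliptic Fourier coefficients of a piecewise-linear closed
    contour given by segment displacement vectors.

    For each harmonic n the four coefficients are the exact integrals of the
    contour's x(t), y(t) against cos and sin of the arc-length parameter,
    evaluated segment by segment (the integrand is linear within a segment).
    """
    dxy = np.asarray(deltas, dtype=float)
    dt = np.sqrt((dxy**2).sum(axis=1))
    if np.any(dt == 0):
        raise ValidationError("contour has zero-length segments")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T  # (H, K+1)
    d_cos = np.diff(np.cos(phi), axis=1)
    d_sin = np.diff(np.sin(phi), axis=1)
    slope = dxy / dt[:, None]  # (K, 2)
    coef = T / (2.0 * np.pi**2 * n**2)  # (H, 1)
    a = coef[:, 0] * (d_cos * slope[None, :, 0]).sum(axis=1)
    b = coef[:, 0] * (d_sin * slope[None, :, 0]).sum(axis=1)
    c = coef[:, 0] * (d_cos * slope[None, :, 1]).sum(axis=1)
    d = coef[:, 0] * (d_sin * slope[None, :, 1]).sum(axis=1)

    # DC terms (position of the contour centroid relative to the start point)
    cum = np.vstack([[0.0, 0.0], np.cumsum(dxy, axis=0)])[:-1]  # offsets at t_{p-1}
    xi = cum - slope * t[:-1, None]
    dt2 = t[1:] ** 2 - t[:-1] ** 2
    dc = (slope * dt2[:, None] / 2.0 + xi * dt[:, None]).sum(axis=0) / T
    origin = (float(dc[0] + start[0]), float(dc[1] + start[1]))

    return EFDCoefficients(
        np.column_stack([a, b, c, d]), normalized=False, origin=origin
    )


def chain_to_efd(chain: ChainCode, n_harmonics: int = 20) -> EFDCoefficients:
    """Raw elliptic Fourier coefficients of a closed chain code.

    Even codes step one pixel, odd codes sqrt(2), exactly the piecewise-linear
    parameterisation of the chain polyline.
    """
    if not chain.closed:
        raise ValidationError("chain must be closed for Fourier analysis")
    if n_harmonics < 1:
        raise ValidationError("need at least one harmonic")
    deltas = _CODE_STEPS[chain.codes].astype(float)
    return _efd_from_deltas(deltas, np.asarray(chain.start, dtype=float), n_harmonics)


def outline_to_efd(outline: Outline, n_harmonics: int = 20) -> EFDCoefficients:
    """Raw elliptic Fourier coefficients of a closed polyline outline."""
    if n_harmonics < 1:
        raise ValidationError("need at least one harmonic")
    pts = outline.points
    deltas = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return _efd_from_deltas(deltas, pts[0], n_harmonics)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _shift_start(arr: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point of the parameterisation by theta (harmonic n
    rotates by n*theta in parameter space)."""
    out = np.empty_like(arr)
    n = np.arange(1, arr.shape[0] + 1)
    cos_nt, sin_nt = np.cos(n * theta), np.sin(n * theta)
    out[:, 0] = arr[:, 0] * cos_nt + arr[:, 1] * sin_nt
    out[:, 1] = -arr[:, 0] * sin_nt + arr[:, 1] * cos_nt
    out[:, 2] = arr[:, 2] * cos_nt + arr[:, 3] * sin_nt
    out[:, 3] = -arr[:, 2] * sin_nt + arr[:, 3] * cos_nt
    return out


def _rotate_scale(arr: np.ndarray, psi: float, scale: float) -> np.ndarray:
    """Rotate the contour by -psi in the plane and divide by ``scale``."""
    cos_p, sin_p = np.cos(psi), np.sin(psi)
    out = np.empty_like(arr)
    out[:, 0] = (cos_p * arr[:, 0] + sin_p * arr[:, 2]) / scale
    out[:, 1] = (cos_p * arr[:, 1] + sin_p * arr[:, 3]) / scale
    out[:, 2] = (-sin_p * arr[:, 0] + cos_p * arr[:, 2]) / scale
    out[:, 3] = (-sin_p * arr[:, 1] + cos_p * arr[:, 3]) / scale
    return out


def _normalize_candidate(arr: np.ndarray, theta: float) -> np.ndarray:
    shifted = _shift_start(arr, theta)
    a1, _, c1, _ = shifted[0]
    scale = float(np.hypot(a1, c1))
    psi = float(np.arctan2(c1, a1))
    return _rotate_scale(shifted, psi, scale)


def normalize_efd(coeffs: EFDCoefficients) -> EFDCoefficients:
    """First-harmonic normalization of raw coefficients.

    The first-harmonic ellipse fixes the frame: the starting point moves to
    the tip of its semi-major axis, the contour is rotated so that axis lies
    along +x, and all coefficients are divided by the semi-major axis length.
    Afterwards a1 = 1 and b1 = c1 = 0; size, rotation and starting point of
    the source contour no longer matter.

    The semi-major axis has two tips, so the normalized form is ambiguous up
    to a half-period shift; the tie is broken deterministically by choosing
    the orientation whose reconstructed point at parameter 0 has the larger
    x-coordinate.  Idempotent on already-normalized input.
    """
    if coeffs.normalized:
        return coeffs
    arr = coeffs.harmonics
    a1, b1, c1, d1 = arr[0]
    if a1 * d1 - b1 * c1 == 0 and np.hypot(a1, c1) < 1e-12:
        raise DegenerateShapeError("degenerate first harmonic; cannot normalize")
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )
    # theta lands on a semi-axis of the first-harmonic ellipse; pick the major
    e_theta = np.hypot(*_shift_start(arr[:1], theta)[0, [0, 2]])
    e_perp = np.hypot(*_shift_start(arr[:1], theta + np.pi / 2)[0, [0, 2]])
    if e_perp > e_theta:
        theta += np.pi / 2
    if np.hypot(*_shift_start(arr[:1], theta)[0, [0, 2]]) < 1e-12:
        raise DegenerateShapeError("degenerate first harmonic; cannot normalize")

    cand_a = _normalize_candidate(arr, theta)
    cand_b = _normalize_candidate(arr, theta + np.pi)
    chosen = cand_a if cand_a[:, 0].sum() >= cand_b[:, 0].sum() else cand_b
    chosen = chosen.copy()
    chosen[0, :3] = (1.0, 0.0, 0.0)  # exact by construction; clamp rounding
    return EFDCoefficients(chosen, normalized=True, origin=(0.0, 0.0))


# ---------------------------------------------------------------------------
# reconstruction, averaging, harmonic contributions
# ---------------------------------------------------------------------------


def reconstruct(coeffs: EFDCoefficients, n_points: int = 200) -> Outline:
    """Evaluate the truncated Fourier series at equally spaced parameters."""
    if n_points < 16:
        raise ValidationError("reconstruction needs n_points >= 16")
    s = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    ang = 2.0 * np.pi * n * s[None, :]
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    arr = coeffs.harmonics
    x = coeffs.origin[0] + arr[:, 0] @ cos_a + arr[:, 1] @ sin_a
    y = coeffs.origin[1] + arr[:, 2] @ cos_a + arr[:, 3] @ sin_a
    pts = np.column_stack([x, y])
    if signed_area(pts) < 0:
        pts = np.vstack([pts[:1], pts[1:][::-1]])
    return Outline(pts)


def mean_efd(subset: Sequence[EFDCoefficients]) -> EFDCoefficients:
    """Coefficient-wise arithmetic mean of normalized coefficient sets."""
    subset = list(subset)
    if not subset:
        raise ValidationError("cannot average an empty set of coefficients")
    hs = {c.n_harmonics for c in subset}
    if len(hs) != 1:
        raise ValidationError(f"mixed harmonic counts {sorted(hs)}")
    if not all(c.normalized for c in subset):
        raise ValidationError("mean_efd expects normalized coefficients")
    mean = np.mean([c.harmonics for c in subset], axis=0)
    mean[0, :3] = (1.0, 0.0, 0.0)
    return EFDCoefficients(mean, normalized=True)


@dataclass(frozen=True)
class HarmonicGrid:
    """Reconstructed outlines with one harmonic amplified by varying factors;
    rows are harmonic ranks, columns amplification factors."""

    ranks: tuple[int, ...]
    factors: tuple[float, ...]
    shapes: tuple[tuple[Outline, ...], ...]  # shapes[i][j]: rank i, factor j


def harmonic_contribution(
    base: EFDCoefficients,
    ranks: Sequence[int],
    factors: Sequence[float],
    n_points: int = 200,
) -> HarmonicGrid:
    """Visualisation grid of how each harmonic rank shapes the contour.

    Cell (rank, factor) reconstructs the outline with that rank's quadruple
    multiplied by the factor, all other harmonics untouched.  Factor 1
    reproduces the base reconstruction; factor 0 removes the harmonic.
    """
    for r in ranks:
        if r < 1 or r > base.n_harmonics:
            raise ValidationError(
                f"rank {r} outside 1..{base.n_harmonics}"
            )
    rows = []
    for r in ranks:
        row = []
        for f in factors:
            arr = base.harmonics.copy()
            arr[r - 1] *= f
            modified = EFDCoefficients(arr, normalized=False, origin=base.origin)
            row.append(reconstruct(modified, n_points))
        rows.append(tuple(row))
    return HarmonicGrid(tuple(int(r) for r in ranks), tuple(float(f) for f in factors), tuple(rows))
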