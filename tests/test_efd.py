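"""Chain-code tracing, Kuhl-Giardina coefficients, normalization, inversion."""

import numpy as np
import pytest
from skimage import draw as skdraw

from leafmorph.data_model import EFDCoefficients, Outline
from leafmorph.efd import (
    ChainCode,
    chain_to_efd,
    harmonic_contribution,
    mean_efd,
    normalize_efd,
    outline_to_efd,
    reconstruct,
    trace_contour,
)
from leafmorph.errors import DegenerateShapeError, ValidationError
from leafmorph.synthetic import BOUNDARY_ORDER, SimParams, generate_dataset, landmarks_to_outline, rasterize

from .oracles import efd_quadrature, ellipse_arc_length_d1


def _disk_mask(radius=50, pad=10):
    size = 2 * (radius + pad)
    m = np.zeros((size, size), bool)
    rr, cc = skdraw.disk((size // 2, size // 2), radius)
    m[rr, cc] = True
    return m


def _square_mask(side=10, pad=2):
    m = np.zeros((side + 2 * pad, side + 2 * pad), bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def _mean_dist_to_polyline(samples: np.ndarray, poly: np.ndarray) -> float:
    """Mean distance from sample points to a closed polyline (segment-wise)."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a  # (m, 2)
    denom = (ab**2).sum(axis=1)
    ap = samples[:, None, :] - a[None, :, :]  # (n, m, 2)
    t = np.clip((ap * ab[None]).sum(-1) / denom[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.sqrt(((samples[:, None, :] - proj) ** 2).sum(-1)).min(axis=1)
    return float(d.mean())


class TestTraceContour:
    def test_square_chain_uses_only_axis_moves(self):
        chain = trace_contour(_square_mask())
        assert len(chain.codes) == 36
        assert set(chain.codes.tolist()) <= {0, 2, 4, 6}

    def test_closure_on_assorted_masks(self):
        from leafmorph.efd import _CODE_STEPS

        for mask in (_square_mask(), _disk_mask(20)):
            chain = trace_contour(mask)
            net = _CODE_STEPS[chain.codes].sum(axis=0)
            assert tuple(net) == (0, 0)

    def test_start_is_leftmost_of_topmost_row(self):
        mask = _square_mask(side=10, pad=2)
        chain = trace_contour(mask)
        # top-most foreground row is image row 2, left-most col 2;
        # in y-up coordinates that pixel is (2, H - 1 - 2)
        assert chain.start == (2, mask.shape[0] - 3)

    def test_empty_and_multi_component_masks_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            trace_contour(np.zeros((5, 5), bool))
        m = np.zeros((10, 10), bool)
        m[1:4, 1:4] = True
        m[6:9, 6:9] = True
        with pytest.raises(ValidationError, match="2 components"):
            trace_contour(m)

    def test_single_pixel_rejected(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with pytest.raises(DegenerateShapeError):
            trace_contour(m)


class TestChainToEFD:
    def test_digitized_circle_is_degenerate_ellipse(self):
        coeffs = normalize_efd(chain_to_efd(trace_contour(_disk_mask(50)), 5))
        np.testing.assert_allclose(
            coeffs.harmonics[0], [1.0, 0.0, 0.0, 1.0], atol=0.02
        )
        assert np.abs(coeffs.harmonics[1:]).max() < 0.02

    def test_digitized_ellipse_axis_ratio_matches_arc_length_oracle(self):
        m = np.zeros((140, 240), bool)
        rr, cc = skdraw.ellipse(70, 120, 50, 100)
        m[rr, cc] = True
        coeffs = normalize_efd(chain_to_efd(trace_contour(m), 5))
        # oracle: analytic first-harmonic axis ratio of a 2:1 ellipse under
        # the arc-length parameterization the chain code realises (~0.5869)
        assert coeffs.harmonics[0, 3] == pytest.approx(
            ellipse_arc_length_d1(2.0, 1.0), abs=0.02
        )

    def test_square_matches_quadrature_oracle(self):
        chain = trace_contour(_square_mask())
        ours = chain_to_efd(chain, 6)
        poly = chain.points().astype(float)
        oracle = efd_quadrature(poly, 6)
        np.testing.assert_allclose(ours.harmonics, oracle, atol=1e-6)

    def test_open_chain_rejected(self):
        with pytest.raises(ValidationError):
            chain = ChainCode(start=(0, 0), codes=[0] * 8, closed=False)
            chain_to_efd(chain)

    def test_energy_invariant_under_start_shift(self):
        chain = trace_contour(_disk_mask(30))
        raw1 = chain_to_efd(chain, 15)
        shift = 17
        pts = chain.points()
        start2 = pts[shift]
        rolled = ChainCode(
            start=(int(start2[0]), int(start2[1])),
            codes=np.roll(chain.codes, -shift),
        )
        raw2 = chain_to_efd(rolled, 15)
        assert (raw1.harmonics**2).sum() == pytest.approx(
            (raw2.harmonics**2).sum(), abs=1e-9
        )


class TestNormalization:
    def test_idempotent(self, leaf_outline):
        once = normalize_efd(outline_to_efd(leaf_outline, 10))
        assert normalize_efd(once) is once
        assert once.normalized
        np.testing.assert_allclose(once.harmonics[0, :3], [1, 0, 0], atol=1e-9)

    def test_invariant_to_rotation_scale_and_start(self, leaf_outline):
        base = normalize_efd(outline_to_efd(leaf_outline, 12))
        ang = 0.6458
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = np.roll(leaf_outline.points @ R.T * 3.0, 17, axis=0)
        alt = normalize_efd(outline_to_efd(Outline(moved), 12))
        np.testing.assert_allclose(alt.harmonics, base.harmonics, atol=1e-6)

    def test_degenerate_first_harmonic_rejected(self):
        arr = np.zeros((3, 4))
        arr[1] = [0.5, 0, 0, 0.5]  # energy only in harmonic 2
        with pytest.raises(DegenerateShapeError):
            normalize_efd(EFDCoefficients(arr))


class TestReconstruct:
    def test_unit_circle_from_first_harmonic(self):
        circle = reconstruct(EFDCoefficients(np.array([[1.0, 0.0, 0.0, 1.0]])), 64)
        np.testing.assert_allclose(np.hypot(*circle.points.T), 1.0, atol=1e-9)

    def test_error_non_increasing_in_harmonics(self):
        chain = trace_contour(_square_mask())
        poly = chain.points().astype(float)
        errs = []
        for h in (2, 4, 8, 16, 32):
            rec = reconstruct(chain_to_efd(chain, h), 512).points
            errs.append(_mean_dist_to_polyline(rec, poly))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] < errs[0]

    def test_leaf_fixture_close_at_h20(self, leaf_outline):
        rec = reconstruct(outline_to_efd(leaf_outline, 20), 512).points
        # < 1 pixel at a 200 px/unit raster scale = 0.005 units
        assert _mean_dist_to_polyline(rec, leaf_outline.points) < 0.005

    def test_too_few_points_rejected(self, leaf_outline):
        with pytest.raises(ValidationError):
            reconstruct(outline_to_efd(leaf_outline, 5), 8)


class TestMeanAndContribution:
    def test_mean_of_identical_sets(self, leaf_outline):
        c = normalize_efd(outline_to_efd(leaf_outline, 8))
        m = mean_efd([c, c, c])
        np.testing.assert_allclose(m.harmonics, c.harmonics, atol=1e-12)

    def test_mean_of_symmetric_offsets_is_center(self, leaf_outline):
        c = normalize_efd(outline_to_efd(leaf_outline, 8))
        delta = np.zeros_like(c.harmonics)
        delta[2:, :] = 0.01
        up = EFDCoefficients(c.harmonics + delta, normalized=True)
        down = EFDCoefficients(c.harmonics - delta, normalized=True)
        np.testing.assert_allclose(
            mean_efd([up, down]).harmonics, c.harmonics, atol=1e-12
        )

    def test_mixed_harmonic_counts_rejected(self, leaf_outline):
        a = normalize_efd(outline_to_efd(leaf_outline, 8))
        b = normalize_efd(outline_to_efd(leaf_outline, 9))
        with pytest.raises(ValidationError):
            mean_efd([a, b])

    def test_grid_shape_and_identity_factor(self, leaf_outline):
        base = outline_to_efd(leaf_outline, 8)
        grid = harmonic_contribution(base, ranks=[1, 2, 3], factors=[0, 0.5, 1, 2])
        assert len(grid.shapes) == 3 and all(len(r) == 4 for r in grid.shapes)
        identity_cell = grid.shapes[1][2]  # rank 2, factor 1
        np.testing.assert_allclose(
            identity_cell.points, reconstruct(base, 200).points, atol=1e-12
        )
        # factor 0 removes the harmonic
        removed = base.harmonics.copy()
        removed[1] = 0
        np.testing.assert_allclose(
            grid.shapes[1][0].points,
            reconstruct(EFDCoefficients(removed, origin=base.origin), 200).points,
            atol=1e-12,
        )

    def test_out_of_range_rank_rejected(self, leaf_outline):
        base = outline_to_efd(leaf_outline, 8)
        with pytest.raises(ValidationError):
            harmonic_contribution(base, ranks=[0], factors=[1.0])
        with pytest.raises(ValidationError):
            harmonic_contribution(base, ranks=[9], factors=[1.0])


def test_full_chain_reproduces_synthetic_outline():
    """landmarks -> spline outline -> mask -> chain -> EFD(H=40) -> contour
    stays within one pixel of the rasterized outline."""
    coll, _ = generate_dataset(
        SimParams(seed=4, n_species=2, vines_per_species=1, nodes_per_vine=2,
                  shape_noise_sd=0.0)
    )
    rec = coll.records[-1]  # an adult, lobed leaf
    outline = landmarks_to_outline(rec.landmarks, n_points=300, boundary=BOUNDARY_ORDER)
    mask = rasterize(outline, resolution=200.0)
    chain = trace_contour(mask)
    recon = reconstruct(chain_to_efd(chain, 40), 1024).points
    assert _mean_dist_to_polyline(recon, chain.points().astype(float)) < 1.0
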