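"""Superimposition, generalized Procrustes analysis, and distances."""

import numpy as np
import pytest

from leafmorph.data_model import LandmarkConfig, LeafCollection, LeafRecord
from leafmorph.errors import DegenerateShapeError, ValidationError
from leafmorph.procrustes import (
    center_and_scale,
    gpa,
    node_mean_shapes,
    optimal_superimposition,
    procrustes_distance,
)

from .oracles import grid_rotation_residual

pytestmark = []


def _rot(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def _pad15(pts):
    """Tile a small configuration up to 15 landmarks with distinct offsets."""
    reps = int(np.ceil(15 / len(pts)))
    tiled = np.vstack([pts + 0.01 * k for k in range(reps)])[:15]
    return tiled


class TestCenterAndScale:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        cfg = LandmarkConfig(_pad15(square))
        normed, size = center_and_scale(cfg)
        assert np.abs(normed.points.mean(axis=0)).max() < 1e-9
        assert normed.centroid_size() == pytest.approx(1.0, abs=1e-9)
        # hand value: centroid size of the padded square computed from the
        # definition, root of summed squared centroid distances
        centered = cfg.points - cfg.points.mean(axis=0)
        assert size == pytest.approx(np.sqrt((centered**2).sum()), abs=1e-12)
        # pure 4-corner square: every corner is sqrt(0.5) from the centroid,
        # so the centroid size is sqrt(4 * 0.5) = sqrt(2)
        sq_centered = square - square.mean(axis=0)
        assert np.sqrt((sq_centered**2).sum()) == pytest.approx(np.sqrt(2.0))

    def test_idempotent(self, random_config):
        once, _ = center_and_scale(random_config)
        twice, size = center_and_scale(once)
        assert size == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateShapeError):
            center_and_scale(LandmarkConfig(np.ones((15, 2))))


class TestOptimalSuperimposition:
    def test_pure_rotation_recovered(self, random_config):
        A, _ = center_and_scale(random_config)
        R90 = _rot(np.pi / 2)
        B = LandmarkConfig(A.points @ R90.T)
        R, resid = optimal_superimposition(A, B)
        assert resid < 1e-9
        np.testing.assert_allclose(R @ R90, np.eye(2), atol=1e-9)

    def test_reflection_flag(self, random_config):
        A, _ = center_and_scale(random_config)
        mirrored = LandmarkConfig(A.points * [-1, 1])
        _, resid_ref = optimal_superimposition(A, mirrored, allow_reflection=True)
        _, resid_rot = optimal_superimposition(A, mirrored, allow_reflection=False)
        assert resid_ref < 1e-9
        assert resid_rot > 1e-3

    @pytest.mark.parametrize("allow_reflection", [True, False])
    def test_matches_grid_search_oracle(self, rng, allow_reflection):
        A, _ = center_and_scale(LandmarkConfig(rng.normal(size=(15, 2))))
        B, _ = center_and_scale(LandmarkConfig(rng.normal(size=(15, 2))))
        _, resid = optimal_superimposition(A, B, allow_reflection=allow_reflection)
        oracle = grid_rotation_residual(
            A.points, B.points, allow_reflection=allow_reflection
        )
        # the grid is 0.001 rad coarse; the analytic optimum can only be better
        assert resid <= oracle + 1e-9
        assert oracle - resid < 1e-5


class TestGPA:
    def test_similarity_transformed_pair_aligns_exactly(self, random_config):
        base = random_config.points
        moved = 3.2 * base @ _rot(1.1).T + [5.0, -2.0]
        result = gpa([LandmarkConfig(base), LandmarkConfig(moved)])
        d = np.sqrt(
            ((result.aligned[0].points - result.aligned[1].points) ** 2).sum()
        )
        assert d < 1e-9

    def test_invariance_to_input_similarity_transforms(self, rng):
        configs = [LandmarkConfig(rng.normal(size=(15, 2))) for _ in range(6)]
        moved = [
            LandmarkConfig(
                rng.uniform(0.5, 2.0) * c.points @ _rot(rng.uniform(0, 7)).T
                + rng.normal(size=2)
            )
            for c in configs
        ]
        r1, r2 = gpa(configs), gpa(moved)

        def pairwise(result):
            n = len(result.aligned)
            return np.array(
                [
                    np.sqrt(((result.aligned[i].points - result.aligned[j].points) ** 2).sum())
                    for i in range(n)
                    for j in range(i + 1, n)
                ]
            )

        np.testing.assert_allclose(pairwise(r1), pairwise(r2), atol=1e-9)

    def test_gpa_result_invariants(self, rng):
        configs = [LandmarkConfig(rng.normal(size=(15, 2))) for _ in range(5)]
        result = gpa(configs)
        assert result.converged
        for a in result.aligned:
            assert np.abs(a.points.mean(axis=0)).max() < 1e-9
            assert a.centroid_size() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            result.mean_shape.points,
            np.mean([a.points for a in result.aligned], axis=0),
            atol=1e-12,
        )

    def test_mirrored_dataset_same_distances_with_reflection(self, rng):
        configs = [LandmarkConfig(rng.normal(size=(15, 2))) for _ in range(5)]
        mirrored = [LandmarkConfig(c.points * [-1, 1]) for c in configs]
        d1 = [
            procrustes_distance(a, b)
            for i, a in enumerate(configs)
            for b in configs[i + 1 :]
        ]
        d2 = [
            procrustes_distance(a, b)
            for i, a in enumerate(mirrored)
            for b in mirrored[i + 1 :]
        ]
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_needs_two_configs(self, random_config):
        with pytest.raises(ValidationError):
            gpa([random_config])


class TestProcrustesDistance:
    def test_metric_basics(self, random_config, rng):
        other = LandmarkConfig(rng.normal(size=(15, 2)))
        assert procrustes_distance(random_config, random_config) == pytest.approx(0, abs=1e-9)
        scaled = LandmarkConfig(2.0 * random_config.points)
        assert procrustes_distance(random_config, scaled) == pytest.approx(0, abs=1e-9)
        assert procrustes_distance(random_config, other) == pytest.approx(
            procrustes_distance(other, random_config), abs=1e-12
        )

    def test_square_vs_rectangle_matches_grid_oracle(self):
        square = _pad15(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
        rect = _pad15(np.array([[0, 0], [2, 0], [2, 1], [0, 1]], dtype=float))
        d = procrustes_distance(LandmarkConfig(square), LandmarkConfig(rect))
        a, _ = center_and_scale(LandmarkConfig(square))
        b, _ = center_and_scale(LandmarkConfig(rect))
        oracle = grid_rotation_residual(a.points, b.points, allow_reflection=True)
        assert abs(d - oracle) < 1e-5


class TestNodeMeans:
    def _coll(self, shapes_by_node):
        records = []
        for node, shapes in shapes_by_node.items():
            for i, s in enumerate(shapes):
                records.append(
                    LeafRecord(
                        species="sp",
                        vine_id=f"v{i}",
                        node=node,
                        landmarks=LandmarkConfig(s),
                    )
                )
        return LeafCollection(records=tuple(records))

    def test_single_leaf_node_mean_is_that_leaf(self, rng):
        s = rng.normal(size=(15, 2))
        means = node_mean_shapes(self._coll({1: [s]}))
        np.testing.assert_array_equal(means[1].points, s)

    def test_symmetric_pair_mean_is_midpoint(self, rng):
        mid = rng.normal(size=(15, 2))
        delta = rng.normal(size=(15, 2))
        means = node_mean_shapes(self._coll({2: [mid + delta, mid - delta]}))
        np.testing.assert_allclose(means[2].points, mid, atol=1e-12)

    def test_empty_nodes_absent(self, rng):
        means = node_mean_shapes(
            self._coll({1: [rng.normal(size=(15, 2))], 3: [rng.normal(size=(15, 2))]})
        )
        assert sorted(means) == [1, 3]
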