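"""Containers, table/NEF I/O round trips, and node renumbering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafmorph.data_model import (
    BASE_FIRST,
    TIP_FIRST,
    EFDCoefficients,
    LandmarkConfig,
    LeafCollection,
    LeafRecord,
    Outline,
    TableDialect,
    collection_from_json,
    collection_to_json,
    read_landmark_table,
    read_nef,
    renumber_nodes,
    write_landmark_table,
    write_nef,
)
from leafmorph.errors import DegenerateShapeError, FormatError, ValidationError


def _collection(rng, n_vines=2, nodes=(1, 2, 3), numbering=BASE_FIRST):
    records = []
    for v in range(n_vines):
        for node in nodes:
            records.append(
                LeafRecord(
                    species="sp01" if v == 0 else "sp02",
                    vine_id=f"v{v}",
                    node=node,
                    class_label="A",
                    landmarks=LandmarkConfig(rng.normal(size=(15, 2))),
                )
            )
    return LeafCollection(records=tuple(records), numbering=numbering)


class TestContainers:
    def test_landmark_config_rejects_wrong_shape_and_nonfinite(self):
        with pytest.raises(ValidationError):
            LandmarkConfig(np.zeros((14, 2)))
        bad = np.zeros((15, 2))
        bad[3, 1] = np.nan
        with pytest.raises(ValidationError):
            LandmarkConfig(bad)

    def test_outline_requires_ccw_and_enough_points(self):
        th = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        circle = np.column_stack([np.cos(th), np.sin(th)])
        Outline(circle)  # fine
        with pytest.raises(ValidationError):
            Outline(circle[::-1])  # clockwise
        with pytest.raises(DegenerateShapeError):
            Outline(circle[:5])
        with pytest.raises(DegenerateShapeError):
            Outline(np.vstack([circle[:1], circle]))  # repeated vertex

    def test_normalized_efd_invariant_enforced(self):
        arr = np.array([[0.9, 0.0, 0.0, 0.5]])
        with pytest.raises(ValidationError):
            EFDCoefficients(arr, normalized=True)
        EFDCoefficients(arr, normalized=False)

    def test_record_needs_some_shape_and_valid_node(self, rng):
        with pytest.raises(ValidationError):
            LeafRecord(species="s", vine_id="v", node=1)
        with pytest.raises(ValidationError):
            LeafRecord(
                species="s",
                vine_id="v",
                node=0,
                landmarks=LandmarkConfig(rng.normal(size=(15, 2))),
            )

    def test_duplicate_vine_node_rejected(self, rng):
        rec = LeafRecord(
            species="s",
            vine_id="v",
            node=1,
            landmarks=LandmarkConfig(rng.normal(size=(15, 2))),
        )
        with pytest.raises(ValidationError):
            LeafCollection(records=(rec, rec))


class TestLandmarkTable:
    def test_round_trip_is_lossless(self, rng, tmp_path):
        coll = _collection(rng)
        path = tmp_path / "landmarks.csv"
        write_landmark_table(coll, path)
        back = read_landmark_table(path)
        assert len(back) == len(coll)
        for a, b in zip(coll.records, back.records):
            assert (a.species, a.vine_id, a.node) == (b.species, b.vine_id, b.node)
            np.testing.assert_allclose(
                a.landmarks.points, b.landmarks.points, rtol=0, atol=1e-12
            )

    def test_well_formed_three_row_table(self, tmp_path):
        header = "species,vine,node," + ",".join(
            f"x{i},y{i}" for i in range(1, 16)
        )
        rows = [
            f"sp01,v1,{k}," + ",".join(f"{j}.0,{j}.5" for j in range(15))
            for k in (1, 2, 3)
        ]
        path = tmp_path / "t.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        coll = read_landmark_table(path)
        assert len(coll) == 3
        assert all(r.landmarks.points.shape == (15, 2) for r in coll.records)

    def test_missing_coordinate_column_is_format_error(self, tmp_path):
        header = "species,vine,node," + ",".join(
            f"x{i},y{i}" for i in range(1, 15)
        ) + ",x15"  # y15 missing: 29 coordinates
        path = tmp_path / "t.csv"
        path.write_text(header + "\n" + "sp,v,1," + ",".join(["0"] * 29) + "\n")
        with pytest.raises(FormatError, match="y15"):
            read_landmark_table(path)

    def test_non_numeric_coordinate_names_row(self, tmp_path):
        header = "species,vine,node," + ",".join(
            f"x{i},y{i}" for i in range(1, 16)
        )
        good = "sp,v,1," + ",".join(["0"] * 30)
        bad = "sp,v,2," + ",".join(["0"] * 29 + ["oops"])
        path = tmp_path / "t.csv"
        path.write_text(header + "\n" + good + "\n" + bad + "\n")
        with pytest.raises(FormatError, match="row 1"):
            read_landmark_table(path)


class TestNef:
    def test_single_record_and_round_trip(self, rng, tmp_path):
        arr = rng.normal(size=(20, 4))
        arr[0, :3] = (1.0, 0.0, 0.0)
        coeffs = {"leaf_a": EFDCoefficients(arr, normalized=True)}
        path = tmp_path / "shapes.nef"
        write_nef(coeffs, path)
        back = read_nef(path)
        assert list(back) == ["leaf_a"]
        assert back["leaf_a"].n_harmonics == 20
        np.testing.assert_allclose(
            back["leaf_a"].harmonics, arr, rtol=0, atol=1e-12
        )

    def test_tolerates_windows_line_endings(self, tmp_path):
        content = "leaf\r\n2\r\n1 0 0 0.5\r\n0.1  0.2   0.3 0.4\r\n"
        path = tmp_path / "w.nef"
        path.write_bytes(content.encode())
        back = read_nef(path)
        assert back["leaf"].n_harmonics == 2

    def test_truncated_record_names_record(self, tmp_path):
        path = tmp_path / "bad.nef"
        path.write_text("leaf_x\n3\n1 0 0 0.5\n0 0 0 0\n")
        with pytest.raises(FormatError, match="leaf_x"):
            read_nef(path)

    def test_inconsistent_harmonic_count_rejected(self, tmp_path):
        path = tmp_path / "bad.nef"
        path.write_text(
            "a\n1\n1 0 0 0.5\nb\n2\n1 0 0 0.5\n0 0 0 0\n"
        )
        with pytest.raises(FormatError, match="differs"):
            read_nef(path)

    def test_non_numeric_token_rejected(self, tmp_path):
        path = tmp_path / "bad.nef"
        path.write_text("a\n1\n1 0 zero 0.5\n")
        with pytest.raises(FormatError):
            read_nef(path)


class TestRenumbering:
    def test_full_vine_reversal(self, rng):
        coll = _collection(rng, n_vines=1, nodes=tuple(range(1, 11)), numbering=TIP_FIRST)
        flipped = renumber_nodes(coll, BASE_FIRST)
        assert flipped.numbering == BASE_FIRST
        # tip-first node 1 (youngest, at tip) becomes base-first node 10
        mapping = {a.node: b.node for a, b in zip(coll.records, flipped.records)}
        assert mapping == {k: 11 - k for k in range(1, 11)}

    def test_gap_preserved(self, rng):
        coll = _collection(rng, n_vines=1, nodes=(1, 2, 4), numbering=TIP_FIRST)
        flipped = renumber_nodes(coll, BASE_FIRST)
        assert sorted(r.node for r in flipped.records) == [1, 3, 4]
        mapping = {a.node: b.node for a, b in zip(coll.records, flipped.records)}
        assert mapping == {1: 4, 2: 3, 4: 1}

    def test_identity_and_unknown_target(self, rng):
        coll = _collection(rng)
        assert renumber_nodes(coll, BASE_FIRST) is coll
        with pytest.raises(ValidationError):
            renumber_nodes(coll, "leaf_first")

    @settings(deadline=None, derandomize=True)
    @given(
        nodes=st.sets(st.integers(min_value=2, max_value=30), min_size=0, max_size=11).map(
            lambda s: s | {1}  # numbering starts at 1 in both conventions
        )
    )
    def test_renumbering_is_an_involution(self, nodes):
        pts = np.arange(30, dtype=float).reshape(15, 2)
        records = tuple(
            LeafRecord(
                species="s", vine_id="v", node=n, landmarks=LandmarkConfig(pts)
            )
            for n in sorted(nodes)
        )
        coll = LeafCollection(records=records, numbering=TIP_FIRST)
        twice = renumber_nodes(renumber_nodes(coll, BASE_FIRST), TIP_FIRST)
        assert [r.node for r in twice.records] == [r.node for r in coll.records]
        assert len(twice) == len(coll)


def test_json_round_trip(rng, tmp_path):
    coll = _collection(rng)
    path = tmp_path / "dataset.json"
    collection_to_json(coll, path)
    back = collection_from_json(path)
    assert back.numbering == coll.numbering
    for a, b in zip(coll.records, back.records):
        np.testing.assert_array_equal(a.landmarks.points, b.landmarks.points)
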