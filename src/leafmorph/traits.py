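"""Leaf trait matrices: aligned landmark coordinates plus EFD coefficients.

Downstream statistics (effect decomposition, per-node discrimination,
embedding) all consume one rectangular matrix with a row per leaf.  Columns
are the 30 Procrustes-aligned landmark coordinates (x1..x15, y1..y15) and the
4H normalized elliptical Fourier coefficients (a1..dH).  Column labels carry
the trait kind so heatmaps can group landmark-x, landmark-y and EFD traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import LeafCollection, N_LANDMARKS
from .efd import normalize_efd, outline_to_efd
from .errors import ValidationError
from .procrustes import align_collection


@dataclass(frozen=True)
class TraitMatrix:
    """Rows = leaves (collection order), columns = traits."""

    values: pd.DataFrame  # numeric trait columns
    meta: pd.DataFrame  # species, class, vine, node per row
    kinds: dict[str, str]  # column -> {"landmark-x", "landmark-y", "efd"}

    def __post_init__(self) -> None:
        if len(self.values) != len(self.meta):
            raise ValidationError("trait values and metadata row counts differ")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("trait matrix contains non-finite values")

    @property
    def n_leaves(self) -> int:
        return len(self.values)

    def columns(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.values.columns)
        return [c for c in self.values.columns if self.kinds[c] == kind]

    def constant_columns(self, tol: float = 1e-12) -> list[str]:
        v = self.values.to_numpy()
        return [c for c, s in zip(self.values.columns, v.std(axis=0)) if s < tol]

    def informative(self, tol: float = 1e-12) -> "TraitMatrix":
        """Drop near-constant columns (e.g. the normalization-fixed a1, b1,
        c1 coefficients) before model fitting or discrimination."""
        drop = set(self.constant_columns(tol))
        keep = [c for c in self.values.columns if c not in drop]
        return TraitMatrix(
            values=self.values[keep],
            meta=self.meta,
            kinds={c: self.kinds[c] for c in keep},
        )


def landmark_traits(collection: LeafCollection) -> TraitMatrix:
    """Aligned landmark coordinates only (30 columns)."""
    rows, meta = [], []
    for rec in collection.records:
        if rec.landmarks is None:
            raise ValidationError(
                f"record ({rec.vine_id}, node {rec.node}) lacks landmarks"
            )
        rows.append(rec.landmarks.points.reshape(-1))
        meta.append(
            {
                "species": rec.species,
                "class_label": rec.class_label,
                "vine": rec.vine_id,
                "node": rec.node,
            }
        )
    cols, kinds = [], {}
    for i in range(1, N_LANDMARKS + 1):
        cols += [f"x{i}", f"y{i}"]
        kinds[f"x{i}"] = "landmark-x"
        kinds[f"y{i}"] = "landmark-y"
    return TraitMatrix(
        values=pd.DataFrame(np.array(rows), columns=cols),
        meta=pd.DataFrame(meta),
        kinds=kinds,
    )


def build_trait_matrix(
    collection: LeafCollection,
    n_harmonics: int = 20,
    align: bool = True,
    allow_reflection: bool = True,
) -> TraitMatrix:
    """Combined landmark + EFD trait matrix for a full collection.

    Runs generalized Procrustes alignment over the landmark configurations
    (unless ``align`` is False, for data already in a common frame) and
    normalized elliptical Fourier analysis over each record's outline (or its
    stored coefficients when no outline is present).
    """
    if align:
        collection, _ = align_collection(collection, allow_reflection=allow_reflection)
    tm = landmark_traits(collection)

    efd_rows = []
    for rec in collection.records:
        if rec.outline is not None:
            coeffs = normalize_efd(outline_to_efd(rec.outline, n_harmonics))
        elif rec.efd is not None:
            if rec.efd.n_harmonics < n_harmonics:
                raise ValidationError(
                    f"record ({rec.vine_id}, node {rec.node}) has only "
                    f"{rec.efd.n_harmonics} harmonics; {n_harmonics} requested"
                )
            coeffs = rec.efd
        else:
            efd_rows.append(None)
            continue
        efd_rows.append(coeffs.harmonics[:n_harmonics].reshape(-1))

    if all(r is None for r in efd_rows):
        return tm
    if any(r is None for r in efd_rows):
        raise ValidationError("some records lack both outline and EFD coefficients")

    cols, kinds = [], {}
    for n in range(1, n_harmonics + 1):
        for letter in "abcd":
            name = f"{letter}{n}"
            cols.append(name)
            kinds[name] = "efd"
    efd_df = pd.DataFrame(np.array(efd_rows), columns=cols)
    return TraitMatrix(
        values=pd.concat([tm.values, efd_df], axis=1),
        meta=tm.meta,
        kinds={**tm.kinds, **kinds},
    )
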