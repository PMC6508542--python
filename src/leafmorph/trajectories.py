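"""Heteroblastic trajectories in a two-dimensional embedding of shape space.

All leaves are embedded in 2-D (t-SNE by default, matching the field's use of
perplexity 40; a deterministic PCA projection is available for fast exact
reproducibility).  Each vine then becomes a vector from its first sampled
node (base) to its last sampled node (tip).  If species share a juvenile
shape and diverge later, vector bases cluster while tips disperse; the
base/tip mean-pairwise-distance ratio quantifies that juvenile convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .data_model import LeafCollection
from .errors import ValidationError
from .traits import TraitMatrix


@dataclass(frozen=True)
class Embedding2D:
    coords: np.ndarray  # (n, 2)
    method: str
    perplexity: float  # effective value (0 for non-t-SNE methods)
    seed: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or not np.all(np.isfinite(arr)):
            raise ValidationError("embedding must be a finite (n, 2) array")
        object.__setattr__(self, "coords", arr)


@dataclass(frozen=True)
class VineVector:
    vine_id: str
    species: str
    class_label: str | None
    base: tuple[float, float]  # embedded coords of the lowest sampled node
    tip: tuple[float, float]  # embedded coords of the highest sampled node
    base_node: int
    tip_node: int

    def __post_init__(self) -> None:
        if self.base_node >= self.tip_node:
            raise ValidationError("base node must precede tip node")

    @property
    def length(self) -> float:
        return float(np.hypot(self.tip[0] - self.base[0], self.tip[1] - self.base[1]))


def embed_2d(
    traits: TraitMatrix,
    perplexity: float = 40.0,
    seed: int = 0,
    method: str = "tsne",
) -> Embedding2D:
    """2-D embedding of the trait matrix.

    t-SNE needs n >= 3 * perplexity + 1; smaller samples auto-reduce the
    perplexity with a warning.  Identical input and seed give identical
    coordinates.
    """
    X = traits.values.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValidationError("embedding needs at least 10 leaves")
    if method == "pca":
        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
        return Embedding2D(coords=coords, method="pca", perplexity=0.0, seed=seed)
    if method != "tsne":
        raise ValidationError(f"unknown embedding method {method!r}")
    eff = perplexity
    if n < 3 * perplexity + 1:
        eff = float(np.floor((n - 1) / 3))
        warnings.warn(
            f"perplexity {perplexity} too large for n={n}; reduced to {eff}",
            stacklevel=2,
        )
    tsne = TSNE(
        n_components=2,
        perplexity=eff,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(X)
    return Embedding2D(coords=np.asarray(coords, float), method="tsne", perplexity=eff, seed=seed)


def vine_vectors(embedding: Embedding2D, collection: LeafCollection) -> list[VineVector]:
    """One vector per vine: first sampled node -> last sampled node.

    'First/last sampled', not nominal first/last: vines may have gaps.  Vines
    with a single leaf are skipped with a warning.
    """
    if embedding.coords.shape[0] != len(collection.records):
        raise ValidationError("embedding rows must match collection records")
    by_vine: dict[str, list[tuple[int, int]]] = {}
    for i, rec in enumerate(collection.records):
        by_vine.setdefault(rec.vine_id, []).append((rec.node, i))
    vectors = []
    skipped = 0
    for vine, items in by_vine.items():
        if len(items) < 2:
            skipped += 1
            continue
        items.sort()
        (b_node, b_i), (t_node, t_i) = items[0], items[-1]
        rec = collection.records[b_i]
        vectors.append(
            VineVector(
                vine_id=vine,
                species=rec.species,
                class_label=rec.class_label,
                base=tuple(embedding.coords[b_i]),
                tip=tuple(embedding.coords[t_i]),
                base_node=int(b_node),
                tip_node=int(t_node),
            )
        )
    if skipped:
        warnings.warn(f"{skipped} single-leaf vines skipped", stacklevel=2)
    return vectors


def center_vectors(vectors: list[VineVector]) -> list[VineVector]:
    """Translate every vector's base to the origin (lengths preserved;
    idempotent)."""
    if not vectors:
        raise ValidationError("no vectors to center")
    return [
        replace(
            v,
            base=(0.0, 0.0),
            tip=(v.tip[0] - v.base[0], v.tip[1] - v.base[1]),
        )
        for v in vectors
    ]


def convergence_stat(vectors: list[VineVector]) -> tuple[float, float, float]:
    """Base and tip dispersions and their ratio.

    Dispersion is the mean pairwise Euclidean distance among vector bases
    (resp. tips); a ratio below 1 means vines start from a tighter region of
    shape space than they end in — the signature of a shared juvenile form.
    """
    if len(vectors) < 3:
        raise ValidationError("need >= 3 vectors for a dispersion ratio")
    bases = np.array([v.base for v in vectors])
    tips = np.array([v.tip for v in vectors])
    base_disp = float(pdist(bases).mean())
    tip_disp = float(pdist(tips).mean())
    ratio = base_disp / tip_disp if tip_disp > 0 else np.inf
    return base_disp, tip_disp, ratio
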