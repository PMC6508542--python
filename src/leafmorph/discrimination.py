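"""Per-node species discrimination and per-node trait variability.

For each heteroblastic node, every leaf is assigned to a species by a linear
discriminant analysis fitted on all *other* leaves of that node
(leave-one-out cross-validation): Gaussian classes with a pooled within-class
covariance, priors proportional to training counts.  The per-species
proportion correctly assigned, the node average and the full confusion matrix
quantify how distinctive leaves of each node are.

Trait variability is the sample standard deviation of each trait across all
leaves at a node, pooled over species: low SD at basal nodes is the signature
of a shared juvenile shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .errors import ValidationError
from .traits import TraitMatrix


@dataclass(frozen=True)
class NodeDiscrimination:
    node: int
    species: tuple[str, ...]  # classes that entered the LDA at this node
    confusion: pd.DataFrame  # true species x assigned species counts
    excluded: tuple[str, ...] = ()  # species with < 2 leaves at this node

    @property
    def proportions(self) -> pd.Series:
        """Per-species proportion of leaves correctly assigned."""
        diag = pd.Series(np.diag(self.confusion), index=self.confusion.index)
        return diag / self.confusion.sum(axis=1)

    @property
    def average(self) -> float:
        """Unweighted mean of the per-species proportions."""
        return float(self.proportions.mean())


class _PooledLDA:
    """Gaussian LDA with pooled within-class covariance and count priors.

    A singular pooled covariance is ridge-regularised with
    epsilon = 1e-8 * trace / p (warned once per node analysis).
    """

    def __init__(self):
        self.warned_singular = False

    def fit(self, X: np.ndarray, y: np.ndarray):
        classes, counts = np.unique(y, return_counts=True)
        n, p = X.shape
        means = np.stack([X[y == c].mean(axis=0) for c in classes])
        resid = X - means[np.searchsorted(classes, y)]
        cov = (resid.T @ resid) / max(n - len(classes), 1)
        try:
            chol = np.linalg.cholesky(cov)
            singular = False
        except np.linalg.LinAlgError:
            singular = True
        if singular:
            eps = 1e-8 * np.trace(cov) / p
            cov = cov + eps * np.eye(p)
            chol = np.linalg.cholesky(cov)
            if not self.warned_singular:
                warnings.warn(
                    "singular pooled covariance; ridge-regularised "
                    "(eps = 1e-8 * trace / p)",
                    stacklevel=2,
                )
                self.warned_singular = True
        self._classes = classes
        self._means = means
        self._chol = chol
        self._log_priors = np.log(counts / n)
        return self

    def predict(self, x: np.ndarray) -> str:
        # discriminant: -(1/2)(x - mu)' Sigma^-1 (x - mu) + log prior
        diff = x[None, :] - self._means
        w = solve_triangular(self._chol, diff.T, lower=True)
        mahal = (w**2).sum(axis=0)
        scores = -0.5 * mahal + self._log_priors
        return self._classes[int(np.argmax(scores))]


def loo_species_assignment(
    X: np.ndarray, y: np.ndarray, node: int = 0
) -> NodeDiscrimination:
    """Leave-one-out LDA species assignment for one node's leaves.

    Each leaf is classified by an LDA fitted on all other leaves of the node;
    species with fewer than 2 leaves are excluded (with a warning).  Features
    with negligible variance are dropped before fitting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    if not np.all(np.isfinite(X)):
        raise ValidationError("features must be finite")
    counts = pd.Series(y).value_counts()
    excluded = tuple(sorted(counts.index[counts < 2]))
    if excluded:
        warnings.warn(
            f"node {node}: species {excluded} have < 2 leaves; excluded",
            stacklevel=2,
        )
        keep = ~np.isin(y, excluded)
        X, y = X[keep], y[keep]
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValidationError(f"node {node}: fewer than 2 usable species")
    X = X[:, X.std(axis=0) > 1e-12]
    if X.shape[1] == 0:
        raise ValidationError(f"node {node}: all features are constant")

    lda = _PooledLDA()
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            continue
        lda.fit(X[mask], y[mask])
        assigned = lda.predict(X[i])
        confusion.loc[y[i], assigned] += 1
    return NodeDiscrimination(
        node=int(node), species=tuple(classes), confusion=confusion, excluded=excluded
    )


def node_discrimination_table(
    traits: TraitMatrix,
) -> list[NodeDiscrimination]:
    """Leave-one-out LDA per heteroblastic node over a full trait matrix.

    Nodes with fewer than 2 usable species are skipped with a warning.
    """
    nodes = sorted(set(traits.meta["node"]))
    out = []
    values = traits.values.to_numpy()
    for node in nodes:
        rows = (traits.meta["node"] == node).to_numpy()
        try:
            out.append(
                loo_species_assignment(
                    values[rows], traits.meta.loc[rows, "species"].to_numpy(), node=node
                )
            )
        except ValidationError as exc:
            warnings.warn(f"node {node} skipped: {exc}", stacklevel=2)
    return out


def discrimination_frame(results: list[NodeDiscrimination]) -> pd.DataFrame:
    """Species x node matrix of correct-assignment proportions, with an
    ``average`` row (missing cells where a species was excluded)."""
    cols = {}
    for r in results:
        col = r.proportions
        col.loc["average"] = r.average
        cols[r.node] = col
    return pd.DataFrame(cols)


def trait_sd_by_node(traits: TraitMatrix) -> pd.DataFrame:
    """Sample standard deviation (n-1 denominator) of each trait across all
    leaves at each node, pooled over species.  Returns traits x nodes; a node
    with a single leaf yields a column of NaN."""
    nodes = sorted(set(traits.meta["node"]))
    cols = {}
    for node in nodes:
        rows = traits.values[(traits.meta["node"] == node).to_numpy()]
        if len(rows) < 2:
            warnings.warn(f"node {node}: single leaf; SD undefined", stacklevel=2)
            cols[node] = pd.Series(np.nan, index=traits.values.columns)
        else:
            cols[node] = rows.std(axis=0, ddof=1)
    return pd.DataFrame(cols)
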