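"""Species, heteroblasty and species x heteroblasty effect decomposition.

Every trait column (aligned landmark coordinate or EFD coefficient) is
modelled independently by ordinary least squares:

    trait ~ species * node

with treatment coding: the reference species is absorbed into the intercept,
node enters as a numeric covariate (one slope per term, as a single
"heteroblasty" row demands), and the interaction terms give each
non-reference species its own deviation slope.  The reference species'
effects are exactly zero by coding; by default the reference is the
alphabetically first species label.

The full matrix of fitted effects is the input to heatmap figures; traits are
ordered by agglomerative clustering of their effect profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ValidationError
from .traits import TraitMatrix


def _design(
    species: np.ndarray, node: np.ndarray, reference: str
) -> tuple[np.ndarray, list[str], list[str]]:
    labels = sorted(set(species))
    if reference not in labels:
        raise ValidationError(f"reference species {reference!r} not in data")
    others = [s for s in labels if s != reference]
    n = len(species)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for s in others:
        cols.append((species == s).astype(float))
        names.append(f"species[{s}]")
    cols.append(node.astype(float))
    names.append("node")
    for s in others:
        cols.append((species == s) * node.astype(float))
        names.append(f"species[{s}]:node")
    return np.column_stack(cols), names, others


def fit_trait_model(
    trait: np.ndarray,
    species: np.ndarray,
    node: np.ndarray,
    reference: str,
) -> dict[str, dict[str, float]]:
    """OLS decomposition of one trait into species, node and interaction terms.

    Returns ``{"coef": {...}, "se": {...}}`` keyed by term name (``intercept``,
    ``species[s]``, ``node``, ``species[s]:node``).  Coefficients involving a
    species observed at a single node value are non-estimable and returned as
    NaN.
    """
    trait = np.asarray(trait, dtype=float)
    species = np.asarray(species)
    node = np.asarray(node)
    if not (len(trait) == len(species) == len(node)):
        raise ValidationError("trait, species and node must have equal length")
    if len(set(species)) < 2 or len(set(node)) < 2:
        raise ValidationError("need >= 2 species and >= 2 distinct node values")
    X, names, others = _design(species, node, reference)
    coef, se, _ = _ols_multi(X, trait[:, None], species, node, others, names)
    return {
        "coef": dict(zip(names, coef[:, 0])),
        "se": dict(zip(names, se[:, 0])),
    }


def _ols_multi(X, Y, species, node, others, names):
    """Vectorised OLS of many trait columns on one shared design matrix."""
    n, p = X.shape
    bad_species = {
        s for s in others if len(set(node[species == s])) < 2
    }
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        XtX_inv = np.linalg.pinv(XtX)
    else:
        XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coef
    dof = max(n - rank, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    if bad_species:
        for i, name in enumerate(names):
            for s in bad_species:
                if name in (f"species[{s}]", f"species[{s}]:node"):
                    coef[i, :] = np.nan
                    se[i, :] = np.nan
    return coef, se, rank


@dataclass
class TraitEffectsResults:
    """Fitted per-trait effect decomposition.

    ``params``/``bse`` are term x trait frames including the intercept;
    :meth:`effect_table` is the heatmap-ready traits x effects matrix in
    which the reference species' rows are exactly zero.
    """

    params: pd.DataFrame  # index: term names, columns: traits
    bse: pd.DataFrame
    reference: str
    species: list[str]  # all labels, including the reference
    constant_traits: list[str]

    def species_effects(self) -> pd.DataFrame:
        """Species main effects (species x traits); reference row is zero."""
        rows = {}
        for s in self.species:
            if s == self.reference:
                rows[s] = pd.Series(0.0, index=self.params.columns)
            else:
                rows[s] = self.params.loc[f"species[{s}]"]
        return pd.DataFrame(rows).T

    def heteroblasty_effect(self) -> pd.Series:
        """The single node slope of the reference species (traits vector)."""
        return self.params.loc["node"]

    def interaction_effects(self) -> pd.DataFrame:
        """Per-species node-slope deviations (species x traits)."""
        rows = {}
        for s in self.species:
            if s == self.reference:
                rows[s] = pd.Series(0.0, index=self.params.columns)
            else:
                rows[s] = self.params.loc[f"species[{s}]:node"]
        return pd.DataFrame(rows).T

    def effect_table(self) -> pd.DataFrame:
        """Traits x effect columns: (S-1) species, 1 heteroblasty, (S-1)
        interaction terms (reference omitted, being identically zero)."""
        non_ref = [s for s in self.species if s != self.reference]
        blocks = {}
        for s in non_ref:
            blocks[f"species:{s}"] = self.params.loc[f"species[{s}]"]
        blocks["heteroblasty"] = self.params.loc["node"]
        for s in non_ref:
            blocks[f"interaction:{s}"] = self.params.loc[f"species[{s}]:node"]
        return pd.DataFrame(blocks)

    def magnitude_summary(self) -> dict[str, float]:
        """Mean absolute effect magnitude per term family, over all traits
        and non-reference species."""
        sp = self.species_effects().drop(index=self.reference)
        ia = self.interaction_effects().drop(index=self.reference)
        return {
            "species": float(np.nanmean(np.abs(sp.to_numpy()))),
            "interaction": float(np.nanmean(np.abs(ia.to_numpy()))),
            "heteroblasty": float(np.nanmean(np.abs(self.heteroblasty_effect()))),
        }

    def predict(self, species: np.ndarray, node: np.ndarray) -> pd.DataFrame:
        X, names, _ = _design(np.asarray(species), np.asarray(node), self.reference)
        assert names == list(self.params.index)
        return pd.DataFrame(
            X @ self.params.to_numpy(), columns=self.params.columns
        )

    def summary(self) -> str:
        mags = self.magnitude_summary()
        lines = [
            "Trait effect decomposition: trait ~ species * node",
            f"reference species: {self.reference}",
            f"traits fitted: {self.params.shape[1]}"
            + (f" ({len(self.constant_traits)} constant traits flagged)" if self.constant_traits else ""),
            f"species labels: {len(self.species)}",
            "",
            "mean |effect| across traits:",
            f"  species      {mags['species']:.5f}",
            f"  interaction  {mags['interaction']:.5f}",
            f"  heteroblasty {mags['heteroblasty']:.5f}",
        ]
        return "\n".join(lines)


class TraitEffectsModel:
    """Per-trait OLS decomposition over a full trait matrix.

    Constant trait columns (e.g. the normalization-fixed first-harmonic
    coefficients) are fitted as all-zero effects and flagged.
    """

    def __init__(self, traits: TraitMatrix, reference: str | None = None):
        self.traits = traits
        labels = sorted(set(traits.meta["species"]))
        if len(labels) < 2:
            raise ValidationError("need >= 2 species")
        self.reference = reference if reference is not None else labels[0]
        if self.reference not in labels:
            raise ValidationError(f"reference species {self.reference!r} not in data")
        self.species_labels = labels

    def fit(self) -> TraitEffectsResults:
        tm = self.traits
        species = tm.meta["species"].to_numpy()
        node = tm.meta["node"].to_numpy()
        X, names, others = _design(species, node, self.reference)
        constant = tm.constant_columns()
        Y = tm.values.to_numpy()
        coef, se, _ = _ols_multi(X, Y, species, node, others, names)
        params = pd.DataFrame(coef, index=names, columns=tm.values.columns)
        bse = pd.DataFrame(se, index=names, columns=tm.values.columns)
        for c in constant:  # constant trait: effects are 0 by definition
            params.loc[params.index != "intercept", c] = 0.0
        return TraitEffectsResults(
            params=params,
            bse=bse,
            reference=self.reference,
            species=self.species_labels,
            constant_traits=constant,
        )


def effect_matrices(
    traits: TraitMatrix, reference: str | None = None
) -> TraitEffectsResults:
    """Convenience wrapper: fit :class:`TraitEffectsModel` on a trait matrix."""
    return TraitEffectsModel(traits, reference=reference).fit()


def cluster_traits(
    matrix: pd.DataFrame, method: str = "complete"
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of traits by their effect (or SD) profiles.

    ``matrix`` has one row per trait.  Returns the dendrogram leaf order (a
    deterministic permutation of the row labels; scipy breaks ties by input
    index) and the linkage matrix.
    """
    if len(matrix) < 2:
        raise ValidationError("need >= 2 traits to cluster")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("trait profiles contain non-finite values")
    Z = hierarchy.linkage(values, method=method, metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return [matrix.index[i] for i in order], Z
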