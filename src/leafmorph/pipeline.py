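"""End-to-end pipeline: ingest/simulate -> GPA -> EFD traits -> allometry ->
effects -> discrimination -> trajectories, driven by one YAML config.

Every stage writes its output under the run directory so any stage can be
re-run from the previous stage's serialised output; a manifest records the
seed, per-stage derived seeds, input digests and warning counts.  One root
seed governs all stochastic stages through stage-name-hashed substreams, so
adding a stage does not perturb earlier streams.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .allometry import PolygonSpec, collection_subareas, fit_allometry, subarea_frame
from .data_model import (
    BASE_FIRST,
    LeafCollection,
    TableDialect,
    collection_from_json,
    collection_to_json,
    read_landmark_table,
    read_nef,
    renumber_nodes,
    write_nef,
)
from .discrimination import discrimination_frame, node_discrimination_table, trait_sd_by_node
from .effects import TraitEffectsModel, cluster_traits
from .efd import normalize_efd, outline_to_efd
from .errors import ValidationError
from .procrustes import align_collection
from .synthetic import SimParams, generate_dataset
from .traits import build_trait_matrix
from .trajectories import convergence_stat, embed_2d, vine_vectors


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stable across stage additions)."""
    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``landmarks_path`` (ingest) or ``sim`` (simulate) must be
    present.
    """

    out_dir: str
    seed: int = 0
    landmarks_path: str | None = None
    nef_path: str | None = None
    numbering: str = BASE_FIRST
    sim: SimParams | None = None
    n_harmonics: int = 20
    polygon_spec_path: str | None = None
    reference_species: str | None = None
    perplexity: float = 40.0
    embedding_method: str = "tsne"
    allow_reflection: bool = True

    def __post_init__(self) -> None:
        has_input = self.landmarks_path is not None
        has_sim = self.sim is not None
        if has_input == has_sim:
            raise ValidationError(
                "exactly one of landmarks_path or sim must be configured"
            )
        if self.n_harmonics < 1:
            raise ValidationError("n_harmonics must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = SimParams(**sim)
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(sim=sim, **raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``manifest.json`` in the run directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }

    def record_stage(name: str, caught: list[warnings.WarningMessage], **extra) -> None:
        manifest["stages"][name] = {
            "seed": stage_seed(config.seed, name),
            "warnings": [str(w.message) for w in caught],
            **extra,
        }

    # --- stage: ingest or simulate -------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if config.sim is not None:
            sim = SimParams(**{**asdict(config.sim), "seed": stage_seed(config.seed, "simulate")})
            collection, truth = generate_dataset(sim)
            truth_path = out / "ground_truth.json"
            truth_path.write_text(
                json.dumps(
                    {
                        "area_fractions": truth.area_fractions,
                        "generating_slopes": truth.generating_slopes,
                        "weights": {k: v.tolist() for k, v in truth.weights.items()},
                        "scales": truth.scales.tolist(),
                    }
                )
            )
            record_stage("simulate", caught, n_leaves=len(collection))
        else:
            collection = read_landmark_table(
                config.landmarks_path, TableDialect(numbering=config.numbering)
            )
            manifest["inputs"]["landmarks"] = _digest(Path(config.landmarks_path))
            if config.nef_path:
                nef = read_nef(config.nef_path)
                manifest["inputs"]["nef"] = _digest(Path(config.nef_path))
            collection = renumber_nodes(collection, BASE_FIRST)
            record_stage("ingest", caught, n_leaves=len(collection))
    collection_to_json(collection, out / "dataset.json")

    # --- stage: GPA -----------------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        aligned, gpa_result = align_collection(
            collection, allow_reflection=config.allow_reflection
        )
        record_stage(
            "gpa",
            caught,
            iterations=gpa_result.iterations,
            converged=gpa_result.converged,
        )
    collection_to_json(aligned, out / "aligned.json")

    # --- stage: EFD + traits -------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        traits = build_trait_matrix(aligned, n_harmonics=config.n_harmonics, align=False)
        if any(r.outline is not None for r in aligned.records):
            per_leaf = {
                f"{r.vine_id}_n{r.node}": normalize_efd(
                    outline_to_efd(r.outline, config.n_harmonics)
                )
                for r in aligned.records
                if r.outline is not None
            }
            write_nef(per_leaf, out / "shapes.nef")
        record_stage("efd", caught, n_traits=traits.values.shape[1])
    traits.values.join(traits.meta).to_csv(out / "traits.csv", index=False)

    # --- stage: allometry ----------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        spec = (
            PolygonSpec.from_yaml(config.polygon_spec_path)
            if config.polygon_spec_path
            else PolygonSpec.default()
        )
        subareas = collection_subareas(aligned, spec)
        fits = fit_allometry(subareas, group_by="species")
        overall = fit_allometry(subareas, group_by="overall")
        record_stage("allometry", caught, n_flagged=sum(not r.valid for r in subareas))
    subarea_frame(subareas).to_csv(out / "subareas.csv", index=False)
    fits.frame().to_csv(out / "allometry_species.csv", index=False)
    overall.frame().to_csv(out / "allometry_overall.csv", index=False)

    # --- stage: effects -------------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        informative = traits.informative()
        effects_res = TraitEffectsModel(
            informative, reference=config.reference_species
        ).fit()
        table = effects_res.effect_table()
        order, _ = cluster_traits(table)
        record_stage(
            "effects",
            caught,
            reference=effects_res.reference,
            magnitudes=effects_res.magnitude_summary(),
        )
    table.loc[order].to_csv(out / "effects.csv")

    # --- stage: discrimination ------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        disc = node_discrimination_table(informative)
        sd = trait_sd_by_node(informative)
        record_stage(
            "discrimination",
            caught,
            node_averages={r.node: r.average for r in disc},
        )
    discrimination_frame(disc).to_csv(out / "discrimination.csv")
    sd.to_csv(out / "trait_sd_by_node.csv")

    # --- stage: trajectories --------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        embedding = embed_2d(
            informative,
            perplexity=config.perplexity,
            seed=stage_seed(config.seed, "trajectories"),
            method=config.embedding_method,
        )
        vectors = vine_vectors(embedding, aligned)
        base_d, tip_d, ratio = convergence_stat(vectors)
        record_stage(
            "trajectories",
            caught,
            method=embedding.method,
            perplexity=embedding.perplexity,
            convergence={"base": base_d, "tip": tip_d, "ratio": ratio},
        )
    emb = traits.meta.copy()
    emb["dim1"] = embedding.coords[:, 0]
    emb["dim2"] = embedding.coords[:, 1]
    emb.to_csv(out / "embedding.csv", index=False)
    import pandas as pd

    pd.DataFrame(
        [
            {
                "vine": v.vine_id,
                "species": v.species,
                "class_label": v.class_label,
                "base_node": v.base_node,
                "tip_node": v.tip_node,
                "base1": v.base[0],
                "base2": v.base[1],
                "tip1": v.tip[0],
                "tip2": v.tip[1],
            }
            for v in vectors
        ]
    ).to_csv(out / "vine_vectors.csv", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
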