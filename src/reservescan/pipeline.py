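"""End-to-end benchmark pipeline: simulate -> models -> screen -> call ->
stats -> tree/layers.

Convenience layer used by the command-line interface and by reproducibility
scripts; each stage is a thin call into the corresponding module, so the
whole run is a deterministic function of the seed and the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .homology_search import ScreeningConfig, ScreenResult, calibrate_library, screen_cohort
from .model_factory import ProfileModel, build_model_library
from .pathway_caller import PathwayCallMatrix, build_matrix, default_pathways, summarize_counts
from .registry import SeedRegistry, load_registry
from .reserve_stats import TTestVariant, compare_all
from .synthetic_cohort import Cohort, CohortConfig, default_cohort_config, generate_cohort, synthesize_homolog_store
from .taxonomy_viz import build_tree, default_layer_specs, export_layers, lineages_from_taxonomy


@dataclass
class BenchmarkResult:
    """All artifacts of one simulated screen."""

    cohort: Cohort
    models: dict[str, list[ProfileModel]]
    screen: ScreenResult
    matrix: PathwayCallMatrix
    summary: pd.DataFrame
    comparisons: pd.DataFrame
    newick: str


def build_and_calibrate_models(
    registry: SeedRegistry,
    seed: int = 0,
    n_homologs: int = 24,
    homolog_identity_range: tuple[float, float] = (0.80, 0.95),
    n_calibration: int = 200,
) -> dict[str, list[ProfileModel]]:
    """Synthesize homolog sets, build every enzyme model and calibrate it."""
    homolog_store, domain_homologs = synthesize_homolog_store(
        registry, n_per_seed=n_homologs, identity_range=homolog_identity_range, rng_seed=seed
    )
    models = build_model_library(registry, homolog_store, domain_homologs)
    calibrate_library(models, n_random=n_calibration, rng_seed=seed)
    return models


def run_benchmark(
    seed: int = 0,
    cohort_config: CohortConfig | None = None,
    registry: SeedRegistry | None = None,
    screening: ScreeningConfig | None = None,
    alpha: float = 0.05,
    variant: TTestVariant = TTestVariant.POOLED,
    n_homologs: int = 24,
    n_calibration: int = 200,
    models: dict[str, list[ProfileModel]] | None = None,
) -> BenchmarkResult:
    """Run the full synthetic benchmark and return every artifact."""
    registry = registry or load_registry()
    cohort_config = cohort_config or default_cohort_config(rng_seed=seed)
    screening = screening or ScreeningConfig()
    cohort = generate_cohort(cohort_config, registry)
    if models is None:
        models = build_and_calibrate_models(
            registry, seed=seed, n_homologs=n_homologs, n_calibration=n_calibration
        )
    screen = screen_cohort(models, cohort.proteomes, screening, registry)
    matrix = build_matrix(screen.profiles, default_pathways(), taxonomy=cohort.taxonomy_table())
    summary = summarize_counts(matrix)
    comparisons = compare_all(matrix, alpha=alpha, variant=variant)
    newick = build_tree(lineages_from_taxonomy(cohort.taxonomy_table()))
    return BenchmarkResult(
        cohort=cohort,
        models=models,
        screen=screen,
        matrix=matrix,
        summary=summary,
        comparisons=comparisons,
        newick=newick,
    )


def write_outputs(result: BenchmarkResult, outdir, seed: int, config_dict: dict | None = None) -> None:
    """Write every pipeline artifact plus a provenance manifest."""
    from .io import write_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.cohort.write(outdir / "cohort")
    save_models(result.models, outdir / "models.json")
    write_tsv(result.screen.hits_frame(), outdir / "hits.tsv")
    result.matrix.to_tsv(outdir / "matrix.tsv")
    result.matrix.to_json(outdir / "matrix.json")
    write_tsv(result.summary, outdir / "summary.tsv")
    write_tsv(result.comparisons, outdir / "comparisons.tsv")
    (outdir / "tree.nwk").write_text(result.newick + "\n")
    export_layers(result.matrix, result.newick, default_layer_specs(result.matrix), outdir / "layers")
    config_json = json.dumps(config_dict or {}, sort_keys=True)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_proteomes": len(result.cohort.truth),
        "n_models": sum(len(v) for v in result.models.values()),
        "n_hits_kept": len(result.screen.kept_hits),
        "n_pathways": len(result.matrix.pathway_ids),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def save_models(models: dict[str, list[ProfileModel]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {e: [m.to_dict() for m in ms] for e, ms in models.items()}
    path.write_text(json.dumps(payload))


def load_models(path) -> dict[str, list[ProfileModel]]:
    payload = json.loads(Path(path).read_text())
    return {e: [ProfileModel.from_dict(d) for d in ds] for e, ds in payload.items()}
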