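"""End-to-end orchestration: ingest → embed → reduce → cluster → validate → map.

A single structured config drives the run; every stage records its
parameters, derived seed, input/output content hashes and timestamps in a
flat append-only run manifest, so a re-run with identical config and inputs
can be checked for bitwise-identical deterministic outputs. Stages are
skippable by supplying their outputs as precomputed inputs.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from ._utils import derive_seed, sha256_file
from .corpus_io import (
    distinct_questions,
    load_question_records,
    partition_records,
    write_records_jsonl,
)
from .clustering import elbow_scan, spherical_kmeans
from .dim_reduction import lle_fit, select_dimension, sweep_dimensions
from .embedding import HashedNgramEncoder, encode_texts, load_embeddings, save_embeddings
from .synthetic_data import generate_question_corpus, make_reference_taxonomy
from .taxonomy_mapping import (
    build_category_strings,
    bundled_category_table,
    load_taxonomy,
    map_categories,
    write_mapping,
)
from .validation_igp import replicate_igp

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "embed", "reduce", "cluster", "validate", "map")


class SimulateConfig(BaseModel):
    enabled: bool = True
    categories: list[str] = Field(
        default_factory=lambda: ["Health", "Education", "Employment", "Housing", "Legal", "Family"]
    )
    n_per_category: int = 30
    duplicate_rate: float = 0.2


class IngestConfig(BaseModel):
    records_path: str | None = None  # supplied -> simulate not needed


class EmbedConfig(BaseModel):
    backend: Literal["fallback", "sentence_transformer"] = "fallback"
    dim: int = 128
    model_name: str = "sentence-transformers/all-mpnet-base-v2"
    embeddings_path: str | None = None  # supplied -> stage skipped
    key_mode: Literal["text_only", "path_and_text"] = "text_only"


class ReduceConfig(BaseModel):
    enabled: bool = True
    K: int = 5
    d_grid: list[int] = Field(default_factory=lambda: [2, 3, 5, 8])
    replications: int = 2
    subsample_size: int | None = None
    select_mode: Literal["manual", "knee"] = "knee"
    manual_d: int | None = None
    coordinates_path: str | None = None


class ClusterConfig(BaseModel):
    k_grid: list[int] = Field(default_factory=lambda: list(range(2, 11)))
    k: int | None = None  # None -> knee of the inertia curve
    max_iter: int = 10
    init: str = "cosine_plus_plus"
    restarts: int = 5


class ValidateConfig(BaseModel):
    enabled: bool = True
    n_runs: int = 2
    train_size: int | None = None  # None -> floor(0.54 * n), the study's ratio
    metric: Literal["cosine", "one_minus_pearson"] = "cosine"
    space: Literal["reduced", "raw"] = "reduced"


class MapConfig(BaseModel):
    enabled: bool = True
    taxonomy_path: str | None = None  # None -> bundled category table
    reference_path: str | None = None  # None and no reference_names -> skipped
    reference_names: list[str] | None = None


class PipelineConfig(BaseModel):
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    ingest: IngestConfig = IngestConfig()
    embed: EmbedConfig = EmbedConfig()
    reduce: ReduceConfig = ReduceConfig()
    cluster: ClusterConfig = ClusterConfig()
    validate_: ValidateConfig = Field(default=ValidateConfig(), alias="validate")
    map: MapConfig = MapConfig()

    model_config = {"populate_by_name": True}


class ConfigError(ValueError):
    pass


def load_config(source: str | Path | dict[str, Any]) -> PipelineConfig:
    """Validate a config mapping or YAML file, naming the offending field."""
    if isinstance(source, (str, Path)):
        import yaml

        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = source
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config field '{loc}': {first['msg']}") from exc


class Manifest:
    """Flat append-only record of stage parameters, seeds and content hashes."""

    def __init__(self, master_seed: int):
        self.stages: list[dict[str, Any]] = []
        self.master_seed = master_seed

    def record(
        self,
        name: str,
        parameters: dict[str, Any],
        seed: int | None,
        inputs: list[str],
        outputs: list[str],
        status: str = "completed",
    ) -> None:
        self.stages.append(
            {
                "stage": name,
                "status": status,
                "parameters": parameters,
                "seed": seed,
                "input_hashes": {str(p): sha256_file(p) for p in inputs},
                "output_hashes": {str(p): sha256_file(p) for p in outputs},
                "software_version": f"semharm {__version__}",
                "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            }
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "master_seed": self.master_seed,
            "rng": "numpy.random.default_rng (PCG64), per-stage seeds via SeedSequence spawn keys",
            "stages": self.stages,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def run_pipeline(config: PipelineConfig | dict | str | Path, out_dir: str | Path) -> Manifest:
    """Execute the configured stages, writing artifacts and a run manifest.

    Returns the manifest; on a stage failure the exception propagates after
    the manifest (with completed stages) is written, preserving partial
    outputs for debugging.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(cfg.seed)
    manifest_path = out / "manifest.json"
    try:
        _run_stages(cfg, out, manifest)
    finally:
        manifest.write(manifest_path)
    return manifest


def _run_stages(cfg: PipelineConfig, out: Path, manifest: Manifest) -> None:
    seeds = {name: derive_seed(cfg.seed, i) for i, name in enumerate(STAGES)}

    # -- ingest (or simulate) -------------------------------------------------
    records_path = out / "records.jsonl"
    if cfg.ingest.records_path:
        records = load_question_records(cfg.ingest.records_path)
        write_records_jsonl(records, records_path)
        manifest.record(
            "ingest", {"records_path": cfg.ingest.records_path}, None,
            [cfg.ingest.records_path], [records_path],
        )
        true_category = None
    elif cfg.simulate.enabled:
        corpus = generate_question_corpus(
            cfg.simulate.categories,
            cfg.simulate.n_per_category,
            seed=seeds["simulate"],
            duplicate_rate=cfg.simulate.duplicate_rate,
        )
        records = corpus.records
        true_category = corpus.true_category
        write_records_jsonl(records, records_path)
        truth_path = out / "ground_truth.json"
        truth_path.write_text(json.dumps(corpus.true_category, indent=1))
        manifest.record(
            "simulate", cfg.simulate.model_dump(), seeds["simulate"], [], [records_path, truth_path]
        )
    else:
        raise ConfigError("invalid config field 'ingest.records_path': no input records configured")

    # dedup report at the analysis boundary
    dedup_rows = []
    for mode in ("path_and_text", "text_only"):
        _, count = distinct_questions(records, mode)
        dedup_rows.append({"key_mode": mode, "count": count})
    dedup_path = out / "dedup_report.csv"
    pd.DataFrame(dedup_rows).to_csv(dedup_path, index=False)
    manifest.record("dedup", {}, None, [records_path], [dedup_path])

    # -- embed ----------------------------------------------------------------
    emb_prefix = out / "embeddings"
    if cfg.embed.embeddings_path:
        emb = load_embeddings(cfg.embed.embeddings_path)
        save_embeddings(emb, emb_prefix)
        manifest.record(
            "embed", {"embeddings_path": cfg.embed.embeddings_path, "skipped_encode": True},
            None, [], [emb_prefix.with_suffix(".tsv"), emb_prefix.with_suffix(".json")],
        )
    else:
        keys, _ = distinct_questions(records, cfg.embed.key_mode)
        # embed the first-occurrence verbatim text per distinct key
        seen: dict[str, str] = {}
        for rec in records:
            k, _ = distinct_questions([rec], cfg.embed.key_mode)
            seen.setdefault(k[0], rec.field_name)
        texts = [seen[k] for k in keys]
        if cfg.embed.backend == "fallback":
            encoder = HashedNgramEncoder(dim=cfg.embed.dim, seed=seeds["embed"])
        else:
            from .embedding import SentenceTransformerEncoder

            encoder = SentenceTransformerEncoder(cfg.embed.model_name)
        emb = encode_texts(texts, encoder, ids=keys)
        save_embeddings(emb, emb_prefix)
        manifest.record(
            "embed",
            {"backend": cfg.embed.backend, "dim": emb.dim, "encoder_tag": emb.encoder_tag,
             "key_mode": cfg.embed.key_mode, "n_texts": emb.n},
            seeds["embed"], [records_path],
            [emb_prefix.with_suffix(".tsv"), emb_prefix.with_suffix(".json")],
        )

    # -- reduce ---------------------------------------------------------------
    coords_path = out / "coordinates.tsv"
    if cfg.reduce.coordinates_path:
        coords = np.loadtxt(cfg.reduce.coordinates_path, delimiter="\t", ndmin=2)
        np.savetxt(coords_path, coords, delimiter="\t")
        manifest.record("reduce", {"coordinates_path": cfg.reduce.coordinates_path},
                        None, [cfg.reduce.coordinates_path], [coords_path])
    elif cfg.reduce.enabled:
        n = emb.n
        sub = cfg.reduce.subsample_size or max(min(n, 50), int(0.54 * n))
        sub = min(sub, n)
        table = sweep_dimensions(
            emb.vectors, K=cfg.reduce.K, d_grid=cfg.reduce.d_grid,
            replications=cfg.reduce.replications, subsample_size=sub, seed=seeds["reduce"],
        )
        sweep_path = out / "dimension_sweep.csv"
        table.table.to_csv(sweep_path, index=False)
        d = select_dimension(table, mode=cfg.reduce.select_mode, manual_d=cfg.reduce.manual_d)
        result = lle_fit(emb.vectors, K=cfg.reduce.K, d=d, seed=seeds["reduce"])
        coords = result.Y
        np.savetxt(coords_path, coords, delimiter="\t")
        manifest.record(
            "reduce",
            {"K": cfg.reduce.K, "d_grid": cfg.reduce.d_grid, "selected_d": d,
             "select_mode": cfg.reduce.select_mode, "subsample_size": sub,
             "replications": cfg.reduce.replications, "phi": result.phi},
            seeds["reduce"], [emb_prefix.with_suffix(".tsv")], [sweep_path, coords_path],
        )
    else:
        coords = emb.vectors
        np.savetxt(coords_path, coords, delimiter="\t")
        manifest.record("reduce", {"enabled": False}, None,
                        [emb_prefix.with_suffix(".tsv")], [coords_path])

    # -- cluster --------------------------------------------------------------
    diag = elbow_scan(
        coords, cfg.cluster.k_grid, max_iter=cfg.cluster.max_iter,
        init=cfg.cluster.init, restarts=cfg.cluster.restarts, seed=seeds["cluster"],
    )
    diag_path = out / "selection_diagnostics.csv"
    diag.table.to_csv(diag_path, index=False)
    k = cfg.cluster.k or diag.knee_k()
    model = spherical_kmeans(
        coords, k, max_iter=cfg.cluster.max_iter, init=cfg.cluster.init,
        restarts=cfg.cluster.restarts, seed=seeds["cluster"],
    )
    centroids_path = out / "centroids.tsv"
    labels_path = out / "labels.csv"
    model_path = out / "cluster_model.json"
    np.savetxt(centroids_path, model.centroids, delimiter="\t")
    pd.DataFrame({"item_id": emb.ids if cfg.reduce.coordinates_path is None else
                  [str(i) for i in range(coords.shape[0])],
                  "cluster": model.labels}).to_csv(labels_path, index=False)
    model_path.write_text(json.dumps(
        {"k": model.k, "inertia": model.inertia, "converged": model.converged,
         "n_iter": model.n_iter, "init": model.init_method, "max_iter": model.max_iter},
        indent=1))
    manifest.record(
        "cluster",
        {"k_grid": cfg.cluster.k_grid, "selected_k": k, "max_iter": cfg.cluster.max_iter,
         "init": cfg.cluster.init, "restarts": cfg.cluster.restarts, "inertia": model.inertia},
        seeds["cluster"], [coords_path], [diag_path, centroids_path, labels_path, model_path],
    )

    # -- validate (IGP) -------------------------------------------------------
    if cfg.validate_.enabled:
        n = coords.shape[0]
        train_size = cfg.validate_.train_size or max(2, int(round(n * 1937 / 3582)))
        if train_size >= n:
            raise ConfigError(f"invalid config field 'validate.train_size': {train_size} >= n={n}")
        _, igp_table = replicate_igp(
            coords, k=k, n_runs=cfg.validate_.n_runs, train_size=train_size,
            seed=seeds["validate"], metric=cfg.validate_.metric,
            max_iter=cfg.cluster.max_iter, init=cfg.cluster.init, restarts=cfg.cluster.restarts,
        )
        igp_path = out / "igp_summary.csv"
        igp_table.to_csv(igp_path, index=False)
        manifest.record(
            "validate",
            {"n_runs": cfg.validate_.n_runs, "train_size": train_size,
             "test_size": n - train_size, "metric": cfg.validate_.metric, "k": k},
            seeds["validate"], [coords_path], [igp_path],
        )
    else:
        manifest.record("validate", {"enabled": False}, None, [], [], status="skipped")

    # -- map ------------------------------------------------------------------
    ref_names = cfg.map.reference_names
    if cfg.map.enabled and ref_names is None and cfg.map.reference_path:
        ref_path = Path(cfg.map.reference_path)
        if ref_path.suffix == ".csv":
            ref_names = pd.read_csv(ref_path, header=None)[0].astype(str).tolist()
        else:
            ref_names = [ln.strip() for ln in ref_path.read_text().splitlines() if ln.strip()]
    if cfg.map.enabled and ref_names:
        entries = (
            load_taxonomy(cfg.map.taxonomy_path) if cfg.map.taxonomy_path
            else bundled_category_table()
        )
        strings = build_category_strings(entries)
        encoder = HashedNgramEncoder(dim=cfg.embed.dim, seed=seeds["embed"])
        result = map_categories(
            strings, ref_names, encoder, category_keys=[e.key for e in entries]
        )
        paths = write_mapping(result, out)
        manifest.record(
            "map",
            {"n_categories": len(strings), "n_references": len(ref_names),
             "threshold": result.threshold, "coverage_percent": result.coverage_percent},
            seeds["map"], [], list(paths.values()),
        )
    else:
        manifest.record("map", {"enabled": bool(cfg.map.enabled)}, None, [], [], status="skipped")


def apply_sme_relabels(
    labels: pd.DataFrame, relabels: pd.DataFrame | str | Path
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Apply subject-matter-expert overrides on top of algorithmic labels.

    ``labels`` has columns ``item_id, cluster``; the relabel file has the
    same columns, one row per override. Unknown item or cluster ids are
    rejected with the full offender list. Returns the revised table and an
    audit log with before/after rows and the override fraction (reported,
    not enforced).
    """
    if not isinstance(relabels, pd.DataFrame):
        relabels = pd.read_csv(relabels, dtype={"item_id": str, "cluster": int})
    labels = labels.copy()
    labels["item_id"] = labels["item_id"].astype(str)
    known_ids = set(labels["item_id"])
    known_clusters = set(int(c) for c in labels["cluster"])
    bad_ids = [i for i in relabels["item_id"].astype(str) if i not in known_ids]
    bad_clusters = [int(c) for c in relabels["cluster"] if int(c) not in known_clusters]
    if bad_ids or bad_clusters:
        raise ValueError(
            f"unknown item ids {bad_ids!r} / unknown cluster ids {bad_clusters!r} in relabel file"
        )
    audit = []
    idx = labels.set_index("item_id")["cluster"].to_dict()
    for row in relabels.itertuples(index=False):
        before = int(idx[str(row.item_id)])
        after = int(row.cluster)
        if before != after:
            audit.append({"item_id": str(row.item_id), "before": before, "after": after})
            idx[str(row.item_id)] = after
    revised = labels.copy()
    revised["cluster"] = [idx[i] for i in revised["item_id"]]
    log = {
        "overrides": audit,
        "n_overridden": len(audit),
        "n_items": len(labels),
        "override_fraction_percent": 100.0 * len(audit) / len(labels) if len(labels) else 0.0,
    }
    return revised, log
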