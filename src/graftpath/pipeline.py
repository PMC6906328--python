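"""End-to-end pipeline: activation scoring → GLPAP selection → category
enrichment → crosstalk network / central pathways → DEG profile →
hypothesis evaluation, with file I/O, a run manifest and stage logging."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .data import (
    ExpressionMatrix,
    GraftPathError,
    PathwayDB,
    logger,
    read_ppi_edgelist,
    read_seed_lists,
    write_activity_tsv,
)
from .activity import score_pathways
from .enrichment import (
    enrich_categories,
    select_glpaps,
    write_enrichment_tsv,
    write_glpap_tsv,
)
from .crosstalk import (
    build_pathway_graph,
    select_central_pathways,
    write_graph_tsv,
)
from .propagation import (
    build_deg_profile,
    evaluate_hypotheses,
    write_hypothesis_tsv,
    write_topk_tsv,
)


class PipelineError(GraftPathError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Full-pipeline configuration (YAML-serializable)."""

    expression: str = "expression.tsv"
    pathways: str = "pathways.gmt"
    ppi: str = "ppi_edges.tsv"
    seeds_dir: str = "seeds"
    output_dir: str = "results"
    case_subject: str = "S1"
    control_subject: str = "S2"
    graft_loss_timepoint: str = "t3"
    baseline_timepoint: str = "t2"
    alpha: float = 0.05
    min_expression: float = 1.0
    n_permutations: int = 1000
    min_crosstalk: int = 1
    restart_prob: float = 0.5
    tol: float = 1.0e-10
    max_iter: int = 10000
    n_sim: int = 1000
    top_k: int | None = 100
    sampler: str = "uniform"
    normalization: str = "symmetric"
    rank_by: str = "signed"
    restrict_central_to_top_category: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise PipelineError(f"[config] alpha must be in (0, 1), got {self.alpha}")
        for label in ("expression", "pathways", "ppi", "seeds_dir"):
            path = Path(getattr(self, label))
            if not path.exists():
                raise PipelineError(f"[config] {label} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"[config] unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


def load_schemas() -> dict[str, list[str]]:
    """Output-table column schemas shipped with the package."""
    text = resources.files("graftpath").joinpath("schemas.json").read_text()
    return json.loads(text)


def validate_outputs(output_dir: str | Path) -> None:
    """Check every emitted table's header against the shipped schema."""
    output_dir = Path(output_dir)
    schemas = load_schemas()
    for filename, columns in schemas.items():
        path = output_dir / filename
        if not path.exists():
            continue
        header = path.read_text().splitlines()[0].split("\t")
        if header != columns:
            raise PipelineError(
                f"[schema] {filename}: header {header} != expected {columns}"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the result tables plus a manifest.

    Idempotent for a fixed config: reruns produce byte-identical tables.
    Returns a dict with the in-memory stage results and output paths.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}

    def stage(label: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", label)
                return self

            def __exit__(self, exc_type, exc, tb):
                timers[label] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"[{label}] {exc}") from exc
                logger.info("stage %s: done in %.3fs", label, timers[label])

        return _Timer()

    with stage("load"):
        expr = ExpressionMatrix.read_tsv(config.expression)
        db = PathwayDB.read_gmt(config.pathways)
        ppi = read_ppi_edgelist(config.ppi)
        seeds = read_seed_lists(config.seeds_dir)

    within = (
        (config.case_subject, config.graft_loss_timepoint),
        (config.case_subject, config.baseline_timepoint),
    )
    between = (
        (config.case_subject, config.graft_loss_timepoint),
        (config.control_subject, config.graft_loss_timepoint),
    )
    with stage("activity"):
        results_within = score_pathways(
            expr, db, *within,
            comparison_label="within_subject",
            min_expression=config.min_expression,
            n_permutations=config.n_permutations,
            rng_seed=config.rng_seed,
        )
        results_between = score_pathways(
            expr, db, *between,
            comparison_label="between_subject",
            min_expression=config.min_expression,
            n_permutations=config.n_permutations,
            rng_seed=config.rng_seed + 1,
        )
        write_activity_tsv(results_within, db, out_dir / "activity_within_subject.tsv")
        write_activity_tsv(results_between, db, out_dir / "activity_between_subject.tsv")

    with stage("glpap"):
        glpaps = select_glpaps(results_within, results_between, alpha=config.alpha)
        write_glpap_tsv(glpaps, db, out_dir / "glpap_pathways.tsv")

    with stage("enrichment"):
        enrichment = enrich_categories(glpaps, db)
        write_enrichment_tsv(enrichment, out_dir / "category_enrichment.tsv")

    with stage("network"):
        graph = build_pathway_graph(glpaps, db, ppi, min_crosstalk=config.min_crosstalk)
        write_graph_tsv(
            graph,
            out_dir / "pathway_network_edges.tsv",
            out_dir / "pathway_network_nodes.tsv",
        )
        central = None
        if graph.number_of_nodes() > 0:
            restrict = (
                enrichment[0].category
                if config.restrict_central_to_top_category
                else None
            )
            central = select_central_pathways(graph, restrict_to=restrict)
            rows = [
                {
                    "pathway_id": pid,
                    "name": db[pid].name,
                    "category": db[pid].category,
                    "closeness": central.closeness[pid],
                    "degree": central.degree[pid],
                }
                for pid in central.selected
            ]
            import pandas as pd

            pd.DataFrame(
                rows, columns=["pathway_id", "name", "category", "closeness", "degree"]
            ).to_csv(
                out_dir / "central_pathways.tsv", sep="\t", index=False,
                float_format="%.10g",
            )

    with stage("deg_profile"):
        deg = build_deg_profile(
            expr,
            case=(config.case_subject, config.graft_loss_timepoint),
            control=(config.control_subject, config.graft_loss_timepoint),
            min_expression=config.min_expression,
            rank_by=config.rank_by,
        )

    with stage("hypotheses"):
        top_k = config.top_k
        if top_k is not None:
            n_common = len(set(deg.gene_ids) & set(ppi.nodes))
            if top_k > n_common:
                logger.warning(
                    "top_k=%d exceeds the %d genes shared by profile and network; disabled",
                    top_k, n_common,
                )
                top_k = None
        evaluations = evaluate_hypotheses(
            ppi,
            deg,
            seeds,
            restart_prob=config.restart_prob,
            tol=config.tol,
            max_iter=config.max_iter,
            normalization=config.normalization,
            n_sim=config.n_sim,
            sampler=config.sampler,
            top_k=top_k,
            rng_seed=config.rng_seed,
        )
        write_hypothesis_tsv(evaluations, out_dir / "hypothesis_evaluation.tsv")
        if top_k is not None:
            write_topk_tsv(evaluations, out_dir / "hypothesis_evaluation_topk.tsv")

    with stage("manifest"):
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "input_digests": {
                "expression": _sha256(Path(config.expression)),
                "pathways": _sha256(Path(config.pathways)),
                "ppi": _sha256(Path(config.ppi)),
            },
            "stage_seconds": timers,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    validate_outputs(out_dir)
    return {
        "glpaps": glpaps,
        "enrichment": enrichment,
        "graph": graph,
        "central": central,
        "deg_profile": deg,
        "evaluations": evaluations,
        "output_dir": out_dir,
    }
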