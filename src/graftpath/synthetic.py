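"""Synthetic study generator.

Emulates the sampling design of a two-subject longitudinal blood
transcriptome study: one graft-losing subject and one graft-stable control,
each profiled at four timepoints (t1 before transplantation, t2 stable,
t3 at graft loss, t4 after overt failure). A configurable number of
pathways is "activated" — their member genes are multiplicatively
up-regulated — in exactly one (subject, timepoint) cell, by default the
graft-losing subject at t3, so that both of the comparisons the analysis
makes (within-subject t3 vs t2, between-subject at t3) see the signal.

The generator also emits a scale-free PPI network (Barabási–Albert
preferential attachment), per-hypothesis seed-gene lists with one planted
causal hypothesis whose seeds sit adjacent to the differentially expressed
genes, and a ground-truth manifest for downstream recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data import (
    ConfigurationError,
    ExpressionMatrix,
    Pathway,
    PathwayDB,
    logger,
    write_ppi_edgelist,
    write_seed_lists,
)

#: Default etiological hypotheses for late islet xenograft loss, in the
#: conventional order; the fourth (chronic graft rejection) is causal by
#: default.
DEFAULT_HYPOTHESES: tuple[str, ...] = (
    "ER_stress",
    "islet_exhaustion",
    "lipotoxicity",
    "chronic_graft_rejection",
    "immunosuppressant_toxicity",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 2 subjects × 4 timepoints, five
    hypothesis seed sets of sizes 10/9/8/10/9, activation planted at
    (S1, t3).
    """

    n_genes: int = 2000
    n_pathways: int = 50
    n_categories: int = 10
    pathway_size_range: tuple[int, int] = (10, 40)
    n_subjects: int = 2
    timepoints: tuple[str, ...] = ("t1", "t2", "t3", "t4")
    baseline_logmean: float = 3.0
    baseline_logsd: float = 1.0
    activated_pathways: int | Sequence[str] = 5
    activation_fold: float = 4.0
    activation_timepoint: str = "t3"
    activation_subject: str = "S1"
    ppi_edges_per_node: int = 5
    n_hypotheses: int = 5
    seed_set_sizes: tuple[int, ...] = (10, 9, 8, 10, 9)
    causal_hypothesis_index: int = 3
    hypothesis_names: tuple[str, ...] | None = None
    noise_logsd: float = 0.3
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if lo < 3:
            raise ConfigurationError("pathway_size_range minimum must be >= 3")
        if hi < lo:
            raise ConfigurationError("pathway_size_range must be (min, max) with min <= max")
        if hi > self.n_genes:
            raise ConfigurationError(
                f"pathway size up to {hi} infeasible for n_genes={self.n_genes}"
            )
        if self.activation_fold < 1.0:
            raise ConfigurationError("activation_fold must be >= 1 (1 = null dataset)")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ConfigurationError("timepoints must be unique")
        if self.activation_timepoint not in self.timepoints:
            raise ConfigurationError(
                f"activation_timepoint {self.activation_timepoint!r} not in timepoints"
            )
        if len(self.seed_set_sizes) != self.n_hypotheses:
            raise ConfigurationError("seed_set_sizes length must equal n_hypotheses")
        if any(s < 1 for s in self.seed_set_sizes):
            raise ConfigurationError("seed_set_sizes must all be >= 1")
        if not (0 <= self.causal_hypothesis_index < self.n_hypotheses):
            raise ConfigurationError("causal_hypothesis_index out of range")
        names = self.resolved_hypothesis_names()
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate hypothesis names: {names}")
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects for the between-subject comparison")
        if self.ppi_edges_per_node < 1 or self.ppi_edges_per_node >= self.n_genes:
            raise ConfigurationError("ppi_edges_per_node must be in [1, n_genes)")
        if self.n_categories < 1 or self.n_categories > self.n_pathways:
            raise ConfigurationError("n_categories must be in [1, n_pathways]")

    def resolved_hypothesis_names(self) -> tuple[str, ...]:
        if self.hypothesis_names is not None:
            return tuple(self.hypothesis_names)
        names = list(DEFAULT_HYPOTHESES[: self.n_hypotheses])
        while len(names) < self.n_hypotheses:
            names.append(f"hypothesis_{len(names) + 1}")
        return tuple(names)

    def subject_ids(self) -> tuple[str, ...]:
        ids = [f"S{i + 1}" for i in range(self.n_subjects)]
        if self.activation_subject not in ids:
            raise ConfigurationError(
                f"activation_subject {self.activation_subject!r} not among {ids}"
            )
        return tuple(ids)


@dataclass(frozen=True)
class GroundTruth:
    """Manifest of the planted signal, for recovery tests."""

    activated_pathway_ids: frozenset[str]
    causal_hypothesis: str
    de_genes: frozenset[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "activated_pathways": sorted(self.activated_pathway_ids),
            "causal_hypothesis": self.causal_hypothesis,
            "de_genes": sorted(self.de_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            activated_pathway_ids=frozenset(payload["activated_pathways"]),
            causal_hypothesis=payload["causal_hypothesis"],
            de_genes=frozenset(payload["de_genes"]),
        )


class SyntheticDataset(NamedTuple):
    expression: ExpressionMatrix
    pathways: PathwayDB
    ppi: nx.Graph
    seeds: dict[str, frozenset[str]]
    truth: GroundTruth


def _plant_pathways(cfg: SimulationConfig, pathway_ids: list[str], categories: list[str]) -> list[str]:
    """Resolve the activated-pathway spec to concrete ids.

    When given a count, the planted pathways are all drawn from the first
    category so the activation signal is biologically coherent (one
    functional theme up-regulated, as in an immune response) and category
    enrichment has something to find.
    """
    if isinstance(cfg.activated_pathways, int):
        k = cfg.activated_pathways
        in_first = [pid for pid, cat in zip(pathway_ids, categories) if cat == categories[0]]
        if k > len(in_first):
            raise ConfigurationError(
                f"cannot plant {k} pathways in one category of size {len(in_first)}; "
                "increase n_pathways or decrease n_categories"
            )
        return in_first[:k]
    unknown = set(cfg.activated_pathways) - set(pathway_ids)
    if unknown:
        raise ConfigurationError(f"unknown activated pathway ids: {sorted(unknown)}")
    return list(cfg.activated_pathways)


def _causal_seeds(
    ppi: nx.Graph, de_genes: frozenset[str], size: int, rng: np.random.Generator
) -> frozenset[str]:
    """Sample causal seeds uniformly among direct PPI neighbors of DE genes.

    Seeds are neighbors of DE genes rather than DE genes themselves, so
    propagation has to spread influence over at least one hop for the causal
    hypothesis to look like the measured profile. Uniform sampling (rather
    than, say, preferring hubs) mimics literature-derived seed genes:
    functionally adjacent, typically of ordinary connectivity.
    """
    candidates = sorted({n for g in de_genes for n in ppi.neighbors(g)} - de_genes)
    if len(candidates) < size:
        candidates = sorted(set(ppi.nodes) - de_genes)
    picked = rng.choice(candidates, size=size, replace=False)
    return frozenset(str(g) for g in picked)


def _ensure_adjacency(
    ppi: nx.Graph, seeds: frozenset[str], de_genes: frozenset[str]
) -> None:
    """Wire seeds to uncovered DE genes until >= half the DE set is adjacent.

    The causal hypothesis's contract is that its seeds sit one hop from the
    bulk of the differential signal; when the greedy pick cannot reach half
    coverage on the sampled topology, the remaining adjacency is planted
    explicitly (a handful of extra edges on a graph of thousands).
    """
    covered: set[str] = set()
    for s in seeds:
        covered |= set(ppi.neighbors(s)) & de_genes
    target = -(-len(de_genes) // 2)  # ceil
    uncovered = sorted(de_genes - covered)
    ordered_seeds = sorted(seeds)
    i = 0
    while len(covered) < target and uncovered:
        g = uncovered.pop(0)
        ppi.add_edge(ordered_seeds[i % len(ordered_seeds)], g)
        covered.add(g)
        i += 1


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate expression, pathway DB, PPI, seed sets and ground truth.

    Deterministic for a fixed ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    subjects = config.subject_ids()

    # pathway database: sizes uniform in range, members sampled without
    # replacement per pathway (overlap across pathways allowed), categories
    # assigned round-robin so they partition the database evenly
    lo, hi = config.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    pathway_ids = [f"P{i + 1:03d}" for i in range(config.n_pathways)]
    categories = [f"C{(i % config.n_categories) + 1:02d}" for i in range(config.n_pathways)]
    members: list[frozenset[str]] = []
    for i in range(config.n_pathways):
        idx = rng.choice(config.n_genes, size=int(sizes[i]), replace=False)
        members.append(frozenset(genes[j] for j in idx))
    db = PathwayDB(
        Pathway(pid, f"Pathway {pid}", cat, mem)
        for pid, cat, mem in zip(pathway_ids, categories, members)
    )

    activated = _plant_pathways(config, pathway_ids, categories)
    de_genes: frozenset[str] = frozenset().union(*(db[p].genes for p in activated)) if activated else frozenset()

    # expression: log-normal baseline per gene (shared across samples) plus
    # per-sample log-noise; activation multiplies one (subject, timepoint)
    # cell of the planted genes by activation_fold
    mu = rng.normal(config.baseline_logmean, config.baseline_logsd, size=config.n_genes)
    columns = [(s, t) for s in subjects for t in config.timepoints]
    values = np.empty((config.n_genes, len(columns)))
    de_mask = np.array([g in de_genes for g in genes])
    for j, (subject, timepoint) in enumerate(columns):
        eps = rng.normal(0.0, config.noise_logsd, size=config.n_genes)
        col = np.exp(mu + eps)
        if subject == config.activation_subject and timepoint == config.activation_timepoint:
            col = np.where(de_mask, col * config.activation_fold, col)
        values[:, j] = col
    expr = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(genes, name="gene_id"),
            columns=pd.MultiIndex.from_tuples(columns, names=["subject", "timepoint"]),
        )
    )

    # PPI: preferential attachment, relabelled to gene ids
    ba_seed = int(rng.integers(2**31))
    ppi = nx.barabasi_albert_graph(config.n_genes, config.ppi_edges_per_node, seed=ba_seed)
    ppi = nx.relabel_nodes(ppi, {i: genes[i] for i in range(config.n_genes)})

    # hypothesis seed sets: causal seeds are picked (and, if needed, wired)
    # adjacent to the DE genes before the null pools are derived, so the
    # non-causal pools exclude the final DE neighborhood
    names = config.resolved_hypothesis_names()
    causal_name = names[config.causal_hypothesis_index]
    causal: frozenset[str] = frozenset()
    if de_genes:
        causal_size = config.seed_set_sizes[config.causal_hypothesis_index]
        causal = _causal_seeds(ppi, de_genes, causal_size, rng)
        _ensure_adjacency(ppi, causal, de_genes)
    de_neighborhood: set[str] = set(de_genes)
    for g in de_genes:
        de_neighborhood |= set(ppi.neighbors(g))
    null_pool = sorted(set(ppi.nodes) - de_neighborhood)
    seeds: dict[str, frozenset[str]] = {}
    for name, size in zip(names, config.seed_set_sizes):
        if name == causal_name and de_genes:
            seeds[name] = causal
        else:
            if size > len(null_pool):
                raise ConfigurationError(
                    f"seed set of size {size} exceeds the non-DE-neighborhood pool "
                    f"({len(null_pool)} genes)"
                )
            picked = rng.choice(null_pool, size=size, replace=False)
            seeds[name] = frozenset(str(g) for g in picked)

    truth = GroundTruth(
        activated_pathway_ids=frozenset(activated),
        causal_hypothesis=causal_name,
        de_genes=de_genes,
    )
    return SyntheticDataset(expr, db, ppi, seeds, truth)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the five dataset artifacts; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "pathways": out_dir / "pathways.gmt",
        "ppi": out_dir / "ppi_edges.tsv",
        "seeds_dir": out_dir / "seeds",
        "ground_truth": out_dir / "ground_truth.json",
    }
    try:
        dataset.expression.write_tsv(paths["expression"])
        dataset.pathways.write_gmt(paths["pathways"])
        write_ppi_edgelist(dataset.ppi, paths["ppi"])
        write_seed_lists(dataset.seeds, paths["seeds_dir"])
        dataset.truth.to_json(paths["ground_truth"])
    except OSError as exc:
        raise OSError(f"failed writing dataset artifact: {exc.filename or out_dir}") from exc
    return paths
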