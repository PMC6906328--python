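"""Core containers and plain-text I/O.

All on-disk formats are line-oriented text:

* expression TSV — header ``gene_id<TAB><subject>_<timepoint>...``, one row
  per gene, non-negative abundance values (TPM-like units);
* extended GMT — ``pathway_id<TAB>name|category<TAB>gene1<TAB>gene2...``,
  the pathway category embedded after ``|`` in the description field;
* PPI edge list — two-column TSV ``geneA<TAB>geneB``, undirected, no
  self-loops, deduplicated on read;
* seed lists — one gene id per line, the filename stem is the hypothesis
  name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("graftpath")

SampleKey = tuple[str, str]  # (subject, timepoint)


class GraftPathError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(GraftPathError):
    """Invalid simulation or pipeline configuration."""


class ConvergenceError(GraftPathError):
    """Iterative solver failed to reach the requested tolerance."""


class FormatError(GraftPathError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Genes × (subject, timepoint) abundance table.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene ids and
    whose columns form a two-level MultiIndex ``(subject, timepoint)``.
    Values are non-negative abundances in TPM-like units.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values.columns, pd.MultiIndex) or values.columns.nlevels != 2:
            raise ValueError("columns must be a (subject, timepoint) MultiIndex")
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if values.columns.duplicated().any():
            raise ValueError("duplicate (subject, timepoint) sample keys")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("expression values must not contain NaN")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        values = values.copy()
        values.columns = values.columns.set_names(["subject", "timepoint"])
        values.index = values.index.set_names("gene_id")
        self.values = values

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_keys(self) -> list[SampleKey]:
        return list(self.values.columns)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s, _ in self.values.columns:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def timepoints(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, t in self.values.columns:
            seen.setdefault(t, None)
        return list(seen)

    def sample(self, subject: str, timepoint: str) -> pd.Series:
        """Return the abundance vector of one (subject, timepoint) sample."""
        key = (subject, timepoint)
        if key not in self.values.columns:
            raise KeyError(f"unknown sample key {key!r}; have {list(self.values.columns)}")
        return self.values[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)

    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        for subject, timepoint in out.columns:
            if "_" in subject or "_" in timepoint:
                raise ValueError(
                    f"subject/timepoint labels must not contain '_': {(subject, timepoint)!r}"
                )
        out.columns = [f"{s}_{t}" for s, t in out.columns]
        # %.17g round-trips IEEE doubles exactly
        out.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str).str.strip()
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"{path}: duplicate gene id(s) {dupes[:5]}")
        keys = []
        for col in df.columns:
            if "_" not in col:
                raise FormatError(f"{path}: sample column {col!r} is not <subject>_<timepoint>")
            subject, timepoint = col.rsplit("_", 1)
            keys.append((subject, timepoint))
        df.columns = pd.MultiIndex.from_tuples(keys, names=["subject", "timepoint"])
        return cls(df)


# ---------------------------------------------------------------------------
# Pathway database
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty gene set")
        if not self.category:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty category")


class PathwayDB:
    """Pathway id → (name, category, member genes), insertion-ordered."""

    def __init__(self, pathways: Iterable[Pathway]):
        self._entries: dict[str, Pathway] = {}
        for p in pathways:
            if p.pathway_id in self._entries:
                raise ValueError(f"duplicate pathway id {p.pathway_id!r}")
            self._entries[p.pathway_id] = p

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._entries

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._entries[pathway_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDB):
            return NotImplemented
        return self._entries == other._entries

    @property
    def ids(self) -> list[str]:
        return list(self._entries)

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self:
            seen.setdefault(p.category, None)
        return list(seen)

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self:
            out |= p.genes
        return frozenset(out)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self:
                genes = "\t".join(sorted(p.genes))
                fh.write(f"{p.pathway_id}\t{p.name}|{p.category}\t{genes}\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "PathwayDB":
        pathways: list[Pathway] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                    )
                pathway_id = fields[0].strip()
                desc = fields[1]
                name, _, category = desc.rpartition("|")
                if not name:  # no '|' separator: whole field is the name
                    name, category = desc, "uncategorized"
                genes = frozenset(g.strip() for g in fields[2:] if g.strip())
                if not genes:
                    logger.warning("%s:%d: pathway %s has no genes; skipped", path, lineno, pathway_id)
                    continue
                pathways.append(Pathway(pathway_id, name, category, genes))
        return cls(pathways)


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------


def read_ppi_edgelist(path: str | Path) -> nx.Graph:
    """Read an undirected two-column edge list.

    Reversed duplicates collapse to one edge; self-loops are dropped and
    duplicate counts logged. Malformed lines raise with their line number.
    """
    g: nx.Graph = nx.Graph()
    n_dupes = 0
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty gene id")
            if a == b:
                n_loops += 1
                continue
            if g.has_edge(a, b):
                n_dupes += 1
                continue
            g.add_edge(a, b)
    if n_dupes:
        logger.warning("%s: %d duplicate edge(s) collapsed", path, n_dupes)
    if n_loops:
        logger.warning("%s: %d self-loop(s) dropped", path, n_loops)
    return g


def write_ppi_edgelist(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Hypothesis seed lists
# ---------------------------------------------------------------------------


def read_seed_lists(directory: str | Path) -> dict[str, frozenset[str]]:
    """Read every ``*.txt`` file in *directory* as one hypothesis seed set."""
    directory = Path(directory)
    out: dict[str, frozenset[str]] = {}
    for path in sorted(directory.glob("*.txt")):
        genes = frozenset(
            line.strip() for line in path.read_text().splitlines() if line.strip()
        )
        if not genes:
            logger.warning("%s: empty seed list; skipped", path)
            continue
        out[path.stem] = genes
    if not out:
        raise FormatError(f"{directory}: no non-empty seed lists found")
    return out


def write_seed_lists(seeds: Mapping[str, Iterable[str]], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, genes in seeds.items():
        (directory / f"{name}.txt").write_text("\n".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Pathway comparison results (activation-test output; TSV round-trip)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayComparisonResult:
    """Per-pathway one-sided activation test result for one comparison."""

    pathway_id: str
    comparison_label: str
    statistic: float
    direction: str  # "up" iff statistic > 0
    p_value: float
    n_genes_tested: int
    testable: bool = True

    def __post_init__(self) -> None:
        if self.testable and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


def write_activity_tsv(
    results: Sequence[PathwayComparisonResult], db: PathwayDB, path: str | Path
) -> None:
    rows = []
    for r in results:
        p = db[r.pathway_id]
        rows.append(
            {
                "pathway_id": r.pathway_id,
                "name": p.name,
                "category": p.category,
                "comparison": r.comparison_label,
                "statistic": r.statistic,
                "direction": r.direction,
                "p_value": r.p_value,
                "n_genes_tested": r.n_genes_tested,
                "testable": r.testable,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_activity_tsv(path: str | Path) -> list[PathwayComparisonResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PathwayComparisonResult(
                pathway_id=str(row.pathway_id),
                comparison_label=str(row.comparison),
                statistic=float(row.statistic),
                direction=str(row.direction),
                p_value=float(row.p_value),
                n_genes_tested=int(row.n_genes_tested),
                testable=bool(row.testable),
            )
        )
    return out
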