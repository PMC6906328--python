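"""Graft-loss-period-related activated pathway (GLPAP) selection and
category enrichment.

A pathway is a GLPAP when it is up-regulated with p < alpha in *both*
comparisons: the graft-losing vs graft-maintaining timepoint within the
failing subject, and failing vs stable subject at the graft-losing
timepoint. Per-category enrichment of the GLPAP set is then scored with a
one-sided Fisher's exact test on the 2×2 table (GLPAP membership ×
category membership); categories are reported in ascending p order.
Raw p-values are reported (no multiplicity correction across categories).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

from .data import PathwayComparisonResult, PathwayDB, logger


@dataclass(frozen=True)
class GLPAPSet:
    """Pathways significant and up-regulated in both comparisons."""

    pathway_ids: frozenset[str]
    comparison_labels: tuple[str, str]
    alpha: float


@dataclass(frozen=True)
class CategoryContingency:
    """2×2 table for one category: GLPAP status × category membership."""

    category: str
    a: int  # GLPAPs in category
    b: int  # GLPAPs not in category
    c: int  # non-GLPAP pathways in category
    d: int  # non-GLPAP pathways not in category

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


@dataclass(frozen=True)
class CategoryEnrichmentResult:
    category: str
    p_value: float
    contingency: CategoryContingency


def select_glpaps(
    results_cmp1: Sequence[PathwayComparisonResult],
    results_cmp2: Sequence[PathwayComparisonResult],
    alpha: float = 0.05,
) -> GLPAPSet:
    """Intersect the up-regulated significant sets of the two comparisons.

    Significance is strict (``p_value < alpha``); a pathway flagged
    untestable in either comparison cannot be selected. The two result
    lists must cover the same pathways.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    ids1 = {r.pathway_id for r in results_cmp1}
    ids2 = {r.pathway_id for r in results_cmp2}
    if ids1 != ids2:
        raise ValueError(
            f"comparison result lists cover different pathways: "
            f"{sorted(ids1 ^ ids2)[:5]} ..."
        )

    def significant(results: Sequence[PathwayComparisonResult]) -> frozenset[str]:
        return frozenset(
            r.pathway_id
            for r in results
            if r.testable and r.direction == "up" and r.p_value < alpha
        )

    label1 = results_cmp1[0].comparison_label if results_cmp1 else ""
    label2 = results_cmp2[0].comparison_label if results_cmp2 else ""
    return GLPAPSet(
        pathway_ids=significant(results_cmp1) & significant(results_cmp2),
        comparison_labels=(label1, label2),
        alpha=alpha,
    )


def fisher_exact_one_sided(table: CategoryContingency) -> float:
    """One-sided (enrichment) Fisher's exact p for a 2×2 table.

    With margins fixed, the GLPAP count in the category follows a
    hypergeometric law; the p-value is the upper tail P(X >= a).
    """
    n_total = table.a + table.b + table.c + table.d
    n_glpap = table.a + table.b
    n_category = table.a + table.c
    return float(stats.hypergeom.sf(table.a - 1, n_total, n_category, n_glpap))


def enrich_categories(glpaps: GLPAPSet, db: PathwayDB) -> list[CategoryEnrichmentResult]:
    """Fisher enrichment of the GLPAP set in every category of *db*.

    Returns one result per distinct category, ascending by p-value with
    ties broken by category name. An empty GLPAP set yields all p = 1.
    """
    unknown = set(glpaps.pathway_ids) - set(db.ids)
    if unknown:
        raise ValueError(f"GLPAP ids not in pathway database: {sorted(unknown)[:5]}")
    if not glpaps.pathway_ids:
        logger.warning("empty GLPAP set: all category enrichment p-values are 1")
    n_total = len(db)
    n_glpap = len(glpaps.pathway_ids)
    results = []
    for category in db.categories:
        in_cat = {p.pathway_id for p in db if p.category == category}
        a = len(in_cat & glpaps.pathway_ids)
        b = n_glpap - a
        c = len(in_cat) - a
        d = n_total - a - b - c
        table = CategoryContingency(category, a, b, c, d)
        results.append(
            CategoryEnrichmentResult(category, fisher_exact_one_sided(table), table)
        )
    return sorted(results, key=lambda r: (r.p_value, r.category))


def write_glpap_tsv(glpaps: GLPAPSet, db: PathwayDB, path: str | Path) -> None:
    """Selected-pathway table: pathway_id, name, category."""
    rows = [
        {"pathway_id": p.pathway_id, "name": p.name, "category": p.category}
        for p in db
        if p.pathway_id in glpaps.pathway_ids
    ]
    pd.DataFrame(rows, columns=["pathway_id", "name", "category"]).to_csv(
        path, sep="\t", index=False
    )


def write_enrichment_tsv(
    results: Sequence[CategoryEnrichmentResult], path: str | Path
) -> None:
    """Per-category table in ascending p order, with the 2×2 counts."""
    rows = [
        {
            "category": r.category,
            "p_value": r.p_value,
            "glpap_in_category": r.contingency.a,
            "glpap_not_in_category": r.contingency.b,
            "other_in_category": r.contingency.c,
            "other_not_in_category": r.contingency.d,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "category",
            "p_value",
            "glpap_in_category",
            "glpap_not_in_category",
            "other_in_category",
            "other_not_in_category",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
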