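"""Per-pathway activation scoring.

Scores pathway up-regulation between two samples with a one-sided
competitive gene-set permutation test on the mean log2 fold change: the
observed mean log2FC over a pathway's genes is compared against means of
random same-size gene sets drawn from the filtered gene universe. This is
a transparent stand-in for black-box time-series pathway analysis tools:
downstream stages consume only the (statistic, direction, one-sided
p-value) contract.

Genes whose abundance falls below ``min_expression`` (default 1.0) in
either sample are removed before the fold change is computed, which guards
against extreme ratios between small numbers.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    PathwayComparisonResult,
    PathwayDB,
    SampleKey,
    logger,
)


def gene_log2fc(
    expr: ExpressionMatrix,
    sample_a: SampleKey,
    sample_b: SampleKey,
    min_expression: float = 1.0,
) -> pd.Series:
    """log2(a/b) per gene, after the low-expression filter.

    Genes with abundance below ``min_expression`` in *either* sample are
    absent from the result.
    """
    if min_expression < 0:
        raise ValueError("min_expression must be >= 0")
    a = expr.sample(*sample_a)
    b = expr.sample(*sample_b)
    keep = (a >= min_expression) & (b >= min_expression)
    a, b = a[keep], b[keep]
    if ((a <= 0) | (b <= 0)).any():
        raise ValueError(
            "zero abundance survived the filter (min_expression < 1 with zero values); "
            "log2 fold change undefined"
        )
    out = np.log2(a / b)
    out.name = f"log2fc[{sample_a[0]}_{sample_a[1]}/{sample_b[0]}_{sample_b[1]}]"
    return out


def _permutation_means(
    values: np.ndarray, k: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_permutations`` random k-subsets of *values* (no replacement)."""
    n = values.shape[0]
    if k > n:
        raise ValueError(f"subset size {k} exceeds universe size {n}")
    if k == n:
        return np.full(n_permutations, values.mean())
    # k smallest of a random key per row = uniform k-subset without replacement
    keys = rng.random((n_permutations, n))
    idx = np.argpartition(keys, k, axis=1)[:, :k]
    return values[idx].mean(axis=1)


def _perm_pvalue(observed: float, perm_means: np.ndarray) -> float:
    """One-sided (up) permutation p with the +1 validity correction."""
    n = perm_means.shape[0]
    return float((1 + np.count_nonzero(perm_means >= observed)) / (n + 1))


def pathway_activation_test(
    log2fc: pd.Series | Mapping[str, float],
    pathway_genes: Iterable[str],
    n_permutations: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    *,
    pathway_id: str = "",
    comparison_label: str = "",
) -> PathwayComparisonResult:
    """One-sided competitive permutation test for pathway up-regulation.

    The statistic is the mean log2FC over pathway genes present in the
    filtered map; the null draws equally sized gene sets from the whole map.
    ``p = (1 + #{permuted means >= observed}) / (n_permutations + 1)``, so p
    is never zero. A pathway with no gene in the map is returned flagged
    untestable rather than raising.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if not isinstance(log2fc, pd.Series):
        log2fc = pd.Series(log2fc)
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, (int, np.integer)) else rng_seed
    present = sorted(set(pathway_genes) & set(log2fc.index))
    if not present:
        return PathwayComparisonResult(
            pathway_id=pathway_id,
            comparison_label=comparison_label,
            statistic=float("nan"),
            direction="down",
            p_value=float("nan"),
            n_genes_tested=0,
            testable=False,
        )
    values = log2fc.to_numpy(dtype=float)
    observed = float(log2fc[present].mean())
    perm_means = _permutation_means(values, len(present), n_permutations, rng)
    return PathwayComparisonResult(
        pathway_id=pathway_id,
        comparison_label=comparison_label,
        statistic=observed,
        direction="up" if observed > 0 else "down",
        p_value=_perm_pvalue(observed, perm_means),
        n_genes_tested=len(present),
    )


def score_pathways(
    expr: ExpressionMatrix,
    db: PathwayDB,
    case: SampleKey,
    control: SampleKey,
    *,
    comparison_label: str | None = None,
    min_expression: float = 1.0,
    n_permutations: int = 1000,
    rng_seed: int | np.random.Generator = 0,
) -> list[PathwayComparisonResult]:
    """Activation test for every pathway in *db* for one comparison.

    Permutation draws are shared across pathways of the same size, which
    leaves each pathway's marginal null distribution unchanged.
    """
    label = comparison_label or (
        f"{case[0]}_{case[1]}_vs_{control[0]}_{control[1]}"
    )
    l2fc = gene_log2fc(expr, case, control, min_expression=min_expression)
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, (int, np.integer)) else rng_seed
    values = l2fc.to_numpy(dtype=float)
    gene_index = set(l2fc.index)
    sizes = sorted(
        {len(set(p.genes) & gene_index) for p in db if set(p.genes) & gene_index}
    )
    means_by_size = {
        k: _permutation_means(values, k, n_permutations, rng) for k in sizes
    }
    results: list[PathwayComparisonResult] = []
    n_untestable = 0
    for p in db:
        present = sorted(p.genes & gene_index)
        if not present:
            n_untestable += 1
            results.append(
                PathwayComparisonResult(
                    pathway_id=p.pathway_id,
                    comparison_label=label,
                    statistic=float("nan"),
                    direction="down",
                    p_value=float("nan"),
                    n_genes_tested=0,
                    testable=False,
                )
            )
            continue
        observed = float(l2fc[present].mean())
        results.append(
            PathwayComparisonResult(
                pathway_id=p.pathway_id,
                comparison_label=label,
                statistic=observed,
                direction="up" if observed > 0 else "down",
                p_value=_perm_pvalue(observed, means_by_size[len(present)]),
                n_genes_tested=len(present),
            )
        )
    if n_untestable:
        logger.warning(
            "%s: %d pathway(s) had no gene surviving the filter; flagged untestable",
            label,
            n_untestable,
        )
    return results
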