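"""Hypothesis evaluation by network propagation.

Each etiological hypothesis is represented by a small seed-gene set.
Random walk with restart (RWR) diffuses seed influence over the PPI
network:

    s ← (1 − r) · W · s + r · s0

with restart probability ``r``, ``s0`` uniform over the seeds, and ``W``
the degree-normalized adjacency (symmetric ``D^-1/2 A D^-1/2`` by default,
column-stochastic ``A D^-1`` available). The stationary scores rank every
network gene by how strongly the hypothesis "reaches" it; that ranking is
compared with the measured differential-expression ranking (log2FC between
the failing and stable subject at the graft-losing timepoint, low-abundance
genes removed) by Pearson correlation of the two rank vectors — i.e.
Spearman correlation. Significance of the observed coefficient is assessed
against random seed sets of the same size:

    p = (1/N) · #{ j : c_j > c_ref }

the literal empirical p with strict ``>`` and no pseudocount (a
pseudocounted variant is available via ``corrected=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .data import ConvergenceError, ExpressionMatrix, SampleKey, logger
from .activity import gene_log2fc


# ---------------------------------------------------------------------------
# DEG profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DEGProfile:
    """Per-gene log2 fold change and descending rank (1 = highest)."""

    log2fc: pd.Series
    ranks: pd.Series
    rank_by: str = "signed"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2fc.index)


def build_deg_profile(
    expr: ExpressionMatrix,
    case: SampleKey,
    control: SampleKey,
    min_expression: float = 1.0,
    rank_by: str = "signed",
) -> DEGProfile:
    """Differential-expression profile between two samples.

    Ranks descend by signed log2FC by default (rank 1 = most up-regulated);
    ``rank_by="absolute"`` ranks by magnitude instead. Ties receive
    mid-ranks.
    """
    if rank_by not in ("signed", "absolute"):
        raise ValueError("rank_by must be 'signed' or 'absolute'")
    l2fc = gene_log2fc(expr, case, control, min_expression=min_expression)
    if l2fc.empty:
        raise ValueError("no gene survived the expression filter; cannot rank")
    key = l2fc.abs() if rank_by == "absolute" else l2fc
    ranks = pd.Series(
        stats.rankdata(-key.to_numpy()), index=l2fc.index, name="rank"
    )
    return DEGProfile(log2fc=l2fc, ranks=ranks, rank_by=rank_by)


# ---------------------------------------------------------------------------
# Random walk with restart
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropagationResult:
    """Stationary RWR scores and their descending ranks (1 = most influenced)."""

    scores: pd.Series
    ranks: pd.Series
    parameters: dict = field(default_factory=dict)


class RWROperator:
    """Precomputed normalized adjacency for repeated propagation runs."""

    def __init__(
        self,
        ppi: nx.Graph,
        restart_prob: float = 0.5,
        tol: float = 1e-10,
        max_iter: int = 10000,
        normalization: str = "symmetric",
    ):
        if not (0.0 < restart_prob < 1.0):
            raise ValueError("restart_prob must be in (0, 1)")
        if normalization not in ("symmetric", "column"):
            raise ValueError("normalization must be 'symmetric' or 'column'")
        if ppi.number_of_nodes() == 0:
            raise ValueError("PPI network is empty")
        self.nodes: list[str] = sorted(ppi.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.restart_prob = restart_prob
        self.tol = tol
        self.max_iter = max_iter
        self.normalization = normalization
        adj = nx.to_scipy_sparse_array(ppi, nodelist=self.nodes, dtype=float, format="csr")
        deg = np.asarray(adj.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            if normalization == "symmetric":
                inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
                self.w = sparse.diags(inv_sqrt) @ adj @ sparse.diags(inv_sqrt)
            else:  # column-stochastic: W[i, j] = A[i, j] / deg[j]
                inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
                self.w = adj @ sparse.diags(inv)
        self.w = self.w.tocsr()

    def restart_vector(self, seeds: Iterable[str]) -> np.ndarray:
        idx = [self.index[s] for s in seeds]
        if not idx:
            raise ValueError("no seed maps to the network")
        s0 = np.zeros(len(self.nodes))
        s0[idx] = 1.0 / len(idx)
        return s0

    def run(self, seeds: Iterable[str]) -> np.ndarray:
        """Iterate to the stationary score vector; raises on non-convergence."""
        s0 = self.restart_vector(seeds)
        r = self.restart_prob
        s = s0.copy()
        for _ in range(self.max_iter):
            s_next = (1.0 - r) * (self.w @ s) + r * s0
            delta = float(np.abs(s_next - s).sum())
            s = s_next
            if delta < self.tol:
                return s
        raise ConvergenceError(
            f"RWR did not converge in {self.max_iter} iterations (L1 residual {delta:.3e})"
        )


def propagate(
    ppi: nx.Graph,
    seeds: Iterable[str],
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10000,
    normalization: str = "symmetric",
    *,
    operator: RWROperator | None = None,
) -> PropagationResult:
    """Random walk with restart from a seed set.

    Seeds absent from the network are dropped with a warning; an error is
    raised only when none remain. The fixed point satisfies
    ``s = r (I − (1−r) W)^{-1} s0``.
    """
    op = operator or RWROperator(ppi, restart_prob, tol, max_iter, normalization)
    seeds = set(seeds)
    mapped = sorted(seeds & set(op.index))
    dropped = sorted(seeds - set(op.index))
    if dropped:
        logger.warning("%d seed(s) not in the network; dropped: %s", len(dropped), dropped[:5])
    if not mapped:
        raise ValueError("no seed gene maps to the PPI network")
    scores_arr = op.run(mapped)
    scores = pd.Series(scores_arr, index=pd.Index(op.nodes, name="gene_id"), name="score")
    ranks = pd.Series(stats.rankdata(-scores_arr), index=scores.index, name="rank")
    return PropagationResult(
        scores=scores,
        ranks=ranks,
        parameters={
            "restart_prob": op.restart_prob,
            "tol": op.tol,
            "max_iter": op.max_iter,
            "normalization": op.normalization,
            "n_seeds_used": len(mapped),
        },
    )


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------


def _common_genes(prop: PropagationResult, deg: DEGProfile) -> list[str]:
    return sorted(set(prop.scores.index) & set(deg.log2fc.index))


def _rank_corr(x_ranks: np.ndarray, y_ranks: np.ndarray) -> tuple[float, float]:
    if np.ptp(x_ranks) == 0 or np.ptp(y_ranks) == 0:
        raise ValueError("constant rank vector: correlation undefined")
    res = stats.pearsonr(x_ranks, y_ranks)
    return float(res.statistic), float(res.pvalue)


def rank_correlation(prop: PropagationResult, deg: DEGProfile) -> tuple[float, float]:
    """Pearson correlation of the two rank vectors (= Spearman on scores).

    Restricted to genes present in both the propagation result and the DEG
    profile, re-ranked within that intersection; the parametric p comes
    from the t-distribution.
    """
    common = _common_genes(prop, deg)
    if len(common) < 3:
        raise ValueError(f"need >= 3 genes in common, got {len(common)}")
    x = stats.rankdata(prop.ranks[common].to_numpy())
    y = stats.rankdata(deg.ranks[common].to_numpy())
    return _rank_corr(x, y)


def top_k_correlation(
    prop: PropagationResult, deg: DEGProfile, k: int
) -> tuple[float, float]:
    """Rank correlation restricted to the k most-influenced common genes.

    Genes are ordered by propagation rank with ties broken by gene id; the
    two rank vectors are re-ranked within the selected k.
    """
    common = _common_genes(prop, deg)
    if k > len(common):
        raise ValueError(f"k={k} exceeds the {len(common)} genes in common")
    ordered = sorted(common, key=lambda g: (prop.ranks[g], g))
    top = ordered[:k]
    x = stats.rankdata(prop.ranks[top].to_numpy())
    y = stats.rankdata(deg.ranks[top].to_numpy())
    return _rank_corr(x, y)


# ---------------------------------------------------------------------------
# Empirical null
# ---------------------------------------------------------------------------


def empirical_p(random_coefficients: Sequence[float], reference: float, corrected: bool = False) -> float:
    """Fraction of random coefficients strictly exceeding the reference.

    ``corrected=True`` applies the (1 + b) / (N + 1) pseudocount variant,
    which can never return zero.
    """
    c = np.asarray(random_coefficients, dtype=float)
    n = c.shape[0]
    if n < 1:
        raise ValueError("need at least one random coefficient")
    b = int(np.count_nonzero(c > reference))
    if corrected:
        return float((1 + b) / (n + 1))
    return float(b / n)


def _sample_seeds_uniform(
    nodes: Sequence[str], size: int, rng: np.random.Generator
) -> list[str]:
    idx = rng.choice(len(nodes), size=size, replace=False)
    return [nodes[i] for i in idx]


def _sample_seeds_degree_matched(
    nodes: Sequence[str],
    degrees: Mapping[str, int],
    reference_seeds: Sequence[str],
    rng: np.random.Generator,
) -> list[str]:
    """One random node per reference seed from the same log2-degree bin.

    Falls back to the nearest non-empty bin (warning logged) when a bin has
    no unused node left.
    """
    bins: dict[int, list[str]] = {}
    for n in nodes:
        bins.setdefault(int(np.log2(max(degrees[n], 1))), []).append(n)
    chosen: list[str] = []
    used: set[str] = set()
    for seed in sorted(reference_seeds):
        want = int(np.log2(max(degrees.get(seed, 1), 1)))
        offsets = sorted(set(bins), key=lambda b: (abs(b - want), b))
        picked = None
        for off_i, b in enumerate(offsets):
            avail = [n for n in bins[b] if n not in used]
            if avail:
                if off_i > 0:
                    logger.warning(
                        "degree bin %d exhausted; fell back to bin %d", want, b
                    )
                picked = avail[int(rng.integers(len(avail)))]
                break
        if picked is None:
            raise ValueError("degree-matched sampler exhausted every bin")
        chosen.append(picked)
        used.add(picked)
    return chosen


def empirical_pvalue(
    ppi: nx.Graph,
    deg: DEGProfile,
    seed_size: int,
    reference_coeff: float,
    n_sim: int = 1000,
    sampler: str = "uniform",
    rng_seed: int | np.random.Generator = 0,
    k: int | None = None,
    *,
    reference_seeds: Sequence[str] | None = None,
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10000,
    normalization: str = "symmetric",
    corrected: bool = False,
    operator: RWROperator | None = None,
) -> tuple[float, np.ndarray]:
    """Empirical p for an observed coefficient against random seed sets.

    Draws ``n_sim`` random seed sets of ``seed_size`` genes, recomputes the
    (top-k if ``k`` is given) rank-correlation coefficient for each, and
    returns ``(p, random_coefficients)`` with
    ``p = (1/n_sim)·#{c_j > reference}``. Deterministic for a fixed
    ``rng_seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if seed_size < 1:
        raise ValueError("seed_size must be >= 1")
    if sampler not in ("uniform", "degree_matched"):
        raise ValueError("sampler must be 'uniform' or 'degree_matched'")
    if sampler == "degree_matched" and reference_seeds is None:
        raise ValueError("degree_matched sampler requires reference_seeds")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, (int, np.integer)) else rng_seed
    op = operator or RWROperator(ppi, restart_prob, tol, max_iter, normalization)
    nodes = op.nodes
    degrees = dict(ppi.degree)
    coeffs = np.empty(n_sim)
    for j in range(n_sim):
        if sampler == "uniform":
            seeds = _sample_seeds_uniform(nodes, seed_size, rng)
        else:
            seeds = _sample_seeds_degree_matched(nodes, degrees, reference_seeds, rng)
        prop = propagate(ppi, seeds, operator=op)
        if k is None:
            coeffs[j], _ = rank_correlation(prop, deg)
        else:
            coeffs[j], _ = top_k_correlation(prop, deg, k)
    return empirical_p(coeffs, reference_coeff, corrected=corrected), coeffs


# ---------------------------------------------------------------------------
# Hypothesis evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HypothesisEvalResult:
    """Evaluation of one etiological hypothesis."""

    name: str
    n_seeds: int
    coefficient: float
    parametric_p: float
    empirical_p: float | None
    n_sim: int
    random_coefficients: tuple[float, ...]
    top_k: int | None = None
    top_k_coefficient: float | None = None
    top_k_parametric_p: float | None = None


def evaluate_hypotheses(
    ppi: nx.Graph,
    deg: DEGProfile,
    hypotheses: Mapping[str, Iterable[str]],
    *,
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10000,
    normalization: str = "symmetric",
    n_sim: int = 1000,
    sampler: str = "uniform",
    top_k: int | None = None,
    rng_seed: int = 0,
    corrected: bool = False,
) -> list[HypothesisEvalResult]:
    """Propagate, correlate and null-test every hypothesis.

    Returns one result per hypothesis, sorted by descending coefficient.
    ``n_sim=0`` skips the empirical null (``empirical_p`` is None). Each
    hypothesis gets an independent RNG stream derived from ``rng_seed``, so
    results do not depend on evaluation order.
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis")
    op = RWROperator(ppi, restart_prob, tol, max_iter, normalization)
    names = sorted(hypotheses)
    children = np.random.SeedSequence(rng_seed).spawn(len(names))
    results: list[HypothesisEvalResult] = []
    for name, child in zip(names, children):
        seeds = set(hypotheses[name])
        prop = propagate(ppi, seeds, operator=op)
        coeff, par_p = rank_correlation(prop, deg)
        top_coeff = top_p = None
        if top_k is not None:
            top_coeff, top_p = top_k_correlation(prop, deg, top_k)
        emp_p: float | None = None
        rand_coeffs: tuple[float, ...] = ()
        n_used = prop.parameters["n_seeds_used"]
        if n_sim > 0:
            emp_p, coeffs = empirical_pvalue(
                ppi,
                deg,
                seed_size=n_used,
                reference_coeff=coeff,
                n_sim=n_sim,
                sampler=sampler,
                rng_seed=np.random.default_rng(child),
                reference_seeds=sorted(seeds),
                corrected=corrected,
                operator=op,
            )
            rand_coeffs = tuple(float(c) for c in coeffs)
        results.append(
            HypothesisEvalResult(
                name=name,
                n_seeds=n_used,
                coefficient=coeff,
                parametric_p=par_p,
                empirical_p=emp_p,
                n_sim=n_sim,
                random_coefficients=rand_coeffs,
                top_k=top_k,
                top_k_coefficient=top_coeff,
                top_k_parametric_p=top_p,
            )
        )
    return sorted(results, key=lambda r: -r.coefficient)


def write_hypothesis_tsv(results: Sequence[HypothesisEvalResult], path) -> None:
    """Per-hypothesis table: coefficient, parametric and empirical p."""
    rows = [
        {
            "hypothesis": r.name,
            "n_seeds": r.n_seeds,
            "coefficient": r.coefficient,
            "p_value": r.parametric_p,
            "empirical_p": "" if r.empirical_p is None else r.empirical_p,
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["hypothesis", "n_seeds", "coefficient", "p_value", "empirical_p"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_topk_tsv(results: Sequence[HypothesisEvalResult], path) -> None:
    """Top-k variant table (only meaningful when top_k was requested)."""
    rows = [
        {
            "hypothesis": r.name,
            "top_k": r.top_k,
            "coefficient": r.top_k_coefficient,
            "p_value": r.top_k_parametric_p,
        }
        for r in sorted(results, key=lambda r: -(r.top_k_coefficient or 0.0))
        if r.top_k is not None
    ]
    pd.DataFrame(rows, columns=["hypothesis", "top_k", "coefficient", "p_value"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
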