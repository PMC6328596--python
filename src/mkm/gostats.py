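"""Tail enrichment of GO categories in GWAS results, with Storey FDR.

Each gene is scored by the smallest SNP p-value within its body plus a
flanking window; the genes in the extreme tail of that score
distribution (top 1% by default) are tested for over-representation of
every GO category with a hypergeometric test.  Multiple testing is
handled with Storey's q-values: the null proportion pi0 is estimated on
a lambda grid with cubic-spline smoothing, and q-values are monotonized
BH-style.  With pi0 = 1 the q-values reduce exactly to
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .quantgen import GwasResult

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentGO", "gene_scores", "storey_qvalues",
           "go_tail_enrichment"]


@dataclass
class EnrichmentGO:
    category: str
    n_annotated: int        # scored genes carrying the category
    observed: int           # category genes in the tail
    expected: float
    ratio: float            # observed / expected
    p: float
    q: float = np.nan


def gene_scores(res: GwasResult, genes: pd.DataFrame,
                window_bp: int = 10_000) -> pd.Series:
    """Per-gene score: min SNP p within [start - w, end + w].

    ``genes`` needs columns gene_id, chrom, start, end (1-based
    inclusive).  Genes without any SNP in range are omitted.
    """
    tab = res.table.dropna(subset=["p"])
    scores = {}
    by_chrom = {c: g.sort_values("pos") for c, g in tab.groupby("chrom")}
    for row in genes.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start - window_bp, side="left")
        hi = np.searchsorted(pos, row.end + window_bp, side="right")
        if hi > lo:
            scores[row.gene_id] = float(sub["p"].to_numpy()[lo:hi].min())
    if not scores:
        raise ValueError("no gene overlapped any SNP")
    return pd.Series(scores, name="score")


def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None,
                   pi0: float | None = None) -> np.ndarray:
    """Storey q-values with spline-smoothed pi0 estimation.

    pi0 is estimated as the spline-smoothed value of
    #{p > lambda} / (m (1 - lambda)) at the largest lambda of the grid
    (0.05, 0.10, ..., 0.95), clipped to (0, 1].  Passing ``pi0=1``
    reproduces Benjamini-Hochberg exactly.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_lambda = np.array([
            np.mean(p > lam) / (1.0 - lam) for lam in lambdas
        ])
        if m < 100 or np.all(pi0_lambda == 0):
            pi0 = min(1.0, float(pi0_lambda[0])) if m else 1.0
        else:
            try:
                spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
                pi0 = float(spline(lambdas[-1]))
            except Exception:  # degenerate grids
                pi0 = float(pi0_lambda[-1])
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # monotonize from the largest p downwards
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def go_tail_enrichment(
    res: GwasResult,
    genes: pd.DataFrame,
    go_map: pd.DataFrame,
    tail_fraction: float = 0.01,
    window_bp: int = 10_000,
    min_category_size: int = 2,
) -> pd.DataFrame:
    """Hypergeometric tail enrichment of GO categories, Storey-corrected.

    The tail is the ceil(tail_fraction * N) genes with the smallest
    scores among the N scored genes.  For a category with K scored
    genes, of which k fall in the tail of size n:

        expected = n K / N,  ratio = k / expected,
        p = P[X >= k],  X ~ Hypergeometric(N, K, n).

    Categories annotating fewer than ``min_category_size`` scored genes
    are excluded with a log entry.
    """
    scores = gene_scores(res, genes, window_bp)
    N = len(scores)
    n_tail = math.ceil(tail_fraction * N)
    tail = set(scores.nsmallest(n_tail).index)
    annotated = go_map[go_map["gene_id"].isin(scores.index)]
    rows = []
    for cat, group in annotated.groupby("go_id"):
        members = set(group["gene_id"])
        K = len(members)
        if K < min_category_size:
            logger.info("skipping GO %s with %d scored gene(s)", cat, K)
            continue
        k = len(members & tail)
        expected = n_tail * K / N
        p = float(stats.hypergeom.sf(k - 1, N, K, n_tail))
        rows.append(EnrichmentGO(category=cat, n_annotated=K, observed=k,
                                 expected=expected,
                                 ratio=k / expected if expected > 0 else np.nan,
                                 p=p))
    if not rows:
        return pd.DataFrame(columns=["category", "n_annotated", "observed",
                                     "expected", "ratio", "p", "q"])
    frame = pd.DataFrame([r.__dict__ for r in rows])
    frame["q"] = storey_qvalues(frame["p"].to_numpy())
    return frame.sort_values("p").reset_index(drop=True)
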