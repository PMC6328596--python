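"""Do replicates of the same inbred accession cluster in ordination space?

The analysis scans nested abundance subsets of the bacterial and fungal
communities (top 1%, 2%, ..., 100% best-sequenced taxa), alone and
column-combined.  For each subset: counts are scaled to a common depth
and log1p-transformed, each taxon is residualized on block and run (the
technical covariates), a unit-variance PCA is taken, and the factor fit
of the accession labels to the leading PC scores is measured as

    R2 = 1 - SS(within accession) / SS(total)

over the first ``n_pcs`` score columns jointly.  Significance comes from
permuting accession labels across samples: p = (#{R2perm >= R2obs} + 1)
/ (n_perm + 1), floored at 1/(n_perm + 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleMetadata
from .glmm import design_matrix
from .ordination import pca

logger = logging.getLogger(__name__)

__all__ = ["GridResult", "nested_subsets", "sample_scores",
           "accession_fit_stat", "permutation_p", "grid_scan"]

DEFAULT_FRACTIONS = (0.01, 0.02, 0.03, 0.04, 0.05, 0.10, 0.25, 0.50, 1.00)


@dataclass
class GridResult:
    """Permutation p-values over (bacterial x fungal) subset fractions."""

    cells: pd.DataFrame            # rows: bacteria fraction, cols: fungi fraction
    margin_bacteria: pd.Series     # fraction -> p (single-kingdom)
    margin_fungi: pd.Series
    n_pcs: int
    n_perm: int
    seed: int | None


def nested_subsets(table: CountTable, fractions) -> list[CountTable]:
    """Top ceil(f * T) best-sequenced taxa for each fraction f.

    Subsets are nested: the taxa of a smaller fraction are contained in
    every larger one.  Ties in total reads break lexicographically.
    """
    fractions = list(fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    totals = table.taxon_totals()
    order = sorted(table.taxon_ids, key=lambda t: (-totals[t], t))
    out = []
    for f in fractions:
        n = math.ceil(f * table.n_taxa)
        out.append(table.select_taxa(order[:n]))
    return out


def _transform_counts(
    counts: pd.DataFrame, totals: pd.Series, depth_ref: float,
    transform: str = "log1p-scaled",
) -> np.ndarray:
    """Depth-normalize sample-level counts before ordination."""
    scaled = counts.to_numpy(dtype=float) * (
        depth_ref / totals.to_numpy(dtype=float)
    )[:, None]
    if transform == "log1p-scaled":
        return np.log1p(scaled)
    if transform == "raw-scaled":
        return scaled
    raise ValueError("transform must be 'log1p-scaled' or 'raw-scaled'")


def _residualize(X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of each column of X on the covariate design."""
    coef, *_ = np.linalg.lstsq(covariates, X, rcond=None)
    return X - covariates @ coef


def sample_scores(
    table: CountTable,
    meta: SampleMetadata,
    n_pcs: int,
    depth_ref: float = 400.0,
    transform: str = "log1p-scaled",
) -> pd.DataFrame:
    """Covariate-adjusted sample-level PCA scores of a count subset.

    Counts are scaled to ``depth_ref`` and transformed, each taxon is
    residualized on block + run, then a centered unit-variance PCA is
    taken.  Returns the first ``n_pcs`` score columns.
    """
    frame = meta.frame.loc[table.sample_ids]
    frame = frame[frame["total_reads"] > 0]
    counts = table.counts.loc[frame.index]
    X = _transform_counts(counts, frame["total_reads"], depth_ref, transform)
    factors = [f for f in ("block", "run") if frame[f].nunique() > 1]
    if factors:
        C, _ = design_matrix(frame, factors)
        X = _residualize(X, C)
    res = pca(pd.DataFrame(X, index=frame.index), scale=True, drop_tol=1e-12)
    k = min(n_pcs, res.scores.shape[1])
    return res.scores.iloc[:, :k]


def accession_fit_stat(scores: pd.DataFrame | np.ndarray,
                       labels: pd.Series | np.ndarray) -> float:
    """Factor fit of accession labels to ordination scores.

    R2 = 1 - SS_within / SS_total, with sums of squared Euclidean
    deviations taken jointly over all score columns: 1 when replicates
    coincide within accession, ~(k-1)/(n-1) in expectation under random
    labels.  Degenerate when every accession is a singleton (R2 = 1).
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    lab = np.asarray(labels)
    if len(lab) != S.shape[0]:
        raise ValueError("labels must match score rows")
    levels, codes = np.unique(lab, return_inverse=True)
    if len(levels) == len(lab):
        logger.warning("every accession is a singleton: R2 = 1 degenerate")
    centered = S - S.mean(axis=0)
    ss_total = float(np.sum(centered**2))
    if ss_total == 0:
        return 0.0
    n_g = np.bincount(codes).astype(float)
    ss_between = 0.0
    for j in range(S.shape[1]):
        sums = np.bincount(codes, weights=centered[:, j])
        ss_between += float(np.sum(sums**2 / n_g))
    return ss_between / ss_total


def permutation_p(
    scores: pd.DataFrame | np.ndarray,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation p-value for the accession factor fit.

    Returns (observed R2, p) with p = (#{R2perm >= R2obs} + 1)/(n_perm+1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    lab = np.asarray(labels)
    levels, codes = np.unique(lab, return_inverse=True)
    centered = S - S.mean(axis=0)
    ss_total = float(np.sum(centered**2))
    n_g = np.bincount(codes).astype(float)

    def stat(c: np.ndarray) -> float:
        ss_between = 0.0
        for j in range(S.shape[1]):
            sums = np.bincount(c, weights=centered[:, j], minlength=len(levels))
            ss_between += float(np.sum(sums**2 / n_g))
        return ss_between / ss_total

    r2_obs = stat(codes)
    n_ge = 0
    for _ in range(n_perm):
        if stat(rng.permutation(codes)) >= r2_obs:
            n_ge += 1
    return r2_obs, (n_ge + 1) / (n_perm + 1)


def grid_scan(
    bact: CountTable,
    fung: CountTable,
    meta: SampleMetadata | dict[str, SampleMetadata],
    fractions=DEFAULT_FRACTIONS,
    n_pcs: int = 3,
    n_perm: int = 999,
    seed: int | None = None,
    depth_ref: float = 400.0,
    transform: str = "log1p-scaled",
    min_taxa: int = 3,
) -> GridResult:
    """Permutation grid over nested subsets of both kingdoms.

    Margins hold single-kingdom p-values per fraction; cells hold the
    p-value for the column-combined community at each (bacterial
    fraction, fungal fraction) pair.  Cells with fewer than ``min_taxa``
    retained taxa are NaN.
    """
    rng = np.random.default_rng(seed)
    meta_b = meta["bacteria"] if isinstance(meta, dict) else meta
    meta_f = meta["fungi"] if isinstance(meta, dict) else meta
    shared = [s for s in bact.sample_ids if s in set(fung.sample_ids)]
    if not shared:
        raise ValueError("no shared samples across kingdoms")
    bact = bact.select_samples(shared)
    fung = fung.select_samples(shared)
    subs_b = nested_subsets(bact, fractions)
    subs_f = nested_subsets(fung, fractions)
    labels = meta_b.frame.loc[shared, "accession_id"]

    def margin(subsets, m) -> pd.Series:
        out = {}
        for f, sub in zip(fractions, subsets):
            if sub.n_taxa < min_taxa:
                out[f] = np.nan
                continue
            scores = sample_scores(sub, m, n_pcs, depth_ref, transform)
            _, p = permutation_p(scores, labels.loc[scores.index],
                                 n_perm=n_perm, rng=rng)
            out[f] = p
        return pd.Series(out, name="p")

    margin_b = margin(subs_b, meta_b)
    margin_f = margin(subs_f, meta_f)

    # pre-transform per kingdom once (transform + residualize are
    # column-separable, so subsetting commutes with them)
    cells = pd.DataFrame(index=pd.Index(fractions, name="bacteria_fraction"),
                         columns=pd.Index(fractions, name="fungi_fraction"),
                         dtype=float)
    for fb, sb in zip(fractions, subs_b):
        for ff, sf in zip(fractions, subs_f):
            if sb.n_taxa + sf.n_taxa < min_taxa:
                cells.loc[fb, ff] = np.nan
                continue
            Xb = _transform_counts(sb.counts.loc[shared],
                                   meta_b.frame.loc[shared, "total_reads"],
                                   depth_ref, transform)
            Xf = _transform_counts(sf.counts.loc[shared],
                                   meta_f.frame.loc[shared, "total_reads"],
                                   depth_ref, transform)
            X = np.column_stack([Xb, Xf])
            frames = []
            for m, ncols in ((meta_b, Xb.shape[1]), (meta_f, Xf.shape[1])):
                fr = m.frame.loc[shared]
                factors = [f for f in ("block", "run") if fr[f].nunique() > 1]
                if factors:
                    frames.append((design_matrix(fr, factors)[0], ncols))
                else:
                    frames.append((None, ncols))
            start = 0
            for C, ncols in frames:
                if C is not None:
                    X[:, start:start + ncols] = _residualize(
                        X[:, start:start + ncols], C)
                start += ncols
            sd = X.std(axis=0)
            X = X[:, sd > 1e-12]
            if X.shape[1] < min_taxa:
                cells.loc[fb, ff] = np.nan
                continue
            res = pca(pd.DataFrame(X, index=shared), scale=True,
                      drop_tol=1e-12)
            k = min(n_pcs, res.scores.shape[1])
            _, p = permutation_p(res.scores.iloc[:, :k], labels,
                                 n_perm=n_perm, rng=rng)
            cells.loc[fb, ff] = p
    return GridResult(cells=cells, margin_bacteria=margin_b,
                      margin_fungi=margin_f, n_pcs=n_pcs, n_perm=n_perm,
                      seed=seed)
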