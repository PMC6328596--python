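"""BLUP-based ordination of accession-level community composition.

Each of the best-sequenced taxa is modelled with a Poisson GLMM (block
and run fixed effects, log-depth offset, accession random intercept);
the accession conditional modes (BLUPs) form an accessions x taxa matrix
whose PCA summarizes host-genotype-level community structure.  Marginal
(per-kingdom) and combined (column-concatenated) ordinations are
compared by PC-PC correlations and by a symmetric Procrustes rotation
test with a permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleMetadata
from .filters import top_taxa
from .glmm import GLMMConvergenceError, design_matrix, fit_poisson_glmm

logger = logging.getLogger(__name__)

__all__ = ["BlupMatrix", "PcaResult", "abundance_blups", "pca",
           "combine_kingdoms", "pc_correlation", "procrustes_statistic",
           "procrustes_test"]


@dataclass
class BlupMatrix:
    """Accessions x taxa matrix of GLMM conditional modes."""

    values: pd.DataFrame               # accessions x taxa
    kingdom: pd.Series                 # taxon -> kingdom
    sigma2: pd.Series                  # per-taxon accession variance
    failed_taxa: list[str] = field(default_factory=list)

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PcaResult:
    scores: pd.DataFrame               # rows x PCs ("PC1", ...)
    loadings: pd.DataFrame             # variables x PCs, orthonormal columns
    explained_fraction: np.ndarray


def abundance_blups(
    table: CountTable,
    meta: SampleMetadata,
    top_n: int | None = None,
    max_failed_fraction: float = 0.01,
) -> BlupMatrix:
    """Per-taxon Poisson GLMM BLUPs for the ``top_n`` best-sequenced taxa.

    Model per taxon: count ~ block + run (+ organ) + offset(log reads)
    + (1 | accession).  Taxa whose fit fails are zero-imputed when rare
    (< ``max_failed_fraction`` of columns), otherwise excluded.
    """
    if top_n is not None:
        table = top_taxa(table, top_n)
    frame = meta.frame.loc[table.sample_ids]
    frame = frame[frame["total_reads"] > 0]
    factors = [f for f in ("block", "run", "organ") if frame[f].nunique() > 1]
    X, names = design_matrix(frame, factors)
    offset = np.log(frame["total_reads"].to_numpy(dtype=float))
    groups = frame["accession_id"]
    accessions = sorted(groups.unique())

    cols: dict[str, pd.Series] = {}
    sigma2: dict[str, float] = {}
    failed: list[str] = []
    for taxon in table.taxon_ids:
        y = table.counts.loc[frame.index, taxon].to_numpy()
        try:
            fit = fit_poisson_glmm(y, X, groups, offset=offset, coef_names=names)
            cols[taxon] = fit.blups.reindex(accessions)
            sigma2[taxon] = fit.sigma2_group
        except (GLMMConvergenceError, np.linalg.LinAlgError):
            failed.append(taxon)
    if failed:
        logger.warning("GLMM failed for %d taxa: %s", len(failed), failed[:5])
    values = pd.DataFrame(cols, index=accessions)
    if failed and len(failed) <= max_failed_fraction * table.n_taxa:
        for taxon in failed:
            values[taxon] = 0.0
            sigma2[taxon] = np.nan
        values = values[table.taxon_ids]
    return BlupMatrix(
        values=values,
        kingdom=table.kingdom.reindex(values.columns),
        sigma2=pd.Series(sigma2).reindex(values.columns),
        failed_taxa=failed,
    )


def pca(matrix, scale: bool = True, drop_tol: float = 0.0) -> PcaResult:
    """PCA of a (centered, optionally unit-variance-scaled) matrix.

    Accepts a :class:`BlupMatrix` or a DataFrame.  Zero-variance columns
    are dropped with a warning before scaling.  Each loading column's
    largest-magnitude entry is made positive so signs are reproducible.
    """
    frame = matrix.values if isinstance(matrix, BlupMatrix) else matrix
    frame = pd.DataFrame(frame)
    sd = frame.std(axis=0, ddof=1)
    keep = sd.index[sd > drop_tol]
    if len(keep) < frame.shape[1]:
        logger.warning("pca: dropping %d zero-variance column(s)",
                       frame.shape[1] - len(keep))
    if len(keep) == 0:
        raise ValueError("all columns constant: PCA undefined")
    X = frame[keep].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(X.shape)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    names = [f"PC{j + 1}" for j in range(k)]
    explained = s**2 / np.sum(s**2) if s.size else s
    return PcaResult(
        scores=pd.DataFrame(U * s, index=frame.index, columns=names),
        loadings=pd.DataFrame(Vt.T, index=keep, columns=names),
        explained_fraction=explained,
    )


def combine_kingdoms(b1: BlupMatrix, b2: BlupMatrix) -> BlupMatrix:
    """Column-concatenate two BLUP matrices over a shared accession set."""
    if list(b1.values.index) != list(b2.values.index):
        only1 = set(b1.values.index) - set(b2.values.index)
        only2 = set(b2.values.index) - set(b1.values.index)
        if only1 or only2:
            raise ValueError(
                f"accession mismatch: only-first={sorted(only1)[:5]}, "
                f"only-second={sorted(only2)[:5]}"
            )
        b2 = BlupMatrix(b2.values.loc[b1.values.index], b2.kingdom, b2.sigma2,
                        b2.failed_taxa)
    overlap = set(b1.values.columns) & set(b2.values.columns)
    if overlap:
        raise ValueError(f"duplicate taxon ids across kingdoms: {sorted(overlap)[:5]}")
    return BlupMatrix(
        values=pd.concat([b1.values, b2.values], axis=1),
        kingdom=pd.concat([b1.kingdom, b2.kingdom]),
        sigma2=pd.concat([b1.sigma2, b2.sigma2]),
        failed_taxa=b1.failed_taxa + b2.failed_taxa,
    )


def pc_correlation(p1: PcaResult, p2: PcaResult, i: int = 1, j: int = 1
                   ) -> tuple[float, int]:
    """|Pearson r| between score columns PCi of p1 and PCj of p2.

    PC signs are arbitrary, so the magnitude is the meaningful quantity;
    the sign is returned alongside.
    """
    a = p1.scores[f"PC{i}"].to_numpy()
    b = p2.scores[f"PC{j}"].to_numpy()
    if len(a) != len(b):
        raise ValueError("score vectors differ in length")
    r = float(np.corrcoef(a, b)[0, 1])
    return abs(r), int(np.sign(r)) if r != 0 else 0


def procrustes_statistic(scores1: np.ndarray, scores2: np.ndarray) -> float:
    """Symmetric Procrustes correlation r = sqrt(1 - m2).

    Both configurations are centered and scaled to unit Frobenius norm;
    the optimal rotation comes from the SVD of the cross-product, giving
    m2 = 1 - (sum of singular values)^2.
    """
    A = np.asarray(scores1, dtype=float)
    B = np.asarray(scores2, dtype=float)
    if A.shape != B.shape:
        raise ValueError("configurations must have equal shape")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    A /= np.linalg.norm(A)
    B /= np.linalg.norm(B)
    s = np.linalg.svd(A.T @ B, compute_uv=False)
    m2 = 1.0 - np.sum(s) ** 2
    return float(np.sqrt(max(1.0 - m2, 0.0)))


def procrustes_test(
    p1: PcaResult,
    p2: PcaResult,
    n_pcs: int = 3,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Procrustes rotation test between two ordinations.

    The observed r compares the first ``n_pcs`` score columns; the null
    distribution permutes the rows of the second configuration, and
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1), so the smallest
    attainable p with 999 permutations is 0.001.
    """
    if n_pcs < 2:
        raise ValueError("n_pcs must be >= 2")
    if list(p1.scores.index) != list(p2.scores.index):
        raise ValueError("configurations must share row ordering")
    A = p1.scores.iloc[:, :n_pcs].to_numpy(dtype=float)
    B = p2.scores.iloc[:, :n_pcs].to_numpy(dtype=float)
    r_obs = procrustes_statistic(A, B)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(A.shape[0])
        if procrustes_statistic(A, B[perm]) >= r_obs:
            n_ge += 1
    p = (n_ge + 1) / (n_perm + 1)
    return r_obs, float(p)
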