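"""Per-taxon differential enrichment between organs (root vs leaf).

Each taxon's read count is modelled with a Poisson GLM,

    count ~ organ + block + run,  offset = log(total reads),

so the exponentiated organ coefficient is a depth-corrected rate ratio
root/leaf: >1 means root-enriched, <1 leaf-enriched.  In the balanced
two-sample case without covariates this reduces to the closed-form ratio
of relative abundances.  Wald p-values are reported by default (a
likelihood-ratio test is available); no multiple-testing correction is
applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import CountTable, RANKS, SampleMetadata, UNASSIGNED
from .glmm import design_matrix

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "fit_enrichment", "enrichment_table"]


@dataclass
class EnrichmentResult:
    taxon_id: str
    kingdom: str
    mean_leaf: float          # mean per-sample relative abundance, leaf
    mean_root: float          # mean per-sample relative abundance, root
    pooled_leaf: float        # pooled proportion, leaf
    pooled_root: float        # pooled proportion, root
    enrichment: float         # exp(beta_organ), rate ratio root/leaf
    p_value: float
    boundary: bool            # taxon absent from one organ: separated fit

    @property
    def preferred_habitat(self) -> str:
        return "root" if self.enrichment > 1.0 else "leaf"


def fit_enrichment(
    taxon_counts: pd.Series,
    meta: SampleMetadata,
    kingdom: str = "",
    taxon_id: str = "",
    test: str = "wald",
) -> EnrichmentResult:
    """Fit the organ-enrichment Poisson GLM for one taxon.

    ``taxon_counts`` is indexed by sample id; block and run enter as
    fixed effects when they vary.  Taxa entirely absent from one organ
    produce a boundary (separated) fit: the enrichment is reported at 0
    or inf and flagged.
    """
    frame = meta.frame.loc[taxon_counts.index].copy()
    frame = frame[frame["total_reads"] > 0]
    y = taxon_counts.loc[frame.index].to_numpy(dtype=float)
    organs = set(frame["organ"])
    if organs != {"leaf", "root"}:
        raise ValueError("both organs must be represented")

    is_root = (frame["organ"] == "root").to_numpy(dtype=float)
    totals = frame["total_reads"].to_numpy(dtype=float)
    boundary = (y[is_root == 1].sum() == 0) or (y[is_root == 0].sum() == 0)

    factors = [f for f in ("block", "run") if frame[f].nunique() > 1]
    X, names = design_matrix(frame, factors)
    X = np.column_stack([X[:, :1], is_root, X[:, 1:]])
    names = [names[0], "organ[root]"] + names[1:]

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(totals))
    fit = model.fit(tol=1e-10, maxiter=200)
    beta_organ = fit.params[1]
    enrichment = float(np.exp(beta_organ))
    if test == "wald":
        p = float(fit.pvalues[1])
    elif test == "lrt":
        null_fit = sm.GLM(
            y, np.delete(X, 1, axis=1), family=sm.families.Poisson(),
            offset=np.log(totals),
        ).fit(tol=1e-10, maxiter=200)
        from scipy.stats import chi2

        lr = 2.0 * (fit.llf - null_fit.llf)
        p = float(chi2.sf(max(lr, 0.0), 1))
    else:
        raise ValueError("test must be 'wald' or 'lrt'")
    if boundary:
        # separated fit: coefficient diverges; pin the ratio at its limit
        enrichment = 0.0 if y[is_root == 1].sum() == 0 else np.inf
        p = 0.0 if y.sum() > 0 else 1.0
        logger.warning("taxon %s absent from one organ: boundary fit", taxon_id)

    rel = y / totals
    leaf_mask, root_mask = is_root == 0, is_root == 1
    return EnrichmentResult(
        taxon_id=taxon_id,
        kingdom=kingdom,
        mean_leaf=float(rel[leaf_mask].mean()),
        mean_root=float(rel[root_mask].mean()),
        pooled_leaf=float(y[leaf_mask].sum() / totals[leaf_mask].sum()),
        pooled_root=float(y[root_mask].sum() / totals[root_mask].sum()),
        enrichment=enrichment,
        p_value=p,
        boundary=boundary,
    )


def aggregate_by_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts within each label at a taxonomic rank.

    ``"Unassigned"`` at the rank forms its own category.  The aggregated
    taxon ids are the rank labels; kingdom is carried over (single-kingdom
    tables only).
    """
    if rank not in RANKS and rank != "phylotype":
        raise ValueError(f"unknown rank {rank!r}")
    if rank == "phylotype":
        return table
    kingdoms = set(table.kingdom)
    if len(kingdoms) != 1:
        raise ValueError("aggregate one kingdom at a time")
    labels = table.lineage_at(rank)
    grouped = table.counts.T.groupby(labels).sum().T
    kingdom = pd.Series(next(iter(kingdoms)), index=grouped.columns, dtype=object)
    lineage = pd.Series("", index=grouped.columns, dtype=object)
    return CountTable(grouped, kingdom, lineage)


def enrichment_table(
    table: CountTable,
    meta: SampleMetadata,
    rank: str = "genus",
    test: str = "wald",
) -> pd.DataFrame:
    """Organ enrichment for every taxon aggregated at ``rank``.

    Returns one row per aggregated taxon, sorted by total abundance
    (descending), with mean and pooled relative abundances per organ, the
    rate ratio, and its p-value.
    """
    agg = aggregate_by_rank(table, rank)
    totals = agg.taxon_totals().sort_values(ascending=False)
    rows = []
    for taxon in totals.index:
        res = fit_enrichment(
            agg.counts[taxon], meta, kingdom=str(agg.kingdom[taxon]),
            taxon_id=str(taxon), test=test,
        )
        rows.append({
            "taxon_id": res.taxon_id,
            "kingdom": res.kingdom,
            "habitat": res.preferred_habitat,
            "leaf": res.mean_leaf,
            "root": res.mean_root,
            "enrichment_in_root": res.enrichment,
            "p_value": res.p_value,
            "boundary": res.boundary,
            "total_reads": int(totals[taxon]),
        })
    return pd.DataFrame(rows)
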