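"""Count-table quality filters and genotype MAF filtering.

Taxa unassigned at the kingdom rank, organellar sequences (class
Chloroplast, family Mitochondria) and singletons — taxa observed (count
> 0) in at most one sample across the whole table — are removed before
any downstream analysis.  Singleton status is judged jointly over all
samples (leaf and root together) by default; a per-organ mode is
available through the ``organ_of`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountTable, GenotypeMatrix, UNASSIGNED

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-rule record of taxa removed by :func:`qc_filter`."""

    unassigned_kingdom: list[str] = field(default_factory=list)
    chloroplast: list[str] = field(default_factory=list)
    mitochondria: list[str] = field(default_factory=list)
    singleton: list[str] = field(default_factory=list)
    absent: list[str] = field(default_factory=list)  # observed in zero samples

    @property
    def n_removed(self) -> int:
        removed = (set(self.unassigned_kingdom) | set(self.chloroplast)
                   | set(self.mitochondria) | set(self.singleton) | set(self.absent))
        return len(removed)

    def summary(self) -> dict[str, int]:
        return {
            "unassigned_kingdom": len(self.unassigned_kingdom),
            "chloroplast": len(self.chloroplast),
            "mitochondria": len(self.mitochondria),
            "singleton": len(self.singleton),
            "absent": len(self.absent),
        }


def qc_filter(
    table: CountTable, organ_of: pd.Series | None = None
) -> tuple[CountTable, FilterReport]:
    """Apply the standard quality filters to a count table.

    Removes taxa that are (a) unassigned at the kingdom rank of their
    lineage, (b) class Chloroplast, (c) family Mitochondria, or (d)
    observed (count > 0) in at most one sample.  When ``organ_of`` maps
    sample -> organ, the singleton rule is applied within each organ
    instead of jointly (a taxon survives if present in >= 2 samples of
    any one organ).
    """
    report = FilterReport()
    kingdom_rank = table.lineage_at("kingdom")
    class_rank = table.lineage_at("class")
    family_rank = table.lineage_at("family")
    presence = table.counts > 0

    keep: list[str] = []
    for taxon in table.taxon_ids:
        if kingdom_rank[taxon] == UNASSIGNED:
            report.unassigned_kingdom.append(taxon)
            continue
        if class_rank[taxon] == "Chloroplast":
            report.chloroplast.append(taxon)
            continue
        if family_rank[taxon] == "Mitochondria":
            report.mitochondria.append(taxon)
            continue
        if organ_of is None:
            n_present = int(presence[taxon].sum())
        else:
            n_present = int(presence[taxon].groupby(organ_of).sum().max())
        if n_present == 0:
            report.absent.append(taxon)
            continue
        if n_present <= 1:
            report.singleton.append(taxon)
            continue
        keep.append(taxon)

    if not keep:
        logger.warning("qc_filter removed every taxon; result table is empty")
    return table.select_taxa(keep), report


def top_taxa(table: CountTable, n: int) -> CountTable:
    """Retain the ``n`` best-sequenced taxa (largest read totals).

    Ties in total reads are broken lexicographically on taxon id so that
    the selection is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = table.taxon_totals()
    if n > len(totals):
        logger.warning("requested top %d of %d taxa; returning all", n, len(totals))
        n = len(totals)
    order = sorted(table.taxon_ids, key=lambda t: (-totals[t], t))
    return table.select_taxa(order[:n])


def maf_filter(geno: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs with minor-allele frequency >= ``min_maf``."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    keep = geno.maf() >= min_maf
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("maf_filter dropped %d of %d SNPs", n_drop, geno.n_snps)
    return geno.select_snps(keep)
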