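"""Alpha and beta diversity with explicit depth correction.

Richness (the number of taxa observed in a sample) is modelled with a
Poisson log-link GLMM: fixed effects for block and sequencing run (plus
kingdom with run nested in kingdom when both communities are analyzed
together), a log(total reads) offset to absorb sequencing effort, and a
random intercept per accession whose conditional modes (BLUPs) summarize
each host genotype's diversity deviation.

For visualization-style normalization, samples are resampled once,
without replacement, to a fixed depth (400 reads by default) from the
realized read pool of each sample.  Whittaker's beta measures species
turnover between two rarefied samples: beta = S / mean(alpha) - 1, which
is 0 for identical communities and 1 for disjoint ones.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleMetadata
from .glmm import PoissonGLMMResult, design_matrix, fit_poisson_glmm

logger = logging.getLogger(__name__)

__all__ = ["ResampledTable", "RichnessBlups", "rarefy", "richness",
           "whittaker_beta", "mean_beta", "fit_richness_glmm",
           "kingdom_preference"]


@dataclass
class ResampledTable:
    """A count table resampled to a common per-sample depth."""

    counts: pd.DataFrame          # kept samples x taxa, rows sum to depth
    depth: int
    excluded_samples: list[str]   # samples with fewer than `depth` reads
    seed: int | None

    @property
    def kept_samples(self) -> list[str]:
        return list(self.counts.index)


def rarefy(
    table: CountTable, depth: int, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ResampledTable:
    """Resample every sample once to ``depth`` reads without replacement.

    Draws a multivariate hypergeometric sample from each sample's realized
    read pool, so only observed taxa can be drawn and row sums equal
    ``depth`` exactly.  Samples with fewer than ``depth`` total reads are
    excluded and logged.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    totals = table.total_reads()
    keep = totals.index[totals >= depth].tolist()
    excluded = totals.index[totals < depth].tolist()
    if excluded:
        logger.info("rarefy(depth=%d): excluding %d sample(s): %s",
                    depth, len(excluded), excluded[:10])
    rows = np.empty((len(keep), table.n_taxa), dtype=np.int64)
    for i, s in enumerate(keep):
        pool = table.counts.loc[s].to_numpy()
        rows[i] = rng.multivariate_hypergeometric(pool, depth)
    counts = pd.DataFrame(rows, index=keep, columns=table.taxon_ids)
    return ResampledTable(counts=counts, depth=depth,
                          excluded_samples=excluded, seed=seed)


def richness(sample_counts) -> int | pd.Series:
    """Number of taxa with at least one read.

    Accepts a single count vector (returns an int) or a samples x taxa
    DataFrame (returns a per-sample Series).
    """
    if isinstance(sample_counts, pd.DataFrame):
        return (sample_counts > 0).sum(axis=1)
    arr = np.asarray(sample_counts)
    return int(np.count_nonzero(arr))


def whittaker_beta(presence1, presence2) -> float:
    """Whittaker's species turnover between two samples.

    beta = S / mean(alpha) - 1, with S the union richness.  Ranges from 0
    (identical communities) to 1 (disjoint non-empty communities).
    Arguments may be sets of taxon ids or count/boolean vectors.
    """
    s1, s2 = (_as_set(p) for p in (presence1, presence2))
    if not s1 and not s2:
        raise ValueError("beta undefined: both samples are empty")
    S = len(s1 | s2)
    alpha_bar = (len(s1) + len(s2)) / 2.0
    return S / alpha_bar - 1.0


def _as_set(presence) -> set:
    if isinstance(presence, (set, frozenset)):
        return set(presence)
    if isinstance(presence, pd.Series):
        return set(presence.index[presence > 0])
    arr = np.asarray(presence)
    return set(np.nonzero(arr)[0].tolist())


def mean_beta(resampled: ResampledTable, samples: list[str] | None = None) -> float:
    """Mean Whittaker beta over all unordered sample pairs."""
    counts = resampled.counts if samples is None else resampled.counts.loc[samples]
    presence = [set(counts.columns[counts.loc[s] > 0]) for s in counts.index]
    betas = [whittaker_beta(a, b) for a, b in itertools.combinations(presence, 2)]
    if not betas:
        raise ValueError("need at least two samples for mean beta")
    return float(np.mean(betas))


@dataclass
class RichnessBlups:
    """Accession-level richness deviations from the GLMM."""

    blups: pd.Series              # accession -> conditional mode
    sigma2_accession: float
    fixed_effects: pd.Series
    scope: str                    # kingdom name or "combined"
    model: PoissonGLMMResult


def fit_richness_glmm(
    tables: CountTable | dict[str, CountTable],
    meta: SampleMetadata | dict[str, SampleMetadata],
    scope: str = "combined",
) -> RichnessBlups:
    """Poisson GLMM of per-sample richness with an accession random effect.

    ``scope`` is a kingdom name (fit one table) or ``"combined"``: richness
    observations from both kingdoms are stacked, kingdom enters as a fixed
    effect and the sequencing run is nested within kingdom.

    Model: richness ~ block + organ + run (+ kingdom) + offset(log reads)
    + (1 | accession).  Samples with zero total reads are dropped.
    """
    if scope != "combined":
        table = tables[scope] if isinstance(tables, dict) else tables
        m = meta[scope] if isinstance(meta, dict) else meta
        frame = m.frame.loc[table.sample_ids].copy()
        frame["richness"] = richness(table.counts)
        frame["kingdom"] = scope
    else:
        if not isinstance(tables, dict) or not isinstance(meta, dict):
            raise ValueError("combined scope needs per-kingdom dicts")
        parts = []
        for kingdom, table in tables.items():
            part = meta[kingdom].frame.loc[table.sample_ids].copy()
            part["richness"] = richness(table.counts)
            part["kingdom"] = kingdom
            part.index = [f"{s}::{kingdom}" for s in part.index]
            parts.append(part)
        frame = pd.concat(parts)

    frame = frame[frame["total_reads"] > 0]
    if frame.empty:
        raise ValueError("no samples with positive total reads")

    factors = ["block"]
    if frame["organ"].nunique() > 1:
        factors.append("organ")
    interactions: list[tuple[str, str]] = []
    if scope == "combined":
        factors.append("kingdom")
        interactions.append(("kingdom", "run"))
    else:
        factors.append("run")
    X, names = design_matrix(frame, factors, interactions)
    result = fit_poisson_glmm(
        frame["richness"].to_numpy(),
        X,
        frame["accession_id"],
        offset=np.log(frame["total_reads"].to_numpy(dtype=float)),
        coef_names=names,
    )
    return RichnessBlups(
        blups=result.blups,
        sigma2_accession=result.sigma2_group,
        fixed_effects=result.fixed_effects,
        scope=scope,
        model=result,
    )


def kingdom_preference(bact: RichnessBlups, fung: RichnessBlups) -> pd.Series:
    """Per-accession bacterial-minus-fungal richness deviation.

    Positive values mark hosts that support relatively more diverse
    bacterial than fungal communities.  Accessions present in only one
    kingdom are excluded with a log entry.
    """
    shared = bact.blups.index.intersection(fung.blups.index)
    dropped = set(bact.blups.index).symmetric_difference(fung.blups.index)
    if dropped:
        logger.info("kingdom_preference: excluding %d unshared accession(s)",
                    len(dropped))
    pref = bact.blups[shared] - fung.blups[shared]
    pref.name = "preference"
    return pref
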