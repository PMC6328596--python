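"""Synthetic two-kingdom microbiome communities with the study's design.

The generator emulates a field experiment in which replicated inbred
accessions are grown in a randomized block design and both the bacterial
(16S) and fungal (ITS) communities of each plant organ are sequenced:

* ``n_accessions`` (196) x ``n_replicates`` (4) plants, each contributing
  a leaf and a root sample per kingdom;
* heritable taxon abundances: a per-taxon accession effect that is either
  polygenic (a weighted sum over causal SNPs) or i.i.d., scaled so that
  its realized share of the log-scale variance equals ``h2_taxon``;
* block and sequencing-run artifacts as per-taxon log-scale effects;
* cross-taxon correlation through low-rank latent factors;
* heavily dispersed sequencing depths, lognormal with moments matched to
  the per-kingdom read statistics (bacteria 2524 +/- 1594, fungi
  562 +/- 726 reads per sample).

Counts are multinomial draws of each sample's depth over the taxon
relative rates exp(eta), so every sample's counts sum exactly to its
simulated depth.  All latent effects are kept in a :class:`TruthRecord`
so downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountTable, GenotypeMatrix, SampleMetadata

__all__ = ["SimParams", "TruthRecord", "SimResult", "simulate_genotypes",
           "simulate_community"]


@dataclass
class SimParams:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_accessions: int = 196
    n_replicates: int = 4
    organs: tuple[str, ...] = ("leaf", "root")
    n_snps: int = 1000
    n_clusters: int = 1           # >1 adds population structure
    fst: float = 0.2              # Balding-Nichols divergence when clustered
    n_taxa_bacteria: int = 100
    n_taxa_fungi: int = 100
    h2_taxon: float | dict = 0.3  # target heritability of log-abundance
                                  # (scalar, or per-kingdom dict)
    polygenic: bool = True        # accession effect from causal SNPs vs i.i.d.
    n_causal_snps_per_trait: int = 10
    n_causal_pool: int | None = 25  # per-kingdom pool of host loci from which
                                    # each taxon draws its causal SNPs; None
                                    # draws genome-wide (taxa genetically
                                    # independent)
    evenness_axis_weight: float = 0.5  # share of each taxon's accession
                                       # effect carried by one shared
                                       # polygenic evenness axis (common
                                       # taxa up, rare taxa down), which
                                       # makes richness itself heritable
    sigma_block: float = 0.2      # SD of per-taxon block artifacts (log scale)
    sigma_run: float = 0.2        # SD of per-taxon run artifacts (log scale)
    sigma_noise: float = 0.5      # per-observation log-scale residual SD
    sigma_organ: float = 0.5      # SD of per-taxon organ (root vs leaf) effects
    sigma_taxon_mean: float = 1.5 # spread of baseline log relative abundances
    latent_factor_count: int = 3
    loadings_scale: float = 0.3
    n_runs: int = 6               # sequencing runs per kingdom
    depth_mean: dict = field(
        default_factory=lambda: {"bacteria": 2524.0, "fungi": 562.0}
    )
    depth_sd: dict = field(
        default_factory=lambda: {"bacteria": 1594.0, "fungi": 726.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.evenness_axis_weight <= 1.0:
            raise ValueError("evenness_axis_weight must lie in [0, 1]")
        for name in ("sigma_block", "sigma_run", "sigma_noise", "sigma_organ",
                     "sigma_taxon_mean", "loadings_scale", "fst"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        h2_values = (self.h2_taxon.values() if isinstance(self.h2_taxon, dict)
                     else [self.h2_taxon])
        if any(not 0.0 <= h <= 1.0 for h in h2_values):
            raise ValueError("h2_taxon must lie in [0, 1]")
        if self.n_snps < 1 or self.n_accessions < 2:
            raise ValueError("need n_snps >= 1 and n_accessions >= 2")


@dataclass
class TruthRecord:
    """Latent effects of one simulated kingdom, sufficient to rebuild eta."""

    kingdom: str
    taxa: list[str]
    mu: np.ndarray                 # baseline log relative abundance per taxon
    organ_effect: np.ndarray       # per-taxon root-vs-leaf shift
    accession_effect: pd.DataFrame # accessions x taxa
    block_effect: pd.DataFrame     # blocks x taxa
    run_effect: pd.DataFrame       # runs x taxa
    loadings: np.ndarray           # taxa x latent factors
    factors: pd.DataFrame          # samples x latent factors
    noise: pd.DataFrame            # samples x taxa residual
    depths: pd.Series              # per-sample total reads
    h2_realized: np.ndarray        # realized variance share of accession effect
    evenness_axis: pd.Series | None = None  # shared polygenic diversity score

    def eta(self, meta: SampleMetadata) -> pd.DataFrame:
        """Reconstruct the log-rate matrix eta from the stored components."""
        frame = meta.frame
        samples = list(frame.index)
        is_root = (frame["organ"] == "root").to_numpy(dtype=float)
        eta = (
            self.mu[None, :]
            + is_root[:, None] * self.organ_effect[None, :]
            + self.accession_effect.loc[frame["accession_id"]].to_numpy()
            + self.block_effect.loc[frame["block"]].to_numpy()
            + self.run_effect.loc[frame["run"]].to_numpy()
            + self.factors.loc[samples].to_numpy() @ self.loadings.T
            + self.noise.loc[samples].to_numpy()
        )
        return pd.DataFrame(eta, index=samples, columns=self.taxa)


@dataclass
class SimResult:
    tables: dict[str, CountTable]        # kingdom -> CountTable
    meta: dict[str, SampleMetadata]      # kingdom -> SampleMetadata
    truth: dict[str, TruthRecord]
    genotypes: GenotypeMatrix
    params: SimParams


def simulate_genotypes(
    params: SimParams, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw haploid SNP dosages for the accession panel.

    Allele frequencies are Uniform(0.05, 0.5).  With ``n_clusters > 1``,
    cluster-specific frequencies follow the Balding-Nichols model at the
    given Fst, inducing population structure that the kinship matrix and
    mixed models must absorb.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, m = params.n_accessions, params.n_snps
    p = rng.uniform(0.05, 0.5, size=m)
    if params.n_clusters > 1 and params.fst > 0:
        f = params.fst
        a, b = p * (1 - f) / f, (1 - p) * (1 - f) / f
        cluster_p = rng.beta(a, b, size=(params.n_clusters, m))
        labels = np.repeat(np.arange(params.n_clusters),
                           int(np.ceil(n / params.n_clusters)))[:n]
        dosages = (rng.random((n, m)) < cluster_p[labels]).astype(float)
    else:
        dosages = (rng.random((n, m)) < p[None, :]).astype(float)
    n_chrom = 5
    chrom = np.array([f"Chr{1 + j % n_chrom}" for j in range(m)])
    pos = np.zeros(m, dtype=np.int64)
    for c in range(n_chrom):
        mask = chrom == f"Chr{1 + c}"
        pos[mask] = 1 + 1000 * np.arange(mask.sum())
    order = np.lexsort((pos, chrom))
    return GenotypeMatrix(
        [f"acc{i:04d}" for i in range(n)],
        chrom[order], pos[order],
        np.full(m, "A"), np.full(m, "T"),
        dosages[:, order],
    )


def _moment_matched_lognormal(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _simulate_kingdom(
    kingdom: str,
    geno: GenotypeMatrix,
    params: SimParams,
    design: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[CountTable, SampleMetadata, TruthRecord]:
    n_taxa = params.n_taxa_bacteria if kingdom == "bacteria" else params.n_taxa_fungi
    taxa = [f"{'b' if kingdom == 'bacteria' else 'f'}_otu{t:04d}"
            for t in range(n_taxa)]
    samples = list(design.index)
    n = len(samples)
    accessions = geno.accession_ids
    blocks = sorted(design["block"].unique())

    # per-kingdom sequencing runs: contiguous batches of samples
    run_labels = [f"{kingdom[:1]}run{1 + (i * params.n_runs) // n}"
                  for i in range(n)]
    runs = sorted(set(run_labels))

    mu = rng.normal(0.0, params.sigma_taxon_mean, size=n_taxa)
    organ_eff = rng.normal(0.0, params.sigma_organ, size=n_taxa)
    block_eff = pd.DataFrame(
        rng.normal(0.0, params.sigma_block, size=(len(blocks), n_taxa)),
        index=blocks, columns=taxa,
    )
    run_eff = pd.DataFrame(
        rng.normal(0.0, params.sigma_run, size=(len(runs), n_taxa)),
        index=runs, columns=taxa,
    )
    loadings = rng.normal(0.0, params.loadings_scale,
                          size=(n_taxa, params.latent_factor_count))
    factors = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n, params.latent_factor_count)),
        index=samples,
    )
    noise = pd.DataFrame(
        rng.normal(0.0, params.sigma_noise, size=(n, n_taxa)),
        index=samples, columns=taxa,
    )

    # accession effects, scaled so their realized share of the log-scale
    # variance (over samples) equals h2_taxon
    if params.polygenic:
        X = geno.imputed()
        Xs = (X - X.mean(axis=0))
        raw = np.zeros((len(accessions), n_taxa))
        # taxa draw causal SNPs from a limited per-kingdom pool of host
        # loci, mimicking pleiotropic microbiome genes; pool=None makes
        # taxa genetically independent
        if params.n_causal_pool is None:
            pool = np.arange(geno.n_snps)
        else:
            pool = rng.choice(geno.n_snps,
                              size=min(params.n_causal_pool, geno.n_snps),
                              replace=False)
        for t in range(n_taxa):
            causal = rng.choice(pool,
                                size=min(params.n_causal_snps_per_trait,
                                         len(pool)),
                                replace=False)
            beta = rng.normal(0.0, 1.0, size=len(causal))
            raw[:, t] = Xs[:, causal] @ beta
        # shared polygenic evenness axis: pushes already-common taxa up
        # and rare taxa down, so community evenness (hence richness at a
        # fixed depth) varies additively among accessions
        w_axis = params.evenness_axis_weight
        g_shared_series = None
        if w_axis > 0:
            axis_causal = rng.choice(pool,
                                     size=min(params.n_causal_snps_per_trait,
                                              len(pool)),
                                     replace=False)
            g_shared = Xs[:, axis_causal] @ rng.normal(size=len(axis_causal))
            sd = g_shared.std()
            if sd > 0:
                g_shared = (g_shared - g_shared.mean()) / sd
                col_sd = raw.std(axis=0)
                col_sd[col_sd == 0] = 1.0
                raw = (np.sqrt(1.0 - w_axis) * raw / col_sd
                       + np.sqrt(w_axis) * np.outer(g_shared, np.sign(mu)))
                g_shared_series = pd.Series(g_shared, index=accessions)
    else:
        raw = rng.normal(0.0, 1.0, size=(len(accessions), n_taxa))
        g_shared_series = None
    raw -= raw.mean(axis=0)

    acc_idx = design["accession_id"].to_numpy()
    other = (
        block_eff.loc[design["block"]].to_numpy()
        + run_eff.loc[pd.Index(run_labels)].to_numpy()
        + factors.to_numpy() @ loadings.T
        + noise.to_numpy()
    )
    v_other = other.var(axis=0)
    h2 = (params.h2_taxon[kingdom] if isinstance(params.h2_taxon, dict)
          else params.h2_taxon)
    if h2 >= 1.0 and np.any(v_other > 0):
        raise ValueError("h2_taxon = 1 infeasible with nonzero artifact/noise "
                         "variances")
    raw_expanded = pd.DataFrame(raw, index=accessions, columns=taxa)
    raw_samplewise = raw_expanded.loc[acc_idx].to_numpy()
    v_raw = raw_samplewise.var(axis=0)
    scale = np.zeros(n_taxa)
    nonzero = v_raw > 0
    if h2 > 0:
        target = h2 / (1.0 - h2) * v_other
        scale[nonzero] = np.sqrt(target[nonzero] / v_raw[nonzero])
    acc_eff = pd.DataFrame(raw * scale[None, :], index=accessions, columns=taxa)
    v_acc = acc_eff.loc[acc_idx].to_numpy().var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h2_realized = np.where(v_acc + v_other > 0,
                               v_acc / (v_acc + v_other), 0.0)

    meta_frame = design.copy()
    meta_frame["run"] = run_labels

    truth = TruthRecord(
        kingdom=kingdom, taxa=taxa, mu=mu, organ_effect=organ_eff,
        accession_effect=acc_eff, block_effect=block_eff, run_effect=run_eff,
        loadings=loadings, factors=factors, noise=noise,
        depths=pd.Series(dtype=np.int64), h2_realized=h2_realized,
        evenness_axis=g_shared_series,
    )

    # depths: lognormal, moment-matched to the kingdom's printed mean/sd
    lmu, lsd = _moment_matched_lognormal(
        params.depth_mean[kingdom], params.depth_sd[kingdom]
    )
    depths = np.maximum(1, np.round(rng.lognormal(lmu, lsd, size=n))).astype(
        np.int64
    )
    truth.depths = pd.Series(depths, index=samples, name="depth")
    meta_frame["total_reads"] = depths

    meta = SampleMetadata(meta_frame)
    eta = truth.eta(meta).to_numpy()
    # multinomial draw of each sample's depth over relative rates exp(eta):
    # conserves the depth exactly while matching Poisson proportions
    rates = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs = rates / rates.sum(axis=1, keepdims=True)
    counts = np.empty((n, n_taxa), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])

    prefix = "k__Fungi" if kingdom == "fungi" else "k__Bacteria"
    lineage = pd.Series(
        [f"{prefix};p__P{t % 7};c__C{t % 11};o__O{t % 13};f__F{t % 17};"
         f"g__G{t % 23}" for t in range(n_taxa)],
        index=taxa, dtype=object,
    )
    table = CountTable(
        pd.DataFrame(counts, index=samples, columns=taxa),
        pd.Series(kingdom, index=taxa, dtype=object),
        lineage,
    )
    return table, meta, truth


def simulate_community(
    geno: GenotypeMatrix, params: SimParams, seed: int | None = None
) -> SimResult:
    """Simulate the paired two-kingdom count tables for the full design."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    accessions = geno.accession_ids
    if len(accessions) != params.n_accessions:
        raise ValueError("genotype panel size disagrees with params")

    rows = []
    for a, acc in enumerate(accessions):
        for r in range(params.n_replicates):
            block = f"block{r + 1}"  # replicate r sits in block r (RCBD)
            for organ in params.organs:
                sid = f"{acc}.r{r + 1}.{organ}"
                rows.append((sid, acc, organ, block))
    design = pd.DataFrame(
        rows, columns=["sample_id", "accession_id", "organ", "block"]
    ).set_index("sample_id")

    tables, meta, truth = {}, {}, {}
    for kingdom in ("bacteria", "fungi"):
        tables[kingdom], meta[kingdom], truth[kingdom] = _simulate_kingdom(
            kingdom, geno, params, design, rng
        )
    return SimResult(tables=tables, meta=meta, truth=truth, genotypes=geno,
                     params=params)
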