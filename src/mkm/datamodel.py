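"""Core data containers for multi-kingdom amplicon count data.

The central observation object is a :class:`CountTable`: an integer matrix of
reads per sample x taxon, with a kingdom label (bacteria or fungi) and a
ranked taxonomic lineage attached to every taxon.  Sample-level design
factors (accession, organ, block, sequencing run, total reads) live in
:class:`SampleMetadata`; they drive the fixed effects and the log-depth
offsets of every count model in the pipeline.  Genotypes for the host
accessions are held in :class:`GenotypeMatrix` with haploid {0, 1} dosage
coding, as appropriate for inbred lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__")))
UNASSIGNED = "Unassigned"

KINGDOMS = ("bacteria", "fungi")
ORGANS = ("leaf", "root")


class CountTableError(ValueError):
    """Raised when a count table violates its invariants."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ``k__...;p__...;...`` lineage string into rank -> label.

    Missing ranks and empty labels map to ``"Unassigned"``.
    """
    out = {rank: UNASSIGNED for rank in RANKS}
    if not lineage or (isinstance(lineage, float) and np.isnan(lineage)):
        return out
    for part in str(lineage).split(";"):
        part = part.strip()
        for rank, prefix in RANK_PREFIX.items():
            if part.startswith(prefix):
                label = part[len(prefix):].strip()
                out[rank] = label if label else UNASSIGNED
                break
    return out


def format_lineage(ranks: Mapping[str, str]) -> str:
    return ";".join(RANK_PREFIX[r] + ranks.get(r, UNASSIGNED) for r in RANKS)


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one integer column per taxon.
    kingdom
        Series mapping taxon id -> ``"bacteria"`` or ``"fungi"``.
    lineage
        Series mapping taxon id -> semicolon-ranked lineage string in the
        ``k__;p__;c__;o__;f__;g__`` dialect.  Optional labels default to
        ``"Unassigned"``.
    """

    counts: pd.DataFrame
    kingdom: pd.Series
    lineage: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise CountTableError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise CountTableError(f"duplicate taxon ids: {dups}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))
                i, j = bad[0]
                raise CountTableError(
                    f"non-integer count at sample {self.counts.index[i]!r}, "
                    f"taxon {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise CountTableError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        self.kingdom = pd.Series(self.kingdom, dtype=object).reindex(self.counts.columns)
        if self.kingdom.isna().any():
            missing = self.kingdom.index[self.kingdom.isna()].tolist()
            raise CountTableError(f"taxa without kingdom label: {missing}")
        bad = set(self.kingdom.unique()) - set(KINGDOMS)
        if bad:
            raise CountTableError(f"unknown kingdom labels: {sorted(bad)}")
        self.lineage = (
            pd.Series(self.lineage, dtype=object)
            .reindex(self.counts.columns)
            .fillna(format_lineage({}))
        )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def total_reads(self) -> pd.Series:
        """Per-sample read totals (row sums)."""
        return self.counts.sum(axis=1)

    def taxon_totals(self) -> pd.Series:
        """Per-taxon read totals across all samples."""
        return self.counts.sum(axis=0)

    def lineage_at(self, rank: str) -> pd.Series:
        """Labels of every taxon at ``rank`` (``"Unassigned"`` if absent)."""
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; choose from {RANKS}")
        return pd.Series(
            {t: parse_lineage(self.lineage[t])[rank] for t in self.counts.columns},
            name=rank,
        )

    # -- subsetting ------------------------------------------------------
    def select_taxa(self, taxa: Iterable[str]) -> "CountTable":
        taxa = list(taxa)
        return CountTable(self.counts[taxa], self.kingdom[taxa], self.lineage[taxa])

    def select_samples(self, samples: Iterable[str]) -> "CountTable":
        samples = list(samples)
        return CountTable(self.counts.loc[samples], self.kingdom, self.lineage)

    def subset_kingdom(self, kingdom: str) -> "CountTable":
        taxa = [t for t in self.taxon_ids if self.kingdom[t] == kingdom]
        return self.select_taxa(taxa)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.kingdom.equals(other.kingdom)
            and self.lineage.equals(other.lineage)
        )


class SampleMetadata:
    """Per-sample design factors: accession, organ, block, run, total reads."""

    REQUIRED = ("accession_id", "organ", "block", "run", "total_reads")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "sample_id":
            if "sample_id" in frame.columns:
                frame = frame.set_index("sample_id")
            else:
                frame.index.name = "sample_id"
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].tolist()
            raise CountTableError(f"duplicate sample ids in metadata: {dups}")
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise CountTableError(f"metadata missing columns: {missing}")
        for col in ("accession_id", "organ", "block", "run"):
            if frame[col].isna().any():
                raise CountTableError(f"metadata column {col!r} has missing values")
        bad = set(frame["organ"].unique()) - set(ORGANS)
        if bad:
            raise CountTableError(f"unknown organ labels: {sorted(bad)}")
        frame["total_reads"] = frame["total_reads"].astype(np.int64)
        if (frame["total_reads"] < 0).any():
            raise CountTableError("total_reads must be >= 0")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def for_samples(self, samples: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(samples)])

    def subset_organ(self, organ: str) -> "SampleMetadata":
        return SampleMetadata(self.frame[self.frame["organ"] == organ])

    def column(self, name: str) -> pd.Series:
        return self.frame[name]

    def check_against(self, table: CountTable) -> None:
        """Verify count-table row sums equal recorded total_reads."""
        shared = [s for s in table.sample_ids if s in self.frame.index]
        totals = table.counts.loc[shared].sum(axis=1)
        recorded = self.frame.loc[shared, "total_reads"]
        if not (totals == recorded).all():
            bad = totals.index[totals != recorded].tolist()
            raise CountTableError(
                f"row sums disagree with metadata total_reads for samples: {bad[:5]}"
            )


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs haploid dosage matrix for inbred lines.

    ``dosages`` holds values in {0, 1} with ``nan`` for missing calls.
    SNP records carry chromosome, 1-based position, ref and alt alleles.
    """

    accession_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray  # accessions x snps, float64, nan = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        n, m = self.dosages.shape
        if n != len(self.accession_ids):
            raise ValueError("dosage rows must match accession_ids")
        if m != len(self.pos):
            raise ValueError("dosage columns must match SNP records")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("dosages must be 0/1 (haploid) or nan")
        # positions sorted within chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c!r}")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Per-SNP mean dosage (allele-1 frequency), ignoring missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(~np.isfinite(self.dosages), axis=0)

    def select_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            list(self.accession_ids),
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.dosages[:, mask],
        )

    def select_accessions(self, accessions: Iterable[str]) -> "GenotypeMatrix":
        accessions = list(accessions)
        idx = [self.accession_ids.index(a) for a in accessions]
        return GenotypeMatrix(
            accessions, self.chrom, self.pos, self.ref, self.alt, self.dosages[idx]
        )

    def imputed(self) -> np.ndarray:
        """Dosages with missing values mean-imputed per SNP."""
        X = self.dosages.copy()
        if np.all(np.isfinite(X)):
            return X
        p = self.allele_frequency()
        idx = np.where(~np.isfinite(X))
        X[idx] = p[idx[1]]
        return X


@dataclass
class RunConfig:
    """Analysis constants shared across the pipeline.

    Defaults mirror the study design: 400-read resampling depth, network
    edges at P < 0.01, 999 permutations, the top-100 best-sequenced taxa,
    10-kb GWAS windows, the 1% GWAS tail and an FDR ceiling of q < 0.10.
    """

    seed: int = 0
    resample_depth: int = 400
    edge_alpha: float = 0.01
    n_permutations: int = 999
    top_n_taxa: int = 100
    window_bp: int = 10_000
    tail_fraction: float = 0.01
    fdr_q: float = 0.10

    def __post_init__(self) -> None:
        if self.resample_depth < 1:
            raise ValueError("resample_depth must be >= 1")
        if not 0 < self.edge_alpha <= 1:
            raise ValueError("edge_alpha must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.top_n_taxa < 1:
            raise ValueError("top_n_taxa must be >= 1")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if not 0 < self.tail_fraction <= 1:
            raise ValueError("tail_fraction must be in (0, 1]")
        if not 0 < self.fdr_q <= 1:
            raise ValueError("fdr_q must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
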