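"""Readers and writers for the pipeline's plain-text interchange formats.

Count tables are TSV with taxa as rows and samples as columns; the first
column is ``taxon_id`` and an optional ``lineage`` column carries the
semicolon-ranked ``k__;p__;...`` lineage.  Metadata is a flat TSV.
Genotypes are read either from VCF (biallelic SNPs, via cyvcf2) or from a
TSV dosage matrix.  Gene annotation comes from GFF3 gene features and the
gene -> GO map from a two-column TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CountTable, CountTableError, GenotypeMatrix, SampleMetadata

logger = logging.getLogger(__name__)


def read_count_table(path, kingdom: str) -> CountTable:
    """Read a taxa-rows x sample-columns TSV into a :class:`CountTable`.

    ``kingdom`` is stamped on all taxa in the file (count tables are
    produced per amplicon, so each file is single-kingdom).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.columns[0] != "taxon_id":
        raise CountTableError(
            f"{path}: first column must be 'taxon_id', got {frame.columns[0]!r}"
        )
    frame = frame.set_index("taxon_id")
    if "lineage" in frame.columns:
        lineage = frame.pop("lineage").fillna("")
    else:
        lineage = pd.Series("", index=frame.index, dtype=object)
    counts = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        try:
            values = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            raise CountTableError(f"{path}: non-numeric count in column {col!r}") from exc
        bad = values.index[(values != np.floor(values)) | (values < 0)]
        if len(bad):
            raise CountTableError(
                f"{path}: invalid count {frame.loc[bad[0], col]!r} at "
                f"taxon {bad[0]!r}, sample {col!r} (must be integer >= 0)"
            )
        counts[col] = values.astype(np.int64)
    table = counts.T  # samples x taxa in memory
    kingdom_of = pd.Series(kingdom, index=table.columns, dtype=object)
    return CountTable(table, kingdom_of, lineage)


def write_count_table(table: CountTable, path) -> None:
    """Write a :class:`CountTable` in the taxa-rows TSV dialect."""
    out = table.counts.T.copy()
    out.insert(0, "lineage", table.lineage)
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t")


def read_genotypes(
    path,
    het_policy: str = "missing",
    max_missing: float = 0.2,
) -> GenotypeMatrix:
    """Read genotypes from VCF (``.vcf``) or a TSV dosage matrix.

    Accessions are inbred, so genotypes are coded haploid {0, 1}.
    Heterozygous VCF calls are handled per ``het_policy``: ``"missing"``
    (default) or ``"error"``.  SNPs with missingness above ``max_missing``
    are dropped with a log entry.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        geno = _read_vcf(path, het_policy)
    else:
        geno = _read_dosage_tsv(path)
    miss = geno.missing_rate()
    keep = miss <= max_missing
    if not keep.all():
        n_drop = int((~keep).sum())
        logger.info("dropping %d SNPs with missingness > %.2f", n_drop, max_missing)
        geno = geno.select_snps(keep)
    return geno


def _read_vcf(path, het_policy: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise CountTableError(
                f"{path}: non-biallelic record at {var.CHROM}:{var.POS}"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dose = np.full_like(gt, np.nan)
        dose[gt == 0] = 0.0
        dose[gt == 3] = 1.0
        if np.any(gt == 1):
            if het_policy == "error":
                raise CountTableError(
                    f"{path}: heterozygous call at {var.CHROM}:{var.POS} "
                    "in haploid mode"
                )
            dose[gt == 1] = np.nan
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        rows.append(dose)
    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(accessions), 0))
    return GenotypeMatrix(accessions, np.asarray(chrom), np.asarray(pos),
                          np.asarray(ref), np.asarray(alt), dosages)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    """TSV: columns chrom, pos, ref, alt, then one column per accession."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in frame.columns]
    if missing:
        raise CountTableError(f"{path}: dosage TSV missing columns {missing}")
    accessions = [c for c in frame.columns if c not in meta_cols]
    dosages = frame[accessions].to_numpy(dtype=float).T
    return GenotypeMatrix(
        accessions,
        frame["chrom"].to_numpy(),
        frame["pos"].to_numpy(),
        frame["ref"].to_numpy(),
        frame["alt"].to_numpy(),
        dosages,
    )


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    frame = pd.DataFrame(
        {"chrom": geno.chrom, "pos": geno.pos, "ref": geno.ref, "alt": geno.alt}
    )
    for i, acc in enumerate(geno.accession_ids):
        frame[acc] = geno.dosages[i]
    frame.to_csv(path, sep="\t", index=False)


def read_gff_genes(path) -> pd.DataFrame:
    """Extract gene features from a GFF3 file.

    Returns a DataFrame with columns gene_id, chrom, start, end
    (1-based inclusive coordinates, as in GFF3).
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    frame = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                        dtype={"seqid": str})
    genes = frame[frame["type"] == "gene"].copy()
    if genes.empty:
        raise CountTableError(f"{path}: no gene features found")

    def _gene_id(attrs: str) -> str:
        for part in attrs.split(";"):
            key, _, value = part.strip().partition("=")
            if key == "ID":
                return value
        raise CountTableError(f"gene feature without ID attribute: {attrs!r}")

    genes["gene_id"] = genes["attributes"].map(_gene_id)
    return genes[["gene_id", "seqid", "start", "end"]].rename(
        columns={"seqid": "chrom"}
    ).reset_index(drop=True)


def read_go_map(path) -> pd.DataFrame:
    """Two-column TSV gene_id <tab> go_id (header required)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "go_id"):
        if col not in frame.columns:
            raise CountTableError(f"{path}: GO map missing column {col!r}")
    return frame[["gene_id", "go_id"]].drop_duplicates().reset_index(drop=True)
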