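"""Data containers, readers/writers and the count-table quality filters."""

import numpy as np
import pandas as pd
import pytest

from mkm import (CountTable, GenotypeMatrix, RunConfig, SampleMetadata,
                 maf_filter, qc_filter, read_count_table, read_genotypes,
                 read_metadata, top_taxa, write_count_table, write_genotypes,
                 write_metadata)
from mkm.datamodel import CountTableError, parse_lineage


class TestCountTable:
    def test_row_sums_of_fixture_file(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "taxon_id\tlineage\ts1\ts2\n"
            "t1\tk__Bacteria;g__A\t4\t2\n"
            "t2\tk__Bacteria;g__B\t5\t3\n"
            "t3\tk__Bacteria\t1\t0\n"
        )
        table = read_count_table(path, kingdom="bacteria")
        assert table.total_reads().tolist() == [10, 5]
        assert table.kingdom.eq("bacteria").all()

    def test_negative_count_names_the_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon_id\ts1\ns1taxon\t-1\n")
        with pytest.raises(CountTableError, match="s1taxon"):
            read_count_table(path, kingdom="bacteria")

    def test_duplicate_taxon_ids_rejected(self):
        counts = pd.DataFrame([[1, 2]], index=["s"], columns=["t", "t"])
        with pytest.raises(CountTableError, match="duplicate"):
            CountTable(counts, pd.Series("bacteria", index=["t"]),
                       pd.Series("", index=["t"]))

    def test_round_trip_identity(self, toy_table, tmp_path):
        path = tmp_path / "rt.tsv"
        write_count_table(toy_table, path)
        again = read_count_table(path, kingdom="bacteria")
        assert again == toy_table
        # writing again is bit-identical
        path2 = tmp_path / "rt2.tsv"
        write_count_table(again, path2)
        assert path.read_text() == path2.read_text()

    def test_metadata_round_trip_and_validation(self, tmp_path):
        frame = pd.DataFrame({
            "sample_id": ["a", "b"], "accession_id": ["x", "x"],
            "organ": ["leaf", "root"], "block": ["b1", "b2"],
            "run": ["r1", "r1"], "total_reads": [10, 20],
        })
        meta = SampleMetadata(frame)
        path = tmp_path / "meta.tsv"
        write_metadata(meta, path)
        again = read_metadata(path)
        pd.testing.assert_frame_equal(meta.frame, again.frame)
        with pytest.raises(CountTableError, match="organ"):
            SampleMetadata(frame.assign(organ=["leaf", "stem"]))

    def test_row_sum_check_against_metadata(self, toy_table):
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["s1", "s2", "s3"],
            "accession_id": ["x"] * 3, "organ": ["root"] * 3,
            "block": ["b"] * 3, "run": ["r"] * 3,
            "total_reads": [10, 5, 5],
        }))
        meta.check_against(toy_table)
        bad = SampleMetadata(meta.frame.assign(total_reads=[9, 5, 5]))
        with pytest.raises(CountTableError, match="s1"):
            bad.check_against(toy_table)

    def test_parse_lineage_dialect(self):
        d = parse_lineage("k__Fungi;p__Asco;c__;g__Tetracladium")
        assert d["kingdom"] == "Fungi"
        assert d["class"] == "Unassigned"
        assert d["genus"] == "Tetracladium"


class TestQcFilter:
    @staticmethod
    def _table(counts, lineages):
        counts = pd.DataFrame(counts)
        counts.index = [f"s{i}" for i in range(counts.shape[0])]
        counts.columns = [f"t{j}" for j in range(counts.shape[1])]
        return CountTable(
            counts,
            pd.Series("bacteria", index=counts.columns, dtype=object),
            pd.Series(lineages, index=counts.columns, dtype=object),
        )

    def test_singleton_and_organelle_rules(self):
        # 8 samples; t0 present in one sample only; t1 Chloroplast;
        # t2 Mitochondria; t3 kingdom-unassigned; t4 clean
        counts = np.zeros((8, 5), dtype=int)
        counts[0, 0] = 7
        counts[:, 1] = 1
        counts[:, 2] = 1
        counts[:, 3] = 1
        counts[:2, 4] = 3
        table = self._table(counts, [
            "k__Bacteria;g__A",
            "k__Bacteria;c__Chloroplast",
            "k__Bacteria;f__Mitochondria",
            "",
            "k__Bacteria;g__B",
        ])
        filtered, report = qc_filter(table)
        assert filtered.taxon_ids == ["t4"]
        assert report.singleton == ["t0"]
        assert report.chloroplast == ["t1"]
        assert report.mitochondria == ["t2"]
        assert report.unassigned_kingdom == ["t3"]

    def test_absent_taxon_reported_separately(self):
        counts = np.array([[0, 2], [0, 3]])
        table = self._table(counts, ["k__Bacteria;g__A", "k__Bacteria;g__B"])
        filtered, report = qc_filter(table)
        assert report.absent == ["t0"]
        assert filtered.taxon_ids == ["t1"]

    def test_five_taxon_toy_with_chloroplast(self):
        counts = np.ones((3, 5), dtype=int)
        lineages = ["k__Bacteria;g__%d" % j for j in range(4)]
        lineages.append("k__Bacteria;c__Chloroplast")
        filtered, _ = qc_filter(self._table(counts, lineages))
        assert filtered.n_taxa == 4

    def test_idempotent(self, small_sim):
        table = small_sim.tables["bacteria"]
        once, _ = qc_filter(table)
        twice, report2 = qc_filter(once)
        assert twice == once
        assert report2.n_removed == 0

    def test_never_removes_clean_prevalent_taxon(self, small_sim):
        table = small_sim.tables["fungi"]
        presence = (table.counts > 0).sum(axis=0)
        clean = [t for t in table.taxon_ids if presence[t] >= 2]
        filtered, _ = qc_filter(table)
        assert set(clean) <= set(filtered.taxon_ids)

    def test_per_organ_mode(self):
        # present in 1 leaf + 1 root sample: joint keeps it, per-organ drops
        counts = np.array([[1, 5], [0, 5], [1, 5], [0, 5]])
        table = self._table(counts, ["k__Bacteria;g__A", "k__Bacteria;g__B"])
        organ = pd.Series(["leaf", "leaf", "root", "root"],
                          index=table.sample_ids)
        joint, _ = qc_filter(table)
        per_organ, rep = qc_filter(table, organ_of=organ)
        assert "t0" in joint.taxon_ids
        assert "t0" in rep.singleton and "t0" not in per_organ.taxon_ids


class TestTopTaxa:
    def test_tie_breaks_lexicographically(self):
        counts = pd.DataFrame([[50, 9, 9, 1]], index=["s"],
                              columns=["a", "c", "b", "d"])
        table = CountTable(counts, pd.Series("fungi", index=counts.columns),
                           pd.Series("", index=counts.columns))
        top = top_taxa(table, 2)
        assert top.taxon_ids == ["a", "b"]

    def test_n_equal_to_taxon_count_is_identity_set(self, toy_table):
        top = top_taxa(toy_table, toy_table.n_taxa)
        assert set(top.taxon_ids) == set(toy_table.taxon_ids)

    def test_matches_brute_force_sort(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(6, 20)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"t{j:02d}" for j in range(20)],
        )
        table = CountTable(counts, pd.Series("bacteria", index=counts.columns),
                           pd.Series("", index=counts.columns))
        top = top_taxa(table, 5)
        totals = counts.sum(axis=0)
        expected = sorted(counts.columns, key=lambda t: (-totals[t], t))[:5]
        assert top.taxon_ids == expected

    def test_n_above_taxon_count_returns_all(self, toy_table):
        assert top_taxa(toy_table, 99).n_taxa == toy_table.n_taxa


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=Chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def _write_vcf(path, lines, n_samples=10):
    samples = "\t".join(f"a{i}" for i in range(n_samples))
    path.write_text(VCF_HEADER.format(samples=samples) + "".join(lines))


class TestGenotypes:
    def test_vcf_maf_filter_hand_count(self, tmp_path):
        # 10 accessions; 10 SNPs; 2 SNPs carry a single alt allele
        # (freq 0.1 > maf cut only if >= 0.05... here min_maf=0.15 drops 2)
        lines = []
        for j in range(10):
            n_alt = 1 if j < 2 else 5
            gts = ["1|1"] * n_alt + ["0|0"] * (10 - n_alt)
            lines.append(
                f"Chr1\t{100 * (j + 1)}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
        path = tmp_path / "g.vcf"
        _write_vcf(path, lines)
        geno = read_genotypes(path)
        assert geno.n_snps == 10
        kept = maf_filter(geno, min_maf=0.15)
        assert kept.n_snps == 8

    def test_het_set_missing_by_default(self, tmp_path):
        path = tmp_path / "het.vcf"
        _write_vcf(path, ["Chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t"
                          + "\t".join(["0|1"] * 3 + ["0|0"] * 7) + "\n"])
        geno = read_genotypes(path, max_missing=0.5)
        assert np.isnan(geno.dosages[:3, 0]).all()
        with pytest.raises(CountTableError, match="heterozygous"):
            read_genotypes(path, het_policy="error")

    def test_maf_boundaries(self):
        dosages = np.array([[0, 1], [0, 1], [0, 0], [1, 0],
                            [0, 1], [0, 1], [0, 0], [0, 0],
                            [0, 1], [0, 0]], dtype=float)
        geno = GenotypeMatrix([f"a{i}" for i in range(10)],
                              ["Chr1", "Chr1"], [1, 2], ["A", "A"],
                              ["T", "T"], dosages)
        # SNP0 freq 0.1 -> maf 0.1 dropped at 0.15; SNP1 freq 0.5 retained
        np.testing.assert_allclose(geno.maf(), [0.1, 0.5])
        kept = maf_filter(geno, 0.15)
        assert kept.n_snps == 1 and kept.maf()[0] == 0.5

    def test_dosage_tsv_round_trip(self, tmp_path, rng):
        dosages = rng.integers(0, 2, size=(5, 8)).astype(float)
        geno = GenotypeMatrix([f"a{i}" for i in range(5)],
                              ["Chr1"] * 8, np.arange(1, 9) * 10,
                              ["A"] * 8, ["T"] * 8, dosages)
        path = tmp_path / "g.tsv"
        write_genotypes(geno, path)
        again = read_genotypes(path)
        np.testing.assert_array_equal(geno.dosages, again.dosages)
        assert geno.accession_ids == again.accession_ids


class TestAnnotationReaders:
    def test_gff_gene_features(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "Chr1\t.\tgene\t1000\t2000\t.\t+\t.\tID=AT1G01010;Name=NAC001\n"
            "Chr1\t.\tmRNA\t1000\t2000\t.\t+\t.\tID=AT1G01010.1\n"
            "Chr2\t.\tgene\t500\t900\t.\t-\t.\tID=AT2G01008\n"
        )
        from mkm import read_gff_genes

        genes = read_gff_genes(path)
        assert genes["gene_id"].tolist() == ["AT1G01010", "AT2G01008"]
        assert genes.loc[0, "start"] == 1000 and genes.loc[0, "end"] == 2000
        assert genes.loc[1, "chrom"] == "Chr2"

    def test_go_map_dedup(self, tmp_path):
        path = tmp_path / "go.tsv"
        path.write_text("gene_id\tgo_id\ng1\tGO:1\ng1\tGO:1\ng2\tGO:2\n")
        from mkm import read_go_map

        go = read_go_map(path)
        assert len(go) == 2


class TestRunConfig:
    def test_defaults_and_yaml(self, tmp_path):
        cfg = RunConfig()
        assert (cfg.resample_depth, cfg.edge_alpha, cfg.n_permutations,
                cfg.top_n_taxa, cfg.window_bp, cfg.tail_fraction,
                cfg.fdr_q) == (400, 0.01, 999, 100, 10_000, 0.01, 0.10)
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 7\nresample_depth: 250\n")
        cfg2 = RunConfig.from_yaml(path)
        assert cfg2.seed == 7 and cfg2.resample_depth == 250

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            RunConfig(edge_alpha=0.0)
        with pytest.raises(ValueError):
            RunConfig(resample_depth=0)
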