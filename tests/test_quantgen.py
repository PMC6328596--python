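"""Kinship, REML heritability, mixed-model GWAS, windows and GO stats."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mkm import (GenotypeMatrix, SimParams, broad_sense_h2,
                 cholesky_perm_threshold, gwas_scan, kinship, ols_scan,
                 overlap_scatter, reml_h2, simulate_genotypes,
                 storey_qvalues, window_summary)
from mkm.gostats import gene_scores, go_tail_enrichment
from mkm.quantgen import GwasResult, KinshipMatrix


def _geno(n_acc=50, n_snps=400, seed=0, **kw):
    params = SimParams(n_accessions=n_acc, n_snps=n_snps, seed=seed, **kw)
    return simulate_genotypes(params)


class TestKinship:
    def test_duplicated_accessions_share_diagonal_value(self):
        g = _geno(6, 100, seed=2)
        dos = g.dosages.copy()
        dos[1] = dos[0]
        g2 = GenotypeMatrix(g.accession_ids, g.chrom, g.pos, g.ref, g.alt, dos)
        K = kinship(g2)
        assert K.values[0, 1] == pytest.approx(K.values[0, 0], abs=1e-10)

    def test_unrelated_offdiagonals_shrink_with_markers(self):
        g = _geno(40, 5000, seed=3)
        K = kinship(g)
        n = 40
        off = K.values[~np.eye(n, dtype=bool)]
        # column centering forces sum(K) = 0, so the off-diagonal mean is
        # pinned at -trace/(n(n-1)); unrelatedness shows in the spread
        pinned = -np.trace(K.values) / (n * (n - 1))
        assert off.mean() == pytest.approx(pinned, abs=1e-10)
        assert off.std() < 3.0 / np.sqrt(g.n_snps)

    def test_invariant_to_snp_order(self):
        g = _geno(10, 60, seed=4)
        perm = np.random.default_rng(0).permutation(60)
        # the GRM is a sum over SNPs, so marker order cannot matter
        K1 = kinship(g).values
        X = g.dosages[:, perm]
        X = X[:, X.std(0) > 0]  # kinship() drops monomorphic SNPs
        Z = (X - X.mean(0)) / X.std(0)
        K2 = Z @ Z.T / Z.shape[1]
        np.testing.assert_allclose(K1, K2, atol=1e-10)

    def test_monomorphic_snps_dropped(self):
        dos = np.zeros((5, 3))
        dos[:, 1] = [0, 1, 0, 1, 0]
        g = GenotypeMatrix([f"a{i}" for i in range(5)], ["Chr1"] * 3,
                           [1, 2, 3], ["A"] * 3, ["T"] * 3, dos)
        K = kinship(g)
        K.check_psd()


class TestRemlH2:
    @staticmethod
    def _structured_K(n=196, seed=2):
        g = _geno(n, 800, seed=seed)
        return kinship(g)

    def test_null_phenotype_gives_small_h2(self):
        K = self._structured_K()
        ests = []
        for seed in range(30):
            y = np.random.default_rng(seed).normal(size=196)
            ests.append(reml_h2(y, K).h2)
        assert np.median(ests) < 0.05

    def test_recovery_of_half_heritability(self):
        K = self._structured_K()
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(196))
        ests = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            y = L @ r.normal(size=196) * np.sqrt(0.5) \
                + r.normal(size=196) * np.sqrt(0.5)
            ests.append(reml_h2(y, K).h2)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_top_eigenvector_pins_h2_at_boundary(self):
        K = self._structured_K(n=60, seed=8)
        w, U = np.linalg.eigh(K.values)
        y = U[:, -1] * np.sqrt(w[-1])
        est = reml_h2(y, K)
        assert est.h2 > 0.95
        assert est.boundary or est.h2 == 1.0

    def test_optimum_beats_grid_points(self):
        from mkm.quantgen import _reml_loglik

        K = self._structured_K(n=80, seed=5)
        r = np.random.default_rng(1)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(80))
        y = L @ r.normal(size=80) * 0.6 + r.normal(size=80) * 0.8
        est = reml_h2(y, K)
        lam, U = np.linalg.eigh(K.values)
        lam = np.clip(lam, 0, None)
        yt, Xt = U.T @ y, U.T @ np.ones((80, 1))
        for h2 in (1e-9, 0.5, 1 - 1e-9):
            ll, _ = _reml_loglik(h2, yt, Xt, lam, 80, 1)
            assert est.loglik >= ll - 1e-6

    def test_estimates_stay_in_unit_interval(self):
        K = self._structured_K(n=40, seed=9)
        for seed in range(10):
            y = np.random.default_rng(seed).normal(size=40)
            est = reml_h2(y, K)
            assert 0.0 <= est.h2 <= 1.0
            assert est.sigma2_g >= 0 and est.sigma2_e >= 0


class TestBroadSense:
    @staticmethod
    def _fit_glmm(sigma2_acc, seed, q=196, reps=4, beta_block=0.4):
        from mkm.glmm import design_matrix, fit_poisson_glmm

        rng = np.random.default_rng(seed)
        u = rng.normal(0, np.sqrt(sigma2_acc), q)
        acc = np.repeat([f"a{i:03d}" for i in range(q)], reps)
        block = np.tile([f"b{j}" for j in range(reps)], q)
        off = np.log(rng.integers(300, 3000, q * reps).astype(float))
        block_eff = dict(zip(sorted(set(block)),
                             beta_block * np.arange(reps)))
        eta = -3.5 + u[np.repeat(np.arange(q), reps)] \
            + np.array([block_eff[b] for b in block]) + off
        y = rng.poisson(np.exp(eta))
        frame = pd.DataFrame({"block": block})
        X, names = design_matrix(frame, ["block"])
        fit = fit_poisson_glmm(y, X, acc, offset=off, coef_names=names)
        # true latent partition at the realized design
        s2_fixed = np.var(np.array([block_eff[b] for b in block]))
        rate = float(np.exp(np.mean(eta)))
        h2_true = sigma2_acc / (s2_fixed + sigma2_acc + np.log1p(1 / rate))
        return fit, h2_true

    def test_null_accession_variance_gives_tiny_h2(self):
        fit, _ = self._fit_glmm(0.0, seed=1)
        assert broad_sense_h2(fit).H2 < 0.02

    def test_monotone_in_accession_variance(self):
        vals = []
        for s2 in (0.1, 0.4):
            ests = [broad_sense_h2(self._fit_glmm(s2, seed=s)[0]).H2
                    for s in range(3)]
            vals.append(np.mean(ests))
        assert vals[1] > vals[0]

    def test_recovery_of_known_partition(self):
        errs = []
        for seed in range(5):
            fit, h2_true = self._fit_glmm(0.3, seed=50 + seed)
            errs.append(broad_sense_h2(fit).H2 - h2_true)
        assert abs(np.mean(errs)) < 0.1


class TestGwas:
    def test_matches_dense_gls_oracle(self):
        """30 accessions x 50 SNPs: p-values match an explicit-V GLS."""
        g = _geno(30, 50, seed=6)
        K = kinship(g)
        r = np.random.default_rng(3)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(30))
        y = L @ r.normal(size=30) + r.normal(size=30)
        res = gwas_scan(y, g, K)
        V = res.sigma2_g * K.values + res.sigma2_e * np.eye(30)
        Vi = np.linalg.inv(V)
        X0 = np.ones((30, 1))
        for j in range(50):
            x = g.dosages[:, j]
            if np.isnan(res.table["p"][j]):
                continue
            X = np.column_stack([X0, x])
            XtVi = X.T @ Vi
            A = XtVi @ X
            beta = np.linalg.solve(A, XtVi @ y)
            resid = y - X @ beta
            s2 = float(resid @ Vi @ resid) / (30 - 2)
            se = math.sqrt(s2 * np.linalg.inv(A)[1, 1])
            t = beta[1] / se
            p_ref = 2 * stats.t.sf(abs(t), 28)
            assert res.table["p"][j] == pytest.approx(p_ref, abs=1e-8)

    def test_lambda_calibrated_under_structured_null_while_ols_inflates(self):
        lambdas_lmm, lambdas_ols = [], []
        for seed in range(5):
            g = _geno(150, 1500, seed=20 + seed, n_clusters=3, fst=0.25)
            K = kinship(g)
            r = np.random.default_rng(seed)
            L = np.linalg.cholesky(K.values + 1e-8 * np.eye(150))
            y = L @ r.normal(size=150) * np.sqrt(0.6) \
                + r.normal(size=150) * np.sqrt(0.4)
            lambdas_lmm.append(gwas_scan(y, g, K).lambda_gc)
            lambdas_ols.append(ols_scan(y, g).lambda_gc)
        assert 0.9 < np.mean(lambdas_lmm) < 1.1
        assert np.mean(lambdas_ols) > 1.2

    def test_causal_snp_ranks_first_with_power(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            g = _geno(196, 300, seed=40 + seed)
            K = kinship(g)
            r = np.random.default_rng(seed)
            x = g.dosages[:, 123]
            xs = (x - x.mean()) / x.std()
            L = np.linalg.cholesky(K.values + 1e-8 * np.eye(196))
            y = xs * 1.0 + L @ r.normal(size=196) * np.sqrt(0.3) \
                + r.normal(size=196) * np.sqrt(0.7)
            res = gwas_scan(y, g, K)
            if int(np.nanargmin(res.table["p"].to_numpy())) == 123:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_joint_permutation_equivariance(self):
        g = _geno(40, 80, seed=7)
        K = kinship(g)
        r = np.random.default_rng(5)
        y = r.normal(size=40)
        res1 = gwas_scan(y, g, K)
        perm = r.permutation(40)
        g2 = GenotypeMatrix([g.accession_ids[i] for i in perm], g.chrom,
                            g.pos, g.ref, g.alt, g.dosages[perm])
        K2 = KinshipMatrix(K.values[np.ix_(perm, perm)],
                           [K.accessions[i] for i in perm])
        res2 = gwas_scan(y[perm], g2, K2)
        np.testing.assert_allclose(res1.table["p"], res2.table["p"],
                                   atol=1e-8)


class TestPermutationThreshold:
    def test_identity_kinship_reduces_to_plain_permutation(self):
        g = _geno(60, 300, seed=11)
        K = KinshipMatrix(np.eye(60), g.accession_ids)
        r = np.random.default_rng(2)
        y = r.normal(size=60)
        thr = cholesky_perm_threshold(y, g, K, n_perm=60, alpha=0.05, seed=4)
        # plain permutation reference
        minima = []
        for b in range(60):
            rp = np.random.default_rng(500 + b)
            minima.append(np.nanmin(gwas_scan(rp.permutation(y), g, K).p))
        ref = np.quantile(minima, 0.05)
        assert 0.2 < thr / ref < 5.0  # same scale within Monte-Carlo error

    def test_threshold_near_sidak_for_independent_snps(self):
        g = _geno(80, 1000, seed=12)
        K = KinshipMatrix(np.eye(80), g.accession_ids)
        y = np.random.default_rng(3).normal(size=80)
        thr = cholesky_perm_threshold(y, g, K, n_perm=100, alpha=0.05,
                                      seed=6)
        m_eff = 1000
        sidak = 1.0 - (1.0 - 0.05) ** (1.0 / m_eff)
        assert sidak / 2 < thr < sidak * 2

    def test_threshold_tightens_with_more_markers(self):
        r = np.random.default_rng(9)
        thrs = []
        for m in (100, 1000):
            g = _geno(60, m, seed=13)
            K = KinshipMatrix(np.eye(60), g.accession_ids)
            y = r.normal(size=60)
            thrs.append(cholesky_perm_threshold(y, g, K, n_perm=80,
                                                alpha=0.05, seed=8))
        assert thrs[1] < thrs[0]

    def test_too_few_permutations_refused(self):
        g = _geno(10, 20, seed=1)
        K = kinship(g)
        with pytest.raises(ValueError):
            cholesky_perm_threshold(np.zeros(10), g, K, n_perm=10)


def _gwas_from(chrom, pos, p):
    tab = pd.DataFrame({"chrom": chrom, "pos": pos,
                        "beta": 0.0, "se": 1.0, "stat": 0.0, "p": p})
    return GwasResult(table=tab, lambda_gc=1.0, sigma2_g=0.0, sigma2_e=1.0)


class TestWindows:
    def test_window_index_arithmetic(self):
        res = _gwas_from(["Chr1"], [23_179_000], [1e-7])
        out = window_summary(res, 10_000)
        assert out["window"].tolist() == [2317]

    def test_empty_windows_absent(self):
        res = _gwas_from(["Chr1", "Chr1"], [100, 25_000], [0.5, 0.1])
        out = window_summary(res, 10_000)
        assert out["window"].tolist() == [0, 2]

    def test_min_p_matches_groupby_oracle(self, rng):
        n = 300
        chrom = rng.choice(["Chr1", "Chr2"], n)
        pos = rng.integers(1, 200_000, n)
        p = rng.random(n)
        res = _gwas_from(chrom, pos, p)
        out = window_summary(res, 10_000).set_index(["chrom", "window"])
        ref = pd.DataFrame({"chrom": chrom, "window": (pos - 1) // 10_000,
                            "p": p}).groupby(["chrom", "window"])["p"].min()
        pd.testing.assert_series_equal(out["min_p"], ref.rename("min_p"),
                                       check_like=True)

    def test_overlap_join(self):
        r1 = _gwas_from(["Chr1", "Chr1"], [500, 15_000], [0.1, 0.2])
        r2 = _gwas_from(["Chr1"], [700], [0.3])
        out = overlap_scatter(r1, r2, 10_000)
        row0 = out[out["window"] == 0].iloc[0]
        assert row0["min_p_1"] == 0.1 and row0["min_p_2"] == 0.3
        assert np.isnan(out[out["window"] == 1]["min_p_2"]).all()


class TestStoreyQvalues:
    def test_pi0_one_reduces_to_bh_exactly(self, rng):
        p = rng.random(200)
        q = storey_qvalues(p, pi0=1.0)
        from statsmodels.stats.multitest import multipletests

        _, q_bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_bh, atol=1e-12)

    def test_monotone_in_p_and_bounded(self, rng):
        p = rng.random(500) ** 2
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= 0.0).all()

    def test_uniform_p_yields_almost_no_discoveries(self):
        hits, total = 0, 0
        for seed in range(10):
            p = np.random.default_rng(seed).random(400)
            q = storey_qvalues(p)
            hits += int((q < 0.10).sum())
            total += len(p)
        assert hits / total < 0.005

    def test_signal_pushes_pi0_below_one(self, rng):
        p = np.concatenate([rng.random(300),
                            rng.random(200) * 1e-4])
        q = storey_qvalues(p)
        q_bh = storey_qvalues(p, pi0=1.0)
        assert (q <= q_bh + 1e-12).all()
        assert (q[p < 1e-3] < 0.10).all()


class TestGoEnrichment:
    def test_gene_scores_min_p_within_window(self, rng):
        genes = pd.DataFrame({
            "gene_id": ["gA", "gB"], "chrom": ["Chr1", "Chr1"],
            "start": [1000, 100_000], "end": [2000, 101_000],
        })
        res = _gwas_from(["Chr1"] * 3, [1500, 11_500, 150_000],
                         [0.5, 0.01, 0.9])
        s = gene_scores(res, genes, window_bp=10_000)
        # gA window [−9000, 12000]: SNPs at 1500 (0.5) and 11500 (0.01)
        assert s["gA"] == pytest.approx(0.01)
        assert "gB" not in s.index  # nearest SNP 39 kb away

    def test_constructed_tail_category_matches_closed_form(self, rng):
        n_genes, cat_size, k_in_tail = 1000, 20, 10
        genes = pd.DataFrame({
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "chrom": "Chr1",
            "start": np.arange(n_genes) * 50_000 + 1,
            "end": np.arange(n_genes) * 50_000 + 2000,
        })
        p = rng.uniform(0.1, 1.0, n_genes)
        tail_idx = np.arange(10)
        p[tail_idx] = 1e-8
        res = _gwas_from(["Chr1"] * n_genes,
                         (np.arange(n_genes) * 50_000 + 500).tolist(),
                         p.tolist())
        cat_genes = [f"g{i:04d}" for i in range(cat_size)]  # 10 tail + 10 not
        other = pd.DataFrame({
            "gene_id": [f"g{i:04d}" for i in range(100, 600)],
            "go_id": "GO:other",
        })
        go_map = pd.concat([
            pd.DataFrame({"gene_id": cat_genes, "go_id": "GO:hit"}), other,
        ])
        out = go_tail_enrichment(res, genes, go_map, tail_fraction=0.01,
                                 window_bp=0)
        row = out[out["category"] == "GO:hit"].iloc[0]
        expected = 10 * 20 / 1000  # n_tail * K / N
        assert row["observed"] == k_in_tail
        assert row["ratio"] == pytest.approx(k_in_tail / expected)
        # hypergeometric by explicit enumeration
        p_exact = sum(
            math.comb(20, kk) * math.comb(980, 10 - kk) / math.comb(1000, 10)
            for kk in range(10, 11)
        )
        assert row["p"] == pytest.approx(p_exact, rel=1e-9)

    def test_small_categories_excluded(self, rng):
        genes = pd.DataFrame({
            "gene_id": ["gA", "gB", "gC"], "chrom": "Chr1",
            "start": [1, 10_001, 20_001], "end": [500, 10_500, 20_500],
        })
        res = _gwas_from(["Chr1"] * 3, [100, 10_100, 20_100],
                         [0.001, 0.5, 0.9])
        go_map = pd.DataFrame({"gene_id": ["gA", "gB", "gC"],
                               "go_id": ["GO:solo", "GO:pair", "GO:pair"]})
        out = go_tail_enrichment(res, genes, go_map, tail_fraction=0.34,
                                 window_bp=0, min_category_size=2)
        assert "GO:solo" not in set(out["category"])
        assert "GO:pair" in set(out["category"])
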