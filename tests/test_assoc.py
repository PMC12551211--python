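"""GRM, REML variance components, mixed-model scan and QTL grouping."""

import numpy as np
import pytest

from pangraphsv import assoc
from pangraphsv import synthetic_data as sd
from pangraphsv.assoc import (AssocResult, bonferroni, compute_grm,
                              fit_null_reml, gls_single_marker, group_qtl,
                              ld_r2, mlma_scan, reml_loglik_grid,
                              scs_transform)


def hwe_dosages(rng, n, m):
    return rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)


class TestGRM:
    def test_duplicate_rows_share_relationship(self):
        rng = np.random.default_rng(0)
        X = hwe_dosages(rng, 5, 400)
        X[1] = X[0]
        G = compute_grm(X)
        assert G[0, 1] == pytest.approx(G[0, 0])
        assert G[0, 1] == pytest.approx(G[1, 1])

    def test_hwe_diagonal_near_one(self):
        rng = np.random.default_rng(1)
        G = compute_grm(hwe_dosages(rng, 200, 2000))
        assert 0.95 <= float(np.diag(G).mean()) <= 1.05

    def test_symmetric_psd(self):
        rng = np.random.default_rng(2)
        G = compute_grm(hwe_dosages(rng, 50, 500))
        assert np.allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            compute_grm(np.zeros((10, 5)))


class TestREML:
    def test_identity_g_sum_identified_and_flagged(self):
        """With G = I and D = I only sigma_u2 + sigma_e2 is identified;
        the fit flags the boundary and conserves the total variance."""
        rng = np.random.default_rng(3)
        y = rng.standard_normal(200)
        null = fit_null_reml(y, np.eye(200))
        assert null.boundary
        total = null.sigma_u2 + null.sigma_e2
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.1)

    def test_optimum_beats_lambda_grid(self):
        rng = np.random.default_rng(4)
        snp = sd.simulate_halfsib_genotypes(12, 10, 600, rng)
        n = len(snp)
        G = compute_grm(snp.to_numpy())
        L = np.linalg.cholesky(G + 1e-6 * np.eye(n))
        w = rng.uniform(0.5, 2.0, n)
        y = np.sqrt(0.5) * (L @ rng.standard_normal(n)) \
            + rng.standard_normal(n) * np.sqrt(0.5 / w)
        D = np.diag(1.0 / w)
        null = fit_null_reml(y, G, D)
        grid = reml_loglik_grid(y, G, D, np.linspace(-8, 8, 50))
        assert null.loglik >= grid.max() - 1e-6

    def test_h2_recovery_over_seeds(self):
        """Half-sib families, h2 = 0.5, n = 500: the median estimate over
        20 seeds lands within +/-0.15 of the truth."""
        h2s = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            snp = sd.simulate_halfsib_genotypes(50, 10, 2000, rng)
            n = len(snp)
            G = compute_grm(snp.to_numpy())
            L = np.linalg.cholesky(G + 1e-6 * np.eye(n))
            w = rng.uniform(0.5, 2.0, n)
            y = np.sqrt(0.5) * (L @ rng.standard_normal(n)) \
                + rng.standard_normal(n) * np.sqrt(0.5 / w)
            null = fit_null_reml(y, G, np.diag(1.0 / w))
            h2s.append(null.sigma_u2 / (null.sigma_u2 + null.sigma_e2))
        assert 0.35 <= float(np.median(h2s)) <= 0.65

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            fit_null_reml(np.zeros(5), np.eye(5))


class TestScan:
    def test_reduces_to_ols_when_no_polygenic_term(self):
        rng = np.random.default_rng(5)
        n, m = 80, 12
        X = hwe_dosages(rng, n, m)
        y = rng.standard_normal(n)
        res = mlma_scan(y, X, np.eye(n), sigma_u2=1e-12, sigma_e2=1.0)
        for j, r in enumerate(res):
            x = X[:, j]
            slope = np.polyfit(x, y, 1)[0]
            assert r.beta == pytest.approx(slope, rel=1e-6, abs=1e-10)

    def test_matches_explicit_inverse_gls(self):
        """Eigendecomposition route equals brute-force V^-1 GLS (n <= 50)."""
        rng = np.random.default_rng(6)
        n, m = 50, 30
        snp = sd.simulate_halfsib_genotypes(10, 5, 500, rng)
        G = compute_grm(snp.to_numpy())
        w = rng.uniform(0.5, 2.0, n)
        D = np.diag(1.0 / w)
        y = rng.standard_normal(n)
        X = hwe_dosages(rng, n, m)
        su2, se2 = 0.6, 0.4
        res = mlma_scan(y, X, G, su2, se2, D)
        V = su2 * G + se2 * D
        for j, r in enumerate(res):
            if r.monomorphic:
                continue
            b, se, p = gls_single_marker(y, X[:, j], V)
            assert r.beta == pytest.approx(b, rel=1e-8)
            assert r.se == pytest.approx(se, rel=1e-8)
            assert r.p_value == pytest.approx(p, rel=1e-6)

    def test_null_p_values_uniform(self):
        """Pooled p-values under the null pass a KS uniformity check."""
        from scipy import stats

        pooled = []
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            n = 300
            Xg = hwe_dosages(rng, n, 1500)
            G = compute_grm(Xg)
            L = np.linalg.cholesky(G + 1e-6 * np.eye(n))
            w = rng.uniform(0.5, 2.0, n)
            y = np.sqrt(0.3) * (L @ rng.standard_normal(n)) \
                + rng.standard_normal(n) * np.sqrt(0.7 / w)
            Xt = hwe_dosages(rng, n, 500)
            null = fit_null_reml(y, G, np.diag(1.0 / w))
            res = mlma_scan(y, Xt, G, null.sigma_u2, null.sigma_e2,
                            np.diag(1.0 / w))
            pooled.extend(r.p_value for r in res)
        ks = stats.kstest(pooled, "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_marker_flagged_p_one(self):
        rng = np.random.default_rng(7)
        n = 40
        X = np.column_stack([np.full(n, 2.0), hwe_dosages(rng, n, 1)[:, 0]])
        res = mlma_scan(rng.standard_normal(n), X, np.eye(n), 0.1, 1.0)
        assert res[0].monomorphic and res[0].p_value == 1.0
        assert not res[1].monomorphic


class TestThresholdsAndTransforms:
    @pytest.mark.parametrize("alpha,m,thr,neglog", [
        (0.05, 58191, 8.59e-7, 6.07),
        (0.05, 1, 0.05, 1.301),
        (0.05, 20, 2.5e-3, 2.602),
    ])
    def test_bonferroni(self, alpha, m, thr, neglog):
        got_thr, got_neglog = bonferroni(alpha, m)
        assert got_thr == pytest.approx(thr, rel=1e-2)
        assert got_neglog == pytest.approx(neglog, abs=5e-3)

    def test_bonferroni_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)

    @pytest.mark.parametrize("scc,scs", [(100_000, 3), (200_000, 4),
                                         (50_000, 2)])
    def test_scs_transform(self, scc, scs):
        assert scs_transform(scc) == pytest.approx(scs)

    def test_scs_requires_positive_count(self):
        with pytest.raises(ValueError):
            scs_transform(0)


def _result(mid, p, pos, chrom="chr1"):
    return AssocResult(marker_id=mid, beta=1.0, se=0.1, p_value=p,
                       chromosome=chrom, position=pos)


class TestGroupQTL:
    def test_single_significant_marker_single_region(self):
        rng = np.random.default_rng(8)
        X = hwe_dosages(rng, 50, 2)
        res = [_result("m1", 1e-9, 100), _result("m2", 0.5, 200)]
        regions = group_qtl(res, X, threshold_neglogp=6.0)
        assert len(regions) == 1
        assert regions[0].peak.marker_id == "m1"

    def test_ld_decides_region_membership(self):
        rng = np.random.default_rng(9)
        n = 200
        x1 = hwe_dosages(rng, n, 1)[:, 0]
        x_same = x1.copy()                       # r2 = 1
        x_other = hwe_dosages(rng, n, 1)[:, 0]   # r2 ~ 0
        res = [_result("m1", 1e-9, 1_000_000),
               _result("m2", 1e-8, 2_000_000)]
        X_linked = np.column_stack([x1, x_same])
        X_unlinked = np.column_stack([x1, x_other])
        assert len(group_qtl(res, X_linked, 6.0)) == 1
        assert len(group_qtl(res, X_unlinked, 6.0)) == 2

    def test_no_significant_markers_empty(self):
        rng = np.random.default_rng(10)
        X = hwe_dosages(rng, 30, 1)
        assert group_qtl([_result("m1", 0.9, 5)], X, 6.0) == []

    def test_two_planted_loci_two_regions(self):
        """Two causal loci 30 Mb apart with tight local LD blocks give
        exactly two QTL regions, each containing its causal marker."""
        rng = np.random.default_rng(11)
        n, m = 400, 120
        pos = np.sort(rng.integers(0, 60_000_000, m))
        X = hwe_dosages(rng, n, m)
        c1 = int(np.argmin(np.abs(pos - 10e6)))
        c2 = int(np.argmin(np.abs(pos - 40e6)))
        for j in range(m):
            for c in (c1, c2):
                if j != c and abs(pos[j] - pos[c]) < 1.5e6:
                    copy = rng.random(n) < 0.98
                    X[:, j] = np.where(copy, X[:, c], X[:, j])
        y = 0.6 * X[:, c1] - 0.6 * X[:, c2] + rng.standard_normal(n)
        res = mlma_scan(y, X, np.eye(n), 1e-9, 1.0, positions=pos)
        regions = group_qtl(res, X, threshold_neglogp=5.0,
                            window_bp=10e6, r2_threshold=0.7)
        assert len(regions) == 2
        member_ids = [{r.marker_id for r in reg.members} for reg in regions]
        assert any(f"m{c1 + 1}" in ids for ids in member_ids)
        assert any(f"m{c2 + 1}" in ids for ids in member_ids)

    def test_output_partitions_significant_markers(self):
        rng = np.random.default_rng(12)
        n, m = 150, 40
        X = hwe_dosages(rng, n, m)
        y = X[:, 3] + rng.standard_normal(n)
        res = mlma_scan(y, X, np.eye(n), 1e-9, 1.0,
                        positions=np.arange(m) * 100_000)
        thr = 2.0
        regions = group_qtl(res, X, thr)
        sig = {r.marker_id for r in res if r.neg_log10_p >= thr}
        grouped = [r.marker_id for reg in regions for r in reg.members]
        assert sorted(grouped) == sorted(sig)      # partition, no duplicates
        for reg in regions:
            assert reg.peak.p_value == min(r.p_value for r in reg.members)

    def test_ld_r2_of_identical_vectors(self):
        rng = np.random.default_rng(13)
        x = hwe_dosages(rng, 100, 1)[:, 0]
        assert ld_r2(x, x) == pytest.approx(1.0)
        assert ld_r2(x, np.full(100, 1.0)) == 0.0


class TestPower:
    def test_planted_effect_recovered_and_ranked(self):
        """A marker explaining 5% of variance is the top hit in >=18/20
        seeds and its median effect estimate is within 20% of truth."""
        hits, ratios = 0, []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            snp = sd.simulate_halfsib_genotypes(80, 10, 1200, rng)
            G = compute_grm(snp.to_numpy())
            cfg = sd.SimConfig(h2=0.3, causal_var_frac=0.05)
            causal = "snp77"
            pheno, truth = sd.simulate_phenotypes(
                snp, G, cfg, causal_marker=causal, seed=1000 + seed)
            y = pheno["dyd"].to_numpy()
            D = np.diag(1.0 / pheno["weight"].to_numpy())
            null = fit_null_reml(y, G, D)
            res = mlma_scan(y, snp.to_numpy(), G, null.sigma_u2,
                            null.sigma_e2, D, marker_ids=list(snp.columns))
            top = min(res, key=lambda r: r.p_value)
            if top.marker_id == causal:
                hits += 1
            bhat = next(r.beta for r in res if r.marker_id == causal)
            ratios.append(bhat / truth["beta"])
        assert hits >= 18
        assert abs(float(np.median(ratios)) - 1.0) <= 0.2
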