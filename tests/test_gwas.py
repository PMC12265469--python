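"""SNP filtering, kinship, the mixed-model scan, and window statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pestgs.core import MISSING, GenotypeMatrix, SimCohortSpec
from pestgs.gwas import (
    filter_snps,
    genomic_lambda,
    kinship,
    ld_r2,
    lmm_assoc,
    significant_hits,
    window_fst,
    window_pi,
)
from pestgs.gwas.filters import EmptyFilterResult
from pestgs.simdata import simulate_genotypes, simulate_phenotypes


def _matrix(dosages, pos=None, chrom=None):
    dosages = np.asarray(dosages, dtype=np.int16)
    n, m = dosages.shape
    pos = np.asarray(pos) if pos is not None else np.arange(1, m + 1) * 100
    chrom = np.asarray(chrom) if chrom is not None else np.ones(m, dtype=int)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"s{i}" for i in range(m)]),
        chrom=chrom,
        pos=pos,
        ref=np.full(m, "A"),
        alt=np.full(m, "T"),
        sample_ids=np.array([f"i{i}" for i in range(n)]),
    )


class TestFilters:
    def test_missingness_boundary(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (100, 3)).astype(np.int16)
        d[:6, 0] = MISSING  # 6% missing -> removed
        d[:5, 1] = MISSING  # exactly 5% -> retained
        G = filter_snps(_matrix(d))
        assert list(G.snp_ids) == ["s1", "s2"]

    def test_maf_boundary_and_monomorphic(self):
        n = 100
        d = np.zeros((n, 3), dtype=np.int16)
        d[:, 1] = 1  # all het: maf 0.5
        d[:5, 2] = 2  # maf exactly 0.05
        G = filter_snps(_matrix(d))
        assert list(G.snp_ids) == ["s1", "s2"]

    def test_idempotent(self, small_cohort):
        _, G, _, _ = small_cohort
        once = filter_snps(G)
        twice = filter_snps(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_all_removed_signalled(self):
        d = np.zeros((10, 2), dtype=np.int16)
        with pytest.raises(EmptyFilterResult):
            filter_snps(_matrix(d))


class TestKinship:
    def test_duplicated_individuals(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (20, 200)).astype(np.int16)
        d[1] = d[0]
        K = kinship(_matrix(d))
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-12)
        assert K[0, 1] == pytest.approx(K[1, 1], rel=1e-12)

    def test_unrelateds_near_zero_offdiagonal(self, unstructured_cohort):
        _, G = unstructured_cohort
        K = kinship(G)
        off = K[~np.eye(len(K), dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_positive_semidefinite(self, small_cohort):
        _, G, _, _ = small_cohort
        K = kinship(G)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestLmm:
    def test_zero_kinship_reduces_to_ols(self):
        # 50 random small instances against a closed-form OLS oracle
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(30, 60))
            d = rng.integers(0, 3, (n, 3)).astype(np.int16)
            if any(np.std(d[:, j]) == 0 for j in range(3)):
                continue
            y = rng.standard_normal(n)
            res = lmm_assoc(y, _matrix(d), np.zeros((n, n)))
            for j in range(3):
                X = np.column_stack([np.ones(n), d[:, j]])
                b = np.linalg.lstsq(X, y, rcond=None)[0]
                resid = y - X @ b
                s2 = resid @ resid / (n - 2)
                se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
                p = stats.chi2.sf((b[1] / se) ** 2, df=1)
                assert res.beta[j] == pytest.approx(b[1], abs=1e-8)
                assert res.se[j] == pytest.approx(se, abs=1e-8)
                assert res.p_wald[j] == pytest.approx(p, abs=1e-8)

    def test_planted_qtl_recovered(self):
        spec = SimCohortSpec(n_samples=250, n_snps=400, n_qtl=1, h2=0.3, seed=77)
        G = filter_snps(simulate_genotypes(spec))
        ph, qtl = simulate_phenotypes(G, spec)
        # map planted indices through the filter by snp id
        res = lmm_assoc(ph.continuous, G, kinship(G))
        assert res.p_wald.min() < 1e-5
        top = int(np.nanargmin(res.p_wald.to_numpy()))
        assert abs(res.pos[top] - res.pos[qtl[0]]) <= 5000  # within the LD block

    def test_null_variance_components_recovered(self):
        spec = SimCohortSpec(n_samples=250, n_snps=1500, seed=13)
        G = filter_snps(simulate_genotypes(spec))
        K = kinship(G)
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(len(K)))
        u = L @ rng.standard_normal(len(K))
        y = np.sqrt(0.5) * u / u.std() + np.sqrt(0.5) * rng.standard_normal(len(K))
        res = lmm_assoc(y, G, K)
        assert 0.25 <= res.attrs["null_pve"] <= 0.75

    def test_covariate_path_matches_interceptonly_when_trivial(self):
        rng = np.random.default_rng(4)
        spec = SimCohortSpec(n_samples=60, n_snps=30, n_qtl=5, seed=5)
        G = simulate_genotypes(spec)
        keep = filter_snps(G)
        y = rng.standard_normal(60)
        K = kinship(keep)
        base = lmm_assoc(y, keep, K)
        with_w = lmm_assoc(y, keep, K, W=np.ones((60, 1)))
        np.testing.assert_allclose(base.beta, with_w.beta, atol=1e-6)
        np.testing.assert_allclose(base.p_wald, with_w.p_wald, atol=1e-6)

    def test_nonfinite_phenotype_rejected(self, small_cohort):
        _, G, _, _ = small_cohort
        y = np.zeros(G.n_samples)
        y[0] = np.nan
        with pytest.raises(ValueError):
            lmm_assoc(y, G, np.eye(G.n_samples))


class TestSignificantHits:
    def _assoc(self, chrom, pos, p):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "snp_id": [f"s{i}" for i in range(len(pos))],
                "p_wald": p,
            }
        )

    def test_no_hits(self):
        assoc = self._assoc([1, 1], [100, 200], [0.5, 0.5])
        assert significant_hits(assoc) == []

    def test_nearby_hits_merge(self):
        assoc = self._assoc([1, 1, 2], [10_000, 20_000, 10_000], [1e-7, 1e-6, 1e-8])
        hits = significant_hits(assoc, merge_kb=50)
        assert len(hits) == 2
        first = next(h for h in hits if h.chrom == 1)
        assert len(first.members) == 2
        assert first.lead_snp == "s0" and first.pos_lo == 10_000 and first.pos_hi == 20_000

    def test_distant_hits_split(self):
        assoc = self._assoc([1, 1], [10_000, 500_000], [1e-7, 1e-7])
        assert len(significant_hits(assoc, merge_kb=100)) == 2


class TestWindowStats:
    def test_fst_extremes(self):
        d = np.zeros((8, 1), dtype=np.int16)
        d[4:, 0] = 2  # pop2 fixed for alt, pop1 fixed for ref
        G = _matrix(d)
        labels = np.array([0] * 4 + [1] * 4)
        ws = window_fst(G, labels, window_bp=1000)
        assert ws[0].value == pytest.approx(1.0)

        d2 = np.tile(np.array([0, 1, 2, 1], dtype=np.int16)[:, None], (2, 1))
        ws2 = window_fst(_matrix(d2), labels, window_bp=1000)
        assert ws2[0].value == pytest.approx(0.0, abs=1e-9)

    def test_fst_and_pi_match_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (20, 8)).astype(np.int16)
        pos = (np.arange(8) + 1) * 100
        G = _matrix(d, pos=pos)
        labels = np.array([0] * 10 + [1] * 10)
        ws = window_fst(G, labels, window_bp=1000)
        p1 = d[:10].mean(axis=0) / 2
        p2 = d[10:].mean(axis=0) / 2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / 19 - p2 * (1 - p2) / 19
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert ws[0].value == pytest.approx(
            np.clip(num.sum() / den.sum(), 0, 1), abs=1e-10
        )
        pi = window_pi(G, window_bp=1000)
        p = d.mean(axis=0) / 2
        expect = float(np.sum(2 * p * (1 - p) * 40 / 39) / 1000)
        assert pi[0].value == pytest.approx(expect, abs=1e-10)

    def test_pi_examples(self):
        d = np.zeros((500, 2), dtype=np.int16)
        d[:250, 0] = 2  # p = 0.5
        G = _matrix(d, pos=np.array([10, 20]))
        pi = window_pi(G, window_bp=1000)
        assert pi[0].value == pytest.approx(0.0005, rel=2e-3)
        pi2 = window_pi(G, window_bp=2000)
        assert pi2[0].value == pytest.approx(pi[0].value / 2)

    def test_monomorphic_window_zero(self):
        d = np.full((10, 3), 1, dtype=np.int16)
        d[:, :] = 0
        d[0, 0] = 0
        assert window_pi(_matrix(d), window_bp=500)[0].value == 0.0

    def test_single_population_rejected(self):
        d = np.zeros((6, 2), dtype=np.int16)
        with pytest.raises(ValueError):
            window_fst(_matrix(d), np.zeros(6, dtype=int), window_bp=100)


class TestLdR2:
    def test_identical_and_anticorrelated(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, 50).astype(np.int16)
        d = np.column_stack([x, x, 2 - x])
        G = _matrix(d)
        assert ld_r2(G, 0, 1) == pytest.approx(1.0)
        assert ld_r2(G, 0, 2) == pytest.approx(1.0)

    def test_independent_pairs_near_one_over_n(self):
        rng = np.random.default_rng(8)
        n = 500
        vals = []
        for _ in range(1000):
            a = rng.binomial(2, 0.3, n).astype(np.int16)
            b = rng.binomial(2, 0.3, n).astype(np.int16)
            if a.std() == 0 or b.std() == 0:
                continue
            G = _matrix(np.column_stack([a, b]))
            vals.append(ld_r2(G, 0, 1))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1 / n) <= 3 * se + 2e-4

    def test_monomorphic_rejected(self):
        d = np.zeros((10, 2), dtype=np.int16)
        d[:5, 0] = 1
        with pytest.raises(ValueError):
            ld_r2(_matrix(d), 0, 1)


def test_genomic_lambda_of_uniform_pvalues():
    rng = np.random.default_rng(9)
    lam = genomic_lambda(rng.uniform(size=20_000))
    assert 0.95 <= lam <= 1.05
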