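"""Case-control association, EM haplotype estimation, LD and blocks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sweepscan import assoc

from conftest import make_table


def pheno_frame(statuses, samples=None):
    samples = samples or [f"s{i + 1}" for i in range(len(statuses))]
    return pd.DataFrame({"sample_id": samples, "status": statuses})


class TestSnpAssociation:
    def test_identical_allele_counts_null(self):
        # cases and controls with the same allele counts: chi2 = 0, p = 1
        group = [(0, 1)] * 10 + [(1, 1)] * 10
        t = make_table([group + group])
        res = assoc.snp_association(t, pheno_frame(
            ["case"] * 20 + ["control"] * 20))
        row = res.iloc[0]
        assert row["chi2"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_worked_chi_square_value(self):
        """Allele table (30,70 | 50,50) gives chi2 = 8.333, p ~ 0.0039."""
        cases = [(1, 1)] * 15 + [(0, 0)] * 35
        controls = [(1, 1)] * 25 + [(0, 0)] * 25
        t = make_table([cases + controls])
        res = assoc.snp_association(t, pheno_frame(
            ["case"] * 50 + ["control"] * 50))
        row = res.iloc[0]
        assert row["test"] == "chi2"
        assert row["chi2"] == pytest.approx(200 * (30 * 50 - 70 * 50) ** 2
                                            / (100 * 100 * 80 * 120))
        assert row["p"] == pytest.approx(0.0039, abs=2e-4)

    def test_perfect_separation_extreme_p(self):
        t = make_table([[(1, 1)] * 50 + [(0, 0)] * 50])
        res = assoc.snp_association(t, pheno_frame(
            ["case"] * 50 + ["control"] * 50))
        assert res.iloc[0]["p"] < 1e-20

    def test_monomorphic_snp_skipped(self):
        t = make_table([[(0, 0)] * 6, [(0, 1)] * 6])
        res = assoc.snp_association(t, pheno_frame(["case"] * 3 + ["control"] * 3))
        assert res["tested"].tolist() == [False, True]
        assert np.isnan(res.iloc[0]["p"])

    def test_sparse_table_uses_exact_test(self):
        t = make_table([[(0, 1), (0, 0), (0, 0), (0, 0)]])
        res = assoc.snp_association(t, pheno_frame(
            ["case", "case", "control", "control"]))
        assert res.iloc[0]["test"] == "fisher"

    def test_too_few_cases_rejected(self):
        t = make_table([[(0, 1), (0, 0)]])
        with pytest.raises(ValueError):
            assoc.snp_association(t, pheno_frame(["case", "control"]))

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(4)
        rows = [[tuple(rng.integers(0, 2, 2)) for _ in range(20)]
                for _ in range(30)]
        t = make_table(rows)
        res = assoc.snp_association(t, pheno_frame(
            ["case"] * 10 + ["control"] * 10))
        tested = res[res["tested"]]
        assert (tested["q"] >= tested["p"] - 1e-12).all()


def grid_loglik(geno_counts, f):
    """Multinomial log-likelihood of 2-SNP genotype counts given hap freqs."""
    # haplotype order 00, 10, 01, 11
    ll = 0.0
    for (g1, g2), cnt in geno_counts.items():
        p = 0.0
        for h1, h2 in itertools.product(range(4), repeat=2):
            a1, b1 = h1 & 1, (h1 >> 1) & 1
            a2, b2 = h2 & 1, (h2 >> 1) & 1
            if a1 + a2 == g1 and b1 + b2 == g2:
                p += f[h1] * f[h2]
        ll += cnt * np.log(max(p, 1e-300))
    return ll


class TestEmHaplotypes:
    def test_unambiguous_genotypes_equal_gamete_counts(self):
        # no multi-site heterozygotes: EM fixed point is direct counting
        g = np.array([[2, 2]] * 3 + [[0, 0]] * 5 + [[2, 0]] * 2)
        em = assoc.em_haplotypes(g, seed=0)
        present = em.present()
        assert present[(1, 1)] == pytest.approx(6 / 20)
        assert present[(0, 0)] == pytest.approx(10 / 20)
        assert present[(1, 0)] == pytest.approx(4 / 20)

    def test_coupling_resolved_toward_likelihood_maximum(self):
        """40 AABB + 40 aabb + 20 AaBb converges to pAB ~ pab ~ 0.5."""
        g = np.array([[2, 2]] * 40 + [[0, 0]] * 40 + [[1, 1]] * 20)
        em = assoc.em_haplotypes(g, seed=0)
        f = em.frequencies  # order 00, 10, 01, 11
        assert f[0] == pytest.approx(0.5, abs=0.01)
        assert f[3] == pytest.approx(0.5, abs=0.01)
        assert f[1] + f[2] < 0.01
        # cross-check against exhaustive grid maximisation of the likelihood
        counts = {(2, 2): 40, (0, 0): 40, (1, 1): 20}
        best = max(
            ((a, b, c, 1 - a - b - c)
             for a in np.linspace(0, 1, 51) for b in np.linspace(0, 1 - a, 26)
             for c in np.linspace(0, 1 - a - b, 26)),
            key=lambda f4: grid_loglik(counts, f4))
        assert em.log_likelihood >= grid_loglik(counts, best) - 1e-3

    def test_loglik_nondecreasing_trace(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(50, 3))
        em = assoc.em_haplotypes(g, seed=1)
        trace = np.asarray(em.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()

    def test_recovers_realized_frequencies(self):
        """3 SNPs, 4 true haplotypes, n=200: estimates track the gamete pool."""
        rng = np.random.default_rng(123)
        haps = np.array([[0, 0, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1]])
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        draws = rng.choice(4, size=(200, 2), p=freqs)
        genotypes = haps[draws[:, 0]] + haps[draws[:, 1]]
        realized = np.bincount(draws.ravel(), minlength=4) / 400
        em = assoc.em_haplotypes(genotypes, seed=0)
        est = {h: em.frequencies[sum(b << i for i, b in enumerate(h))]
               for h in map(tuple, haps)}
        for k, h in enumerate(map(tuple, haps)):
            assert est[h] == pytest.approx(realized[k], abs=0.03)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            assoc.em_haplotypes(np.zeros((4, 9)))

    def test_all_missing_snp_dropped(self):
        g = np.array([[1.0, np.nan], [2.0, np.nan], [0.0, np.nan]])
        em = assoc.em_haplotypes(g, seed=0)
        assert len(em.haplotypes) == 2  # one SNP left -> 2 haplotypes


class TestLdStats:
    def test_complete_coupling(self):
        d, dp, r2 = assoc.ld_stats(0.5, 0.5, 0.5)
        assert dp == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_equilibrium(self):
        d, dp, r2 = assoc.ld_stats(0.3 * 0.6, 0.3, 0.6)
        assert d == pytest.approx(0.0) and r2 == pytest.approx(0.0)

    def test_worked_intermediate_example(self):
        # pAB=0.4, pAb=0.1, paB=0.1, pab=0.4
        d, dp, r2 = assoc.ld_stats(0.4, 0.5, 0.5)
        assert d == pytest.approx(0.15)
        assert dp == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_fixed_snp_undefined(self):
        with pytest.raises(ValueError):
            assoc.ld_stats(0.5, 1.0, 0.5)


class TestDefineBlock:
    def test_perfect_ld_single_block(self):
        r2 = np.ones((3, 3))
        block = assoc.define_block([10, 20, 30], r2)
        assert block.positions == [10, 20, 30]
        assert (block.start, block.end) == (10, 30)

    def test_chain_break_limits_block(self):
        r2 = np.array([[1.0, 0.9, 0.1],
                       [0.9, 1.0, 0.1],
                       [0.1, 0.1, 1.0]])
        block = assoc.define_block([10, 20, 30], r2)
        assert block.positions == [10, 20]

    def test_interior_weak_pair_ties_break_leftmost(self):
        r2 = np.ones((4, 4))
        r2[1, 3] = r2[3, 1] = 0.4  # breaks any run containing both 1 and 3
        block = assoc.define_block([10, 20, 30, 40], r2)
        assert block.positions == [10, 20, 30]

    def test_no_passing_pair_returns_none(self):
        r2 = np.full((3, 3), 0.1)
        np.fill_diagonal(r2, 1.0)
        assert assoc.define_block([10, 20, 30], r2) is None


class TestEndToEndBlock:
    def test_block_and_haplotypes_from_genotypes(self):
        """Two tightly linked SNPs + one unlinked: block spans the pair."""
        rng = np.random.default_rng(33)
        n = 120
        hap_pair = rng.random(2 * n) < 0.4
        linked = np.column_stack([hap_pair[:n] + hap_pair[n:],
                                  hap_pair[:n] + hap_pair[n:]]).astype(float)
        unlinked = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        t = make_table(np.stack([np.column_stack([g >= 1, g == 2])
                                 for g in np.hstack([linked, unlinked]).T],
                                axis=0).astype(np.int8),
                       positions=[100, 200, 5000])
        block = assoc.analyse_block(t, [0, 1, 2], seed=0)
        assert block is not None
        assert block.positions == [100, 200]
        assert len(block.em.present()) == 2
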