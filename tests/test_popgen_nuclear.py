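"""Microsatellite estimators against hand values and brute-force oracles."""

import itertools

import numpy as np
import pytest

from seascape import popgen_nuclear as pn
from seascape.datatypes import MISSING, GenotypeTable

from conftest import random_hwe_table


def table(genotypes, loci=None):
    """Build a table from a list of per-individual locus call lists."""
    arr = np.array(genotypes, dtype=np.int32)
    n, L = arr.shape[0], arr.shape[1]
    loci = loci or [f"L{j}" for j in range(L)]
    return GenotypeTable([f"i{k}" for k in range(n)], loci, arr)


class TestHeterozygosity:
    def test_hand_example_two_heterozygotes(self):
        # He = (2n/(2n-1))(1 - sum p^2) = (4/3)(1 - 0.5) = 2/3
        g = table([[[1, 2]], [[1, 2]]])
        res = pn.heterozygosity_fis(g, ["x", "x"])
        assert res.Ho.iloc[0] == 1.0
        assert res.He.iloc[0] == pytest.approx(2 / 3)
        assert res.FIS.iloc[0] < 0

    def test_all_homozygous(self):
        g = table([[[1, 1]], [[1, 1]], [[1, 1]]])
        res = pn.heterozygosity_fis(g, ["x"] * 3)
        assert res.Ho.iloc[0] == 0.0
        assert res.He.iloc[0] == 0.0
        assert not res.fis_defined.iloc[0]

    def test_random_mating_fis_near_zero(self, rng):
        g = random_hwe_table(rng, 400, 8)
        res = pn.heterozygosity_fis(g, ["x"] * 400)
        # |FIS| under HWE ~ O(1/sqrt(2nL)); 3 SE bound
        assert abs(res.FIS.iloc[0]) < 3 / np.sqrt(2 * 400 * 8)

    def test_he_unbiased_under_subsampling(self, rng):
        g = random_hwe_table(rng, 300, 4)
        full = pn.heterozygosity_fis(g, ["x"] * 300).He.iloc[0]
        means = []
        for _ in range(300):
            idx = rng.choice(300, size=30, replace=False)
            means.append(
                float(np.nanmean(pn.per_locus_he(g, idx)))
            )
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - full) < 2 * se + 1e-3


def brute_force_wc_theta(g, labels):
    """Independent variance-components computation, one locus, r groups.

    Follows the definitional estimator: for each allele, compute the
    a/b/c components from group sizes, frequencies and heterozygote
    frequencies with explicit loops, no shared code with the package.
    """
    labels = np.asarray(labels)
    A = B = C = 0.0
    for j in range(g.n_loci):
        groups = []
        for lab in dict.fromkeys(labels):
            calls = g.alleles[labels == lab, j, :]
            calls = calls[calls[:, 0] >= 0]
            groups.append(calls)
        r = len(groups)
        ns = [len(x) for x in groups]
        nbar = sum(ns) / r
        nc = (sum(ns) - sum(n**2 for n in ns) / sum(ns)) / (r - 1)
        alleles = sorted({a for grp in groups for a in grp.ravel().tolist()})
        if len(alleles) < 2:
            continue
        for al in alleles:
            ps = [np.mean(grp == al) for grp in groups]
            hs = [np.mean([(al in row) and row[0] != row[1] for row in grp])
                  for grp in groups]
            pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / (
                (r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                / (nbar - 1))
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


class TestWcFst:
    def test_fixed_groups_give_one(self):
        g = table([[[1, 1]]] * 4 + [[[2, 2]]] * 4)
        assert pn.wc_fst(g, ["A"] * 4 + ["B"] * 4) == pytest.approx(1.0)

    def test_identity_partition_near_zero(self, rng):
        g = random_hwe_table(rng, 100, 6)
        labels = np.array(["A"] * 50 + ["B"] * 50)
        assert abs(pn.wc_fst(g, labels)) < 0.02

    def test_matches_brute_force_variance_components(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            alleles = r.choice([5, 7, 9], size=(14, 1, 2)).astype(np.int32)
            g = GenotypeTable([f"i{k}" for k in range(14)], ["L"], alleles)
            labels = np.array(["A"] * 8 + ["B"] * 6)
            expected = brute_force_wc_theta(g, labels)
            assert pn.wc_fst(g, labels) == pytest.approx(expected, abs=1e-12)

    def test_no_variation_flagged_undefined(self):
        g = table([[[1, 1]]] * 6)
        assert np.isnan(pn.wc_fst(g, ["A"] * 3 + ["B"] * 3))

    def test_matrix_symmetric_with_p_in_unit_interval(self, two_group_table):
        g, labels = two_group_table
        dm, pv = pn.fst_matrix(g, labels, min_size=5, n_perm=99, seed=1)
        assert np.allclose(dm.values, dm.values.T)
        p = pv.loc["A", "B"]
        assert 0 < p <= 1


class TestHweTest:
    def test_fixed_locus_p_one(self):
        g = table([[[1, 1]]] * 10)
        res = pn.hwe_test(g, np.arange(10), n_perm=99, seed=0)
        assert res["per_locus"]["L0"] == 1.0

    def test_heterozygote_deficit_detected(self):
        # two alleles at 50/50 but zero heterozygotes
        g = table([[[1, 1]]] * 10 + [[[2, 2]]] * 10)
        res = pn.hwe_test(g, np.arange(20), n_perm=999, seed=0)
        assert res["global_p"] < 0.01

    def test_small_group_skipped_with_warning(self):
        g = table([[[1, 2]]] * 3)
        with pytest.warns(UserWarning, match="fewer than 5"):
            res = pn.hwe_test(g, np.arange(3))
        assert res["skipped"]


class TestLinkage:
    def test_duplicated_locus_perfect_association(self, rng):
        base = random_hwe_table(rng, 40, 1)
        dup = GenotypeTable(
            base.individual_ids, ["L0", "L0copy"],
            np.concatenate([base.alleles, base.alleles], axis=1),
        )
        res = pn.rbar_d(dup, np.arange(40), n_perm=199, seed=2)
        assert res["rbar_d"] == pytest.approx(1.0, abs=1e-9)
        assert res["p"] <= 1 / 100

    def test_independent_loci_rbar_d_near_zero(self, rng):
        g = random_hwe_table(rng, 80, 6)
        res = pn.rbar_d(g, np.arange(80), n_perm=199, seed=3)
        # equilibrium band observed in practice for unlinked loci
        assert -0.05 < res["rbar_d"] < 0.06
        assert res["p"] > 0.01

    def test_g_test_detects_duplicated_locus(self, rng):
        base = random_hwe_table(rng, 50, 1)
        dup = GenotypeTable(
            base.individual_ids, ["La", "Lb"],
            np.concatenate([base.alleles, base.alleles], axis=1),
        )
        res = pn.g_test_ld(dup, np.arange(50), n_perm=199, seed=1)
        assert res.p.iloc[0] <= 1 / 100


class TestAllelicRichness:
    def test_hand_example(self):
        # counts {A:3, B:1}, N=4, g=2 -> Ar = 1.5
        g = table([[[1, 1]], [[1, 2]]])
        res = pn.allelic_richness(g, ["x", "x"], g_copies=2)
        assert res.Ar.iloc[0] == pytest.approx(1.5)

    def test_equals_exhaustive_subsample_enumeration(self, rng):
        # brute force: mean allele count over all C(N, g) subsamples
        copies = np.array([1, 1, 1, 2, 2, 3, 3, 3, 3, 4], dtype=np.int32)
        g = GenotypeTable(
            [f"i{k}" for k in range(5)], ["L"], copies.reshape(5, 1, 2)
        )
        for gc in (2, 3, 5, 7):
            expect = np.mean([
                len(set(sub))
                for sub in itertools.combinations(copies.tolist(), gc)
            ])
            res = pn.allelic_richness(g, ["x"] * 5, g_copies=gc)
            assert res.Ar.iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_full_sample_gives_observed_count(self):
        g = table([[[1, 2]], [[3, 3]]])
        res = pn.allelic_richness(g, ["x", "x"], g_copies=4)
        assert res.Ar.iloc[0] == 3.0

    def test_ar_nondecreasing_in_g(self, rng):
        g = random_hwe_table(rng, 30, 3)
        values = [
            pn.allelic_richness(g, ["x"] * 30, g_copies=gc).Ar.iloc[0]
            for gc in (1, 5, 10, 20, 40)
        ]
        assert np.all(np.diff(values) >= -1e-12)
        assert values[0] == pytest.approx(1.0)

    def test_private_allele_full_sampling(self):
        # allele 9 private to group A; with g = N everywhere its pAr
        # contribution equals its presence probability (1)
        gt = table([[[1, 9]], [[1, 1]], [[1, 1]], [[1, 1]]])
        res = pn.allelic_richness(
            gt, ["A", "A", "B", "B"], g_copies=4
        )
        assert res.loc["A", "pAr"] == pytest.approx(1.0)
        assert res.loc["B", "pAr"] == pytest.approx(0.0)

    def test_undersized_group_dropped(self):
        g = table([[[1, 2]], [[1, 3]], [[2, 3]]])
        res = pn.allelic_richness(g, ["A", "A", "B"], g_copies=4)
        assert not res.loc["B", "retained"]
        assert res.loc["A", "retained"]


class TestMRatio:
    def test_hand_example(self):
        g = table([[[10, 12]], [[14, 10]], [[12, 12]]])
        res = pn.m_ratio(g, np.arange(3), motif_lengths=[1])
        assert res.M.iloc[0] == pytest.approx(3 / 5)

    def test_contiguous_ladder_gives_one(self):
        g = table([[[10, 11]], [[12, 11]], [[10, 12]]])
        res = pn.m_ratio(g, np.arange(3), motif_lengths=[1])
        assert res.M.iloc[0] == pytest.approx(1.0)

    def test_monomorphic_locus_flagged(self):
        g = table([[[10, 10]], [[10, 10]]])
        res = pn.m_ratio(g, np.arange(2), motif_lengths=[1])
        assert res.M.iloc[0] == 1.0 and res.monomorphic.iloc[0]

    def test_bottleneck_lowers_m(self, rng):
        # equilibrium ladder vs the same ladder with mid-sized alleles
        # knocked out (bottleneck signature: fewer alleles, same range)
        full = table([[[100 + k, 100 + k]] for k in range(8)])
        bott = table([[[100, 100]], [[100, 107]], [[107, 107]]])
        m_full = pn.m_ratio(full, np.arange(8), motif_lengths=[1]).M.iloc[0]
        m_bott = pn.m_ratio(bott, np.arange(3), motif_lengths=[1]).M.iloc[0]
        assert m_bott < m_full


class TestWangRelatedness:
    def _freqs(self, rng, L=15, k=8):
        return [rng.dirichlet(np.ones(k)) for _ in range(L)]

    def test_parent_offspring_near_half(self, rng):
        freqs = self._freqs(rng)
        L = len(freqs)
        parents = np.stack([
            np.stack([rng.choice(8, size=2, p=p) + 1 for p in freqs])
            for _ in range(80)
        ]).astype(np.int32)
        children = parents.copy()
        for k in range(80):
            for j, p in enumerate(freqs):
                children[k, j, 0] = parents[k, j, rng.integers(2)]
                children[k, j, 1] = rng.choice(8, p=p) + 1
        g = GenotypeTable(
            [f"p{k}" for k in range(80)] + [f"c{k}" for k in range(80)],
            [f"L{j}" for j in range(L)],
            np.concatenate([parents, children]),
        )
        ref = pn.allele_frequencies(g)
        rs = [pn.wang_relatedness(g, k, 80 + k, ref) for k in range(80)]
        se = np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs) - 0.5) < 3 * se + 0.02

    def test_unrelated_near_zero(self, rng):
        freqs = self._freqs(rng)
        inds = np.stack([
            np.stack([rng.choice(8, size=2, p=p) + 1 for p in freqs])
            for _ in range(160)
        ]).astype(np.int32)
        g = GenotypeTable([f"i{k}" for k in range(160)],
                          [f"L{j}" for j in range(len(freqs))], inds)
        ref = pn.allele_frequencies(g)
        rs = [pn.wang_relatedness(g, 2 * k, 2 * k + 1, ref)
              for k in range(80)]
        se = np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se + 0.02

    def test_identical_genotypes_near_max(self, rng):
        g = random_hwe_table(rng, 30, 12)
        dup = GenotypeTable(
            ["a", "b"], g.locus_names, np.stack([g.alleles[0], g.alleles[0]])
        )
        r = pn.wang_relatedness(dup, 0, 1, pn.allele_frequencies(g))
        assert r > 0.9

    def test_no_shared_typed_locus_undefined(self):
        arr = np.array([[[1, 2], [MISSING, MISSING]],
                        [[MISSING, MISSING], [3, 4]]], dtype=np.int32)
        g = GenotypeTable(["a", "b"], ["L1", "L2"], arr)
        assert np.isnan(pn.wang_relatedness(g, 0, 1))


class TestLdNe:
    def test_very_large_population_estimates_infinity_scale(self, rng):
        # HWE draws = infinite-Ne limit: no drift LD beyond sampling
        g = random_hwe_table(rng, 100, 10)
        res = pn.ld_ne(g, np.arange(100))
        assert res["Ne"] > 500 or np.isinf(res["Ne"])

    def test_duplicated_locus_excluded(self, rng):
        base = random_hwe_table(rng, 60, 6)
        dup = GenotypeTable(
            base.individual_ids, base.locus_names + ["Ldup"],
            np.concatenate([base.alleles, base.alleles[:, :1]], axis=1),
        )
        res_base = pn.ld_ne(base, np.arange(60))
        res_dup = pn.ld_ne(dup, np.arange(60))
        # the duplicated pair must not drag the estimate toward zero
        assert res_dup["n_pairs"] <= res_base["n_pairs"] + 6
        assert not (res_dup["Ne"] < 5)

    def test_too_few_loci_flagged(self):
        g = GenotypeTable(["a", "b", "c"], ["L"],
                          np.array([[[1, 2]], [[1, 1]], [[2, 2]]], np.int32))
        assert not pn.ld_ne(g, np.arange(3))["defined"]
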