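"""Sequence statistics against hand enumerations, closed forms and the
R `ape` implementation as an independent oracle."""

import itertools
import subprocess

import networkx as nx
import numpy as np
import pytest

from seascape import data_io
from seascape import popgen_mtdna as pm
from seascape.datatypes import SequenceAlignment

from conftest import mutate_copies


class TestHaplotypes:
    def test_identical_sequences_collapse(self):
        a = SequenceAlignment(list("abcd"), ["ACGT"] * 4)
        h = pm.collapse_haplotypes(a)
        assert h.n_haplotypes == 1 and h.n_segregating == 0

    def test_site_classification_hand_enumeration(self):
        # columns: (A,A,A,G) singleton; (A,A,A,A) invariant; (A,T,T,T) singleton
        a = SequenceAlignment(list("abcd"), ["AAA", "AAT", "AAT", "GAT"])
        h = pm.collapse_haplotypes(a)
        assert h.n_haplotypes == 3
        assert h.n_segregating == 2
        assert h.n_singleton_mutations == 2
        assert h.n_parsimony_informative == 0

    def test_parsimony_informative_site(self):
        a = SequenceAlignment(list("abcd"), ["A", "A", "T", "T"])
        h = pm.collapse_haplotypes(a)
        assert h.n_parsimony_informative == 1
        assert h.n_singleton_mutations == 0

    def test_order_invariance(self, rng):
        a = mutate_copies(rng, "ACGT" * 20, 10, 4)
        h1 = pm.collapse_haplotypes(a)
        perm = rng.permutation(10).tolist()
        a2 = a.subset(perm)
        h2 = pm.collapse_haplotypes(a2)
        assert h1.n_haplotypes == h2.n_haplotypes
        assert h1.n_segregating == h2.n_segregating
        assert sorted(h1.haplotypes) == sorted(h2.haplotypes)

    def test_counts_sum_to_inputs(self, small_alignment):
        h = pm.collapse_haplotypes(small_alignment)
        assert h.counts.to_numpy().sum() == small_alignment.n_sequences


class TestDistances:
    def test_identical_pair_zero(self):
        a = SequenceAlignment(["x", "y"], ["ACGT", "ACGT"])
        assert pm.seq_distance(a, "JC69").values[0, 1] == 0.0

    def test_jc_closed_form_at_p_ten_percent(self):
        a = SequenceAlignment(["x", "y"], ["A" * 90 + "C" * 10,
                                           "A" * 90 + "G" * 10])
        assert pm.seq_distance(a, "JC69").values[0, 1] == pytest.approx(
            0.107326, abs=1e-6)

    def test_jc_saturated_flagged_infinite(self):
        a = SequenceAlignment(["x", "y"], ["AAAA", "CCCC"])
        assert np.isinf(pm.seq_distance(a, "JC69").values[0, 1])

    def test_jc_at_least_p_distance(self, small_alignment):
        p = pm.seq_distance(small_alignment, "p").values
        jc = pm.seq_distance(small_alignment, "JC69").values
        assert (jc >= p - 1e-12).all()
        iu = np.triu_indices(p.shape[0], 1)
        strict = p[iu] > 0
        assert (jc[iu][strict] > p[iu][strict]).all()

    def test_pairwise_deletion_of_ambiguous_sites(self):
        a = SequenceAlignment(["x", "y"], ["ANAA", "AC-A"])
        # only sites 0 and 3 are comparable, both identical
        assert pm.seq_distance(a, "p").values[0, 1] == 0.0

    def test_tn93_matches_ape(self, tmp_path, small_alignment):
        path = tmp_path / "a.fasta"
        data_io.write_alignment(small_alignment, path)
        script = (
            f'library(ape); a <- read.dna("{path}", format="fasta");'
            'd <- as.matrix(dist.dna(a, model="TN93", pairwise.deletion=TRUE));'
            'cat(d[1,2], d[3,7], d[2,12])'
        )
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        expected = [float(x) for x in out.stdout.split()]
        ours = pm.seq_distance(small_alignment, "TN93").values
        assert ours[0, 1] == pytest.approx(expected[0], abs=1e-6)
        assert ours[2, 6] == pytest.approx(expected[1], abs=1e-6)
        assert ours[1, 11] == pytest.approx(expected[2], abs=1e-6)

    def test_tn93_reduces_to_jc_on_balanced_data(self):
        # equal base frequencies and all six substitution types equally
        # represented (the JC substitution pattern)
        s1 = list("ACGT" * 30)
        s2 = list(s1)
        # one of each unordered change type: AG, CT, AC, AT, CG, GT
        for pos, new in [(0, "G"), (5, "T"), (8, "C"), (12, "T"),
                         (17, "G"), (22, "T")]:
            s2[pos] = new
        a = SequenceAlignment(["x", "y"], ["".join(s1), "".join(s2)])
        jc = pm.seq_distance(a, "JC69").values[0, 1]
        tn = pm.seq_distance(a, "TN93").values[0, 1]
        assert tn == pytest.approx(jc, abs=2e-3)


class TestDiversity:
    def test_all_distinct_haplotype_diversity_one(self):
        a = SequenceAlignment(list("abcd"),
                              ["AAAA", "AAAT", "AATT", "ATTT"])
        assert pm.seq_diversity(a)["Hd"] == pytest.approx(1.0)

    def test_watterson_hand_value(self):
        seqs = ["A" * 100, "T" + "A" * 99, "TC" + "A" * 98, "TCG" + "A" * 97]
        d = pm.seq_diversity(SequenceAlignment(list("abcd"), seqs))
        assert d["thetaW"] == pytest.approx(3 / ((1 + 1 / 2 + 1 / 3) * 100),
                                            abs=1e-9)

    def test_pi_two_sequences_one_percent(self):
        a = SequenceAlignment(["x", "y"], ["A" * 100, "T" + "A" * 99])
        assert pm.seq_diversity(a)["pi"] == pytest.approx(0.01)

    def test_singleton_group_flagged(self):
        a = SequenceAlignment(["x"], ["ACGT"])
        assert not pm.seq_diversity(a)["defined"]

    def test_pi_from_haplotypes_equals_pi_from_alignment(self, rng):
        # collapsing is lossless for pi: recompute from haplotype counts
        a = mutate_copies(rng, "ACGT" * 30, 15, 5)
        h = pm.collapse_haplotypes(a)
        direct = pm.seq_diversity(a)["pi"]
        # expand haplotypes by their counts and recompute
        counts = h.counts.sum(axis=1)
        seqs = [h.haplotypes[i] for i in range(h.n_haplotypes)
                for _ in range(int(counts[i]))]
        a2 = SequenceAlignment([f"r{i}" for i in range(len(seqs))], seqs)
        assert pm.seq_diversity(a2)["pi"] == pytest.approx(direct, abs=1e-12)


class TestNeutrality:
    def test_pi_equal_theta_gives_zero(self):
        # numerator pi - S/a1 vanishes when pi == S/a1 (n=4: a1 = 11/6)
        assert pm.tajimas_d(4, 11, 6.0) == pytest.approx(0.0, abs=1e-12)

    def test_pair_sample_degenerate_variance_flagged(self):
        # n = 2 has zero sampling variance for D; undefined, not zero
        assert np.isnan(pm.tajimas_d(2, 2, 2.0))

    def test_star_like_excess_of_singletons_negative(self):
        base = "A" * 60
        seqs = [base] + [base[:i] + "T" + base[i + 1:] for i in range(9)]
        res = pm.neutrality_tests(
            SequenceAlignment([f"s{i}" for i in range(10)], seqs))
        assert res["TajimaD"] < 0
        assert res["FuLiDstar"] < 0

    def test_no_segregating_sites_flagged_not_zero(self):
        res = pm.neutrality_tests(SequenceAlignment(list("abc"), ["AC"] * 3))
        assert not res["defined"]
        assert np.isnan(res["TajimaD"])

    def test_neutral_coalescent_mean_and_rejection(self):
        # msprime as the independent neutral-model oracle
        msprime = pytest.importorskip("msprime")
        lo, hi = pm.tajima_confint(20)
        ds = []
        rej = 0
        for rep in range(300):
            ts = msprime.sim_ancestry(
                samples=20, ploidy=1, population_size=100,
                sequence_length=500, random_seed=rep + 1)
            mts = msprime.sim_mutations(ts, rate=1e-4, random_seed=rep + 1)
            if mts.num_sites == 0:
                continue
            d = pm.tajimas_d(
                20, mts.num_sites,
                float(mts.diversity(span_normalise=False, mode="site")))
            ds.append(d)
            rej += (d < lo) or (d > hi)
        assert abs(np.mean(ds)) < 0.15
        assert 0.005 < rej / len(ds) < 0.09


def brute_force_snn(d, labels):
    """Direct per-sequence nearest-neighbour count with explicit loops."""
    n = len(labels)
    acc = 0.0
    for i in range(n):
        dists = [(d[i, j], j) for j in range(n) if j != i]
        mind = min(x[0] for x in dists)
        near = [j for x, j in dists if x == mind]
        acc += sum(labels[j] == labels[i] for j in near) / len(near)
    return acc / n


class TestHudsonSnn:
    def test_fixed_groups(self):
        a = SequenceAlignment(list("abcd"),
                              ["AACC", "AACC", "AATT", "AATT"])
        res = pm.hudson_fst(a, ["x", "x", "y", "y"], "x", "y",
                            n_perm=99, seed=0)
        assert res["FST"] == pytest.approx(1.0)
        assert res["Snn"] == pytest.approx(1.0)

    def test_panmictic_split_fst_near_zero(self, rng):
        a = mutate_copies(rng, "ACGT" * 30, 20, 6)
        res = pm.hudson_fst(a, ["x"] * 10 + ["y"] * 10, "x", "y",
                            n_perm=99, seed=1)
        assert abs(res["FST"]) < 0.15
        assert res["p"] > 0.05

    def test_snn_matches_exhaustive_hand_count_with_ties(self, rng):
        for seed in range(4):
            a = mutate_copies(np.random.default_rng(seed), "ACGT" * 10, 8, 3)
            d = pm.raw_difference_matrix(a)
            labels = np.array([0, 0, 0, 1, 1, 1, 0, 1])
            assert pm.snn_statistic(d, labels) == pytest.approx(
                brute_force_snn(d, labels))


def brute_force_amova(d, labels):
    """AMOVA sums of squares computed with explicit double loops."""
    n = len(labels)
    groups = sorted(set(labels))
    sst = sum(d[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in groups:
        ix = [i for i in range(n) if labels[i] == g]
        ssw += sum(d[i, j] for i in ix for j in ix if i < j) / len(ix)
    ssa = sst - ssw
    G = len(groups)
    msw = ssw / (n - G)
    msa = ssa / (G - 1)
    sizes = [sum(1 for l in labels if l == g) for g in groups]
    nprime = (n - sum(s**2 for s in sizes) / n) / (G - 1)
    sa = (msa - msw) / nprime
    return sa / (sa + msw)


class TestPhiSt:
    def test_fixed_divergent_groups_give_one(self):
        s_a = "ACGTAC" * 10
        s_b = "ACGTAC" * 8 + "GTACGT" * 2
        a = SequenceAlignment(list("abcd"), [s_a, s_a, s_b, s_b])
        res = pm.phi_st(a, ["x", "x", "y", "y"], "x", "y",
                        n_perm=99, seed=0)
        assert res["PhiST"] == pytest.approx(1.0)

    def test_identical_groups_near_zero(self, rng):
        a = mutate_copies(rng, "ACGT" * 25, 16, 5)
        res = pm.phi_st(a, ["x"] * 8 + ["y"] * 8, "x", "y",
                        n_perm=199, seed=1)
        assert abs(res["PhiST"]) < 0.15

    def test_matches_brute_force_sums_of_squares(self, rng):
        a = mutate_copies(rng, "ACGT" * 15, 6, 4)
        labels = np.array([0, 0, 0, 1, 1, 1])
        d = pm.seq_distance(a, "TN93").values
        assert pm.amova_phi_st(d, labels) == pytest.approx(
            brute_force_amova(d, labels), abs=1e-12)


class TestNetDivergence:
    def test_arithmetic(self, rng):
        a = mutate_copies(rng, "ACGT" * 25, 8, 3)
        labels = np.array(["x"] * 4 + ["y"] * 4)
        dm = pm.net_divergence(a, labels, model="p")
        d = pm.seq_distance(a, "p").values
        hb = d[np.ix_(range(4), range(4, 8))].mean()
        hw_x = d[np.ix_(range(4), range(4))][np.triu_indices(4, 1)].mean()
        hw_y = d[np.ix_(range(4, 8), range(4, 8))][np.triu_indices(4, 1)].mean()
        assert dm.values[0, 1] == pytest.approx(hb - (hw_x + hw_y) / 2)

    def test_identical_groups_near_zero(self, rng):
        a = mutate_copies(rng, "ACGT" * 25, 12, 4)
        labels = np.array(["x", "y"] * 6)
        dm = pm.net_divergence(a, labels, model="JC69")
        assert abs(dm.values[0, 1]) < 0.01

    def test_da_never_exceeds_between_distance(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = mutate_copies(r, "ACGT" * 20, 10, 5)
            labels = r.choice(["x", "y"], size=10)
            if len(set(labels)) < 2:
                continue
            d = pm.seq_distance(a, "JC69").values
            dm = pm.net_divergence(a, labels, model="JC69")
            ix = np.flatnonzero(labels == "x")
            iy = np.flatnonzero(labels == "y")
            hb = d[np.ix_(ix, iy)].mean()
            assert dm.values[0, 1] <= hb + 1e-12


class TestMedianJoiningNetwork:
    def test_chain_has_no_median_vectors(self):
        a = SequenceAlignment(list("abc"), ["AAA", "AAT", "ATT"])
        net = pm.median_joining_network(pm.collapse_haplotypes(a))
        assert net.number_of_nodes() == 3
        assert sorted(w for _, _, w in net.edges(data="weight")) == [1, 1]

    def test_single_haplotype(self):
        a = SequenceAlignment(list("ab"), ["ACGT", "ACGT"])
        net = pm.median_joining_network(pm.collapse_haplotypes(a))
        assert net.number_of_nodes() == 1
        assert net.number_of_edges() == 0

    def test_star_introduces_median_vector(self):
        a = SequenceAlignment(list("abc"), ["AAA", "TTA", "ATT"])
        net = pm.median_joining_network(pm.collapse_haplotypes(a))
        medians = [n for n in net.nodes if net.nodes[n]["is_median"]]
        assert len(medians) == 1
        assert net.degree(medians[0]) == 3

    def test_network_spans_all_haplotypes(self, rng):
        for seed in range(5):
            a = mutate_copies(np.random.default_rng(seed), "ACGT" * 12,
                              12, 4)
            net = pm.median_joining_network(pm.collapse_haplotypes(a))
            assert nx.is_connected(net)

    def test_refuses_oversized_input(self, rng):
        a = mutate_copies(rng, "ACGT" * 10, 12, 6)
        with pytest.raises(ValueError, match="refus"):
            pm.median_joining_network(pm.collapse_haplotypes(a),
                                      max_haplotypes=3)
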