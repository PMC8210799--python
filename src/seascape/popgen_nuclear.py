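"""Microsatellite statistics.

Allele frequencies, observed/expected heterozygosity and the Weir &
Cockerham (1984) fixation indices, permutation tests for Hardy-Weinberg
and linkage equilibrium, the standardised index of association (RbarD),
rarefied allelic richness and private allelic richness, the
Garza-Williamson M-ratio, Wang's (2002) moment estimator of pairwise
relatedness, and the LD (Burrows' composite) estimator of effective
population size with the Waples (2006) sample-size bias correction.

All exact tests of the original study tools are realised as direct,
seeded permutation tests of the same null hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._util import group_indices, perm_pvalue, rng_from
from .datatypes import DistanceMatrix, GenotypeTable

__all__ = [
    "allele_frequencies",
    "heterozygosity_fis",
    "wc_fst",
    "fst_matrix",
    "hwe_test",
    "g_test_ld",
    "rbar_d",
    "allelic_richness",
    "m_ratio",
    "wang_relatedness",
    "pairwise_relatedness_matrix",
    "mean_group_relatedness",
    "ld_ne",
]


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeTable, indices=None) -> list[dict[int, int]]:
    """Per-locus allele -> count of gene copies (non-missing only).

    ``indices`` restricts to a subset of individuals (a group).
    """
    alleles = g.alleles if indices is None else g.alleles[np.asarray(indices)]
    out = []
    for j in range(g.n_loci):
        col = alleles[:, j, :].ravel()
        col = col[col >= 0]
        vals, cnts = np.unique(col, return_counts=True)
        out.append(dict(zip(vals.tolist(), cnts.tolist())))
    return out


def _freq_vector(counts: dict[int, int]) -> tuple[np.ndarray, np.ndarray]:
    alleles = np.array(sorted(counts))
    n = np.array([counts[a] for a in alleles], dtype=float)
    return alleles, n / n.sum() if n.size else n


# ---------------------------------------------------------------------------
# heterozygosity and F_IS
# ---------------------------------------------------------------------------

def _locus_ho_he(calls: np.ndarray) -> tuple[float, float, int]:
    """(Ho, unbiased He, n individuals typed) for one group x locus.

    He uses the small-sample estimator (2n/(2n-1)) (1 - sum p^2).
    """
    typed = calls[calls[:, 0] >= 0]
    n = typed.shape[0]
    if n == 0:
        return np.nan, np.nan, 0
    ho = float(np.mean(typed[:, 0] != typed[:, 1]))
    copies = typed.ravel()
    _, cnt = np.unique(copies, return_counts=True)
    p = cnt / copies.size
    he = (2 * n / (2 * n - 1)) * (1 - np.sum(p**2)) if n > 1 else np.nan
    return ho, he, n


def _fis_components(calls: np.ndarray) -> tuple[float, float]:
    """Weir & Cockerham within-population components (sum_b+c, sum_c).

    For each allele A with frequency p and heterozygote frequency h:
    b = n/(n-1) (p(1-p) - (2n-1)/(4n) h), c = h/2.  F_IS = 1 - Sc/S(b+c).
    """
    typed = calls[calls[:, 0] >= 0]
    n = typed.shape[0]
    if n < 2:
        return 0.0, 0.0
    alleles = np.unique(typed)
    sum_bc = sum_c = 0.0
    for a in alleles:
        dose = (typed == a).sum(axis=1)
        p = dose.mean() / 2
        h = float(np.mean(dose == 1))
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2
        sum_bc += b + c
        sum_c += c
    return sum_bc, sum_c


def heterozygosity_fis(g: GenotypeTable, groups) -> pd.DataFrame:
    """Per-group Ho, He (unbiased, locus-averaged) and multilocus WC F_IS.

    Monomorphic groups get He = Ho = 0 and F_IS = NaN with a
    ``fis_defined=False`` flag (undefined, not propagated).
    """
    rows = []
    for label, idx in group_indices(groups).items():
        ho_l, he_l, bc_l, c_l = [], [], 0.0, 0.0
        for j in range(g.n_loci):
            calls = g.alleles[idx, j, :]
            ho, he, n = _locus_ho_he(calls)
            if n > 0 and np.isfinite(he):
                ho_l.append(ho)
                he_l.append(he)
            bc, c = _fis_components(calls)
            bc_l += bc
            c_l += c
        defined = bc_l > 0
        fis = 1 - c_l / bc_l if defined else np.nan
        rows.append(
            dict(
                group=label,
                Ho=float(np.mean(ho_l)) if ho_l else np.nan,
                He=float(np.mean(he_l)) if he_l else np.nan,
                FIS=fis,
                fis_defined=bool(defined),
                n=idx.size,
            )
        )
    return pd.DataFrame(rows).set_index("group")


def per_locus_he(g: GenotypeTable, indices) -> np.ndarray:
    """Unbiased He per locus for one group (NaN where untyped)."""
    return np.array(
        [_locus_ho_he(g.alleles[indices, j, :])[1] for j in range(g.n_loci)]
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham theta (F_ST)
# ---------------------------------------------------------------------------

def _wc_abc(g: GenotypeTable, group_idx: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed variance components (a, b, c) over loci and alleles."""
    r = len(group_idx)
    A = B = C = 0.0
    for j in range(g.n_loci):
        calls = [g.alleles[ix, j, :] for ix in group_idx]
        typed = [c[c[:, 0] >= 0] for c in calls]
        ns = np.array([t.shape[0] for t in typed], dtype=float)
        if (ns < 1).any() or ns.sum() < r + 1:
            continue
        alleles = np.unique(np.concatenate([t.ravel() for t in typed]))
        if alleles.size < 2:
            continue
        nbar = ns.mean()
        nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
        for a in alleles:
            p_i = np.array([(t == a).sum() / (2 * t.shape[0]) for t in typed])
            h_i = np.array(
                [np.mean((t == a).sum(axis=1) == 1) for t in typed]
            )
            pbar = np.sum(ns * p_i) / (r * nbar)
            s2 = np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar)
            hbar = np.sum(ns * h_i) / (r * nbar)
            if nbar <= 1 or nc <= 0:
                continue
            a_comp = (nbar / nc) * (
                s2
                - (1 / (nbar - 1))
                * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
            )
            b_comp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c_comp = hbar / 2
            A += a_comp
            B += b_comp
            C += c_comp
    return A, B, C


def wc_fst(g: GenotypeTable, groups, labels=None) -> float:
    """Multilocus Weir & Cockerham (1984) theta over >= 2 groups.

    ``groups`` is a per-individual label vector; ``labels`` optionally
    restricts/orders the groups.  NaN when there is no variation
    (a + b + c = 0, flagged undefined).
    """
    gi = group_indices(groups)
    if labels is None:
        labels = list(gi)
    idx = [gi[l] for l in labels]
    A, B, C = _wc_abc(g, idx)
    tot = A + B + C
    if tot == 0:
        return np.nan
    return A / tot


def fst_matrix(
    g: GenotypeTable,
    groups,
    min_size: int = 10,
    n_perm: int = 0,
    seed=None,
) -> tuple[DistanceMatrix, pd.DataFrame | None]:
    """Pairwise WC theta with optional permutation p-values.

    Groups below ``min_size`` individuals are excluded (study QC rule).
    The permutation null reallocates individuals between the pair.
    """
    gi = {l: ix for l, ix in group_indices(groups).items() if ix.size >= min_size}
    labels = list(gi)
    k = len(labels)
    vals = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    rng = rng_from(seed)
    for i in range(k):
        for j in range(i + 1, k):
            ia, ib = gi[labels[i]], gi[labels[j]]
            sub = g.subset(np.concatenate([ia, ib]))
            lab = np.array([0] * ia.size + [1] * ib.size)
            obs = wc_fst(sub, lab)
            vals[i, j] = vals[j, i] = obs
            if n_perm > 0 and np.isfinite(obs):
                null = np.empty(n_perm)
                for b in range(n_perm):
                    null[b] = wc_fst(sub, rng.permutation(lab))
                p = perm_pvalue(null, obs)
                pvals[i, j] = pvals[j, i] = p
    dm = DistanceMatrix(labels, vals, bounded=False)
    pv = None
    if n_perm > 0:
        pv = pd.DataFrame(pvals, index=labels, columns=labels)
    return dm, pv


# ---------------------------------------------------------------------------
# HWE permutation test
# ---------------------------------------------------------------------------

def _locus_abs_fis(calls: np.ndarray) -> float:
    bc, c = _fis_components(calls)
    return abs(1 - c / bc) if bc > 0 else 0.0


def hwe_test(
    g: GenotypeTable, group_idx, n_perm: int = 10_000, seed=None
) -> dict:
    """Permutation HWE test within one group.

    Alleles are shuffled among individuals within each locus; the
    statistic is |F_IS| (per locus, and multilocus for the global test).
    Returns per-locus and global p-values.
    """
    idx = np.asarray(group_idx)
    if idx.size < 5:
        warnings.warn("HWE test skipped: fewer than 5 individuals")
        return {"per_locus": {}, "global_p": np.nan, "skipped": True}
    rng = rng_from(seed)
    per_locus = {}
    obs_bc = obs_c = 0.0
    null_global = np.zeros(n_perm)
    for j, locus in enumerate(g.locus_names):
        calls = g.alleles[idx, j, :]
        typed = calls[calls[:, 0] >= 0]
        if typed.shape[0] < 2 or np.unique(typed).size < 2:
            per_locus[locus] = 1.0
            continue
        obs = _locus_abs_fis(typed)
        bc, c = _fis_components(typed)
        obs_bc += bc
        obs_c += c
        copies = typed.ravel().copy()
        null = np.empty(n_perm)
        for b in range(n_perm):
            rng.shuffle(copies)
            null[b] = _locus_abs_fis(copies.reshape(-1, 2))
        per_locus[locus] = perm_pvalue(null, obs, ties="mid")
    # global test: permute all loci jointly, statistic = |multilocus FIS|
    obs_global = abs(1 - obs_c / obs_bc) if obs_bc > 0 else 0.0
    for b in range(n_perm):
        tot_bc = tot_c = 0.0
        for j in range(g.n_loci):
            calls = g.alleles[idx, j, :]
            typed = calls[calls[:, 0] >= 0]
            if typed.shape[0] < 2:
                continue
            copies = rng.permutation(typed.ravel())
            bc, c = _fis_components(copies.reshape(-1, 2))
            tot_bc += bc
            tot_c += c
        null_global[b] = abs(1 - tot_c / tot_bc) if tot_bc > 0 else 0.0
    return {
        "per_locus": per_locus,
        "global_p": perm_pvalue(null_global, obs_global, ties="mid"),
        "skipped": False,
    }


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """G-test statistic on the two-locus genotype contingency table."""
    tab = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(float)
    n = tab.sum()
    if n == 0:
        return 0.0
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tab > 0, tab * np.log(tab / exp), 0.0)
    return float(2 * terms.sum())


def _genotype_codes(g: GenotypeTable, idx, j) -> np.ndarray:
    """Unordered-genotype integer code per individual (-1 = missing)."""
    calls = np.sort(g.alleles[idx, j, :], axis=1)
    codes = calls[:, 0] * 10_000 + calls[:, 1]
    codes[calls[:, 0] < 0] = -1
    return codes


def g_test_ld(
    g: GenotypeTable, group_idx, n_perm: int = 1000, seed=None
) -> pd.DataFrame:
    """Pairwise-locus G-tests of genotypic linkage within one group.

    The null distribution permutes one locus's genotypes among
    individuals (keeping single-locus genotype frequencies fixed).
    """
    idx = np.asarray(group_idx)
    rng = rng_from(seed)
    codes = [_genotype_codes(g, idx, j) for j in range(g.n_loci)]
    rows = []
    for a in range(g.n_loci):
        for b in range(a + 1, g.n_loci):
            both = (codes[a] >= 0) & (codes[b] >= 0)
            x, y = codes[a][both], codes[b][both]
            if x.size < 5 or np.unique(x).size < 2 or np.unique(y).size < 2:
                rows.append((g.locus_names[a], g.locus_names[b], np.nan, np.nan))
                continue
            obs = _g_statistic(x, y)
            null = np.empty(n_perm)
            yp = y.copy()
            for r in range(n_perm):
                rng.shuffle(yp)
                null[r] = _g_statistic(x, yp)
            rows.append(
                (g.locus_names[a], g.locus_names[b], obs, perm_pvalue(null, obs))
            )
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "G", "p"])


def _per_locus_distances(g: GenotypeTable, idx) -> np.ndarray:
    """(L, n_pairs) condensed allele-sharing distances per locus.

    d in {0, 0.5, 1}: proportion of the two allele slots differing
    (multiset comparison of unordered genotypes).
    """
    n = idx.size
    iu = np.triu_indices(n, k=1)
    out = np.empty((g.n_loci, iu[0].size))
    for j in range(g.n_loci):
        calls = np.sort(g.alleles[idx, j, :], axis=1)
        a1, a2 = calls[:, 0], calls[:, 1]
        same = (a1[iu[0]] == a1[iu[1]]) & (a2[iu[0]] == a2[iu[1]])
        any_shared = (
            (a1[iu[0]] == a1[iu[1]])
            | (a1[iu[0]] == a2[iu[1]])
            | (a2[iu[0]] == a1[iu[1]])
            | (a2[iu[0]] == a2[iu[1]])
        )
        shared = np.where(same, 2.0, np.where(any_shared, 1.0, 0.0))
        out[j] = 1.0 - shared / 2.0
    return out


def rbar_d(
    g: GenotypeTable, group_idx, n_perm: int = 1000, seed=None
) -> dict:
    """Standardised index of association (Agapow & Burt 2001).

    rbar_d = (V_o - V_e) / (2 S_{l<m} sqrt(var_l var_m)) where V_o is
    the variance over pairs of summed per-locus distances and V_e the
    sum of per-locus variances.  Individuals with any missing call are
    excluded (logged); the null shuffles each locus independently.
    """
    idx = np.asarray(group_idx)
    complete = idx[~g.missing_mask()[idx].any(axis=1)]
    n_dropped = idx.size - complete.size
    if complete.size < 3:
        return {"rbar_d": np.nan, "p": np.nan, "n_dropped": n_dropped}
    rng = rng_from(seed)

    def stat(dmat: np.ndarray) -> float:
        total = dmat.sum(axis=0)
        v_o = total.var(ddof=1)
        v_l = dmat.var(axis=1, ddof=1)
        v_e = v_l.sum()
        sq = np.sqrt(np.outer(v_l, v_l))
        denom = 2 * (np.triu(sq, k=1).sum())
        return (v_o - v_e) / denom if denom > 0 else np.nan

    dmat = _per_locus_distances(g, complete)
    obs = stat(dmat)
    if not np.isfinite(obs):
        return {"rbar_d": np.nan, "p": np.nan, "n_dropped": n_dropped}
    null = np.empty(n_perm)
    sub = g.subset(complete)
    m = complete.size
    for b in range(n_perm):
        shuffled = GenotypeTable(
            sub.individual_ids,
            sub.locus_names,
            np.stack(
                [sub.alleles[rng.permutation(m), j] for j in range(sub.n_loci)],
                axis=1,
            ),
        )
        null[b] = stat(_per_locus_distances(shuffled, np.arange(m)))
    return {
        "rbar_d": float(obs),
        "p": perm_pvalue(null, obs),
        "n_dropped": n_dropped,
    }


# ---------------------------------------------------------------------------
# rarefied allelic richness
# ---------------------------------------------------------------------------

def _miss_prob(N: int, N_ij: int, g_copies: int) -> float:
    """C(N - N_ij, g) / C(N, g): P(allele absent from a g-copy subsample)."""
    if N - N_ij < g_copies:
        return 0.0
    return float(
        np.exp(
            gammaln(N - N_ij + 1)
            - gammaln(N - N_ij - g_copies + 1)
            - (gammaln(N + 1) - gammaln(N - g_copies + 1))
        )
    )


def allelic_richness(
    g: GenotypeTable, groups, g_copies: int = 18
) -> pd.DataFrame:
    """Rarefied allelic richness Ar and private allelic richness pAr.

    Ar = expected number of distinct alleles in a random subsample of
    ``g_copies`` gene copies; pAr = expected number present in the focal
    group's subsample and absent from every other group's subsample
    (both averaged over loci).  Groups with fewer than ``g_copies``
    typed copies at any locus are dropped, logged via the returned
    ``retained`` flag.
    """
    gi = group_indices(groups)
    counts = {lab: allele_frequencies(g, ix) for lab, ix in gi.items()}
    copies = {
        lab: np.array([sum(c.values()) for c in cnt])
        for lab, cnt in counts.items()
    }
    retained = [lab for lab in gi if (copies[lab] >= g_copies).all()]
    rows = []
    for lab in gi:
        if lab not in retained:
            rows.append(dict(group=lab, Ar=np.nan, pAr=np.nan, retained=False))
            continue
        ar_loci, par_loci = [], []
        for j in range(g.n_loci):
            universe = set()
            for other in retained:
                universe |= set(counts[other][j])
            ar = par = 0.0
            for a in sorted(universe):
                nij = counts[lab][j].get(a, 0)
                q_focal = 1.0 - _miss_prob(int(copies[lab][j]), nij, g_copies)
                ar += q_focal
                p_absent_elsewhere = 1.0
                for other in retained:
                    if other == lab:
                        continue
                    p_absent_elsewhere *= _miss_prob(
                        int(copies[other][j]), counts[other][j].get(a, 0), g_copies
                    )
                par += q_focal * p_absent_elsewhere
            ar_loci.append(ar)
            par_loci.append(par)
        rows.append(
            dict(
                group=lab,
                Ar=float(np.mean(ar_loci)),
                pAr=float(np.mean(par_loci)),
                retained=True,
            )
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Garza-Williamson M-ratio
# ---------------------------------------------------------------------------

def m_ratio(
    g: GenotypeTable, group_idx, motif_lengths=None
) -> pd.DataFrame:
    """M = k / (r + 1) per locus: allele count over allele-size range.

    ``motif_lengths`` converts base-pair sizes to repeat units; default
    2 bp (dinucleotide) with a warning.  Monomorphic loci give M = 1 by
    convention (k = 1, r = 0), flagged.
    """
    if motif_lengths is None:
        warnings.warn("motif lengths not supplied; assuming 2 bp repeats")
        motif_lengths = [2] * g.n_loci
    idx = np.asarray(group_idx)
    rows = []
    for j, locus in enumerate(g.locus_names):
        col = g.alleles[idx, j, :].ravel()
        col = col[col >= 0]
        if col.size == 0:
            rows.append(dict(locus=locus, M=np.nan, monomorphic=False))
            continue
        sizes = np.unique(col)
        k = sizes.size
        r = (sizes.max() - sizes.min()) / motif_lengths[j]
        rows.append(
            dict(locus=locus, M=k / (r + 1), monomorphic=bool(k == 1))
        )
    df = pd.DataFrame(rows).set_index("locus")
    df.attrs["mean_M"] = float(df["M"].mean())
    return df


# ---------------------------------------------------------------------------
# Wang (2002) relatedness
# ---------------------------------------------------------------------------

def _dyad_category(g1: np.ndarray, g2: np.ndarray) -> int:
    """Similarity category: 1 identical, 2 hom-het sharing, 3 het-het
    sharing one allele, 4 no allele shared."""
    s1, s2 = set(g1.tolist()), set(g2.tolist())
    if sorted(g1.tolist()) == sorted(g2.tolist()):
        return 1
    shared = s1 & s2
    if not shared:
        return 4
    hom1, hom2 = len(s1) == 1, len(s2) == 1
    if hom1 or hom2:
        return 2
    return 3


def _wang_coefficients(p: np.ndarray) -> tuple[float, ...]:
    a2 = float(np.sum(p**2))
    a3 = float(np.sum(p**3))
    a4 = float(np.sum(p**4))
    b = 2 * a2**2 - a4
    c = a2 - 2 * a2**2 + a4
    d = 4 * (a3 - a4)
    e = 2 * (a2 - 3 * a3 + 2 * a4)
    f = 4 * (a2 - a2**2 - 2 * a3 + 2 * a4)
    gg = 1 - 7 * a2 + 4 * a2**2 + 10 * a3 - 8 * a4
    u = 2 * a2 - a3
    return b, c, d, e, f, gg, u


def wang_relatedness(
    g: GenotypeTable, i: int, j: int, ref_freqs=None
) -> float:
    """Wang's moment estimator of relatedness for one pair.

    Moment conditions: with phi (one pair of genes IBD) and delta (two
    pairs IBD), the probabilities of the dyad similarity categories are
    P1 = b + c phi + (1-b) delta, P2 = d + e phi - d delta,
    P3 = f + g phi - f delta, with b..g polynomials in the reference
    allele-frequency moments.  Locus-weighted (1/u) least squares gives
    (phi, delta); r = phi/2 + delta.  Reference frequencies default to
    the pooled sample.  NaN when the pair shares no typed locus.
    """
    if ref_freqs is None:
        ref_freqs = allele_frequencies(g)
    rows_A, rows_y, wts = [], [], []
    for l in range(g.n_loci):
        g1, g2 = g.alleles[i, l], g.alleles[j, l]
        if g1[0] < 0 or g2[0] < 0:
            continue
        _, p = _freq_vector(ref_freqs[l])
        if p.size < 2:
            continue
        b, c, d, e, f, gg, u = _wang_coefficients(p)
        cat = _dyad_category(g1, g2)
        obs = [float(cat == 1), float(cat == 2), float(cat == 3)]
        rows_A.append(np.array([[c, 1 - b], [e, -d], [gg, -f]]))
        rows_y.append(np.array([obs[0] - b, obs[1] - d, obs[2] - f]))
        wts.append(1.0 / u if u > 0 else 0.0)
    if not rows_A:
        return np.nan
    w = np.asarray(wts)
    w = w / w.sum()
    A = np.tensordot(w, np.stack(rows_A), axes=1)
    y = np.tensordot(w, np.stack(rows_y), axes=1)
    phi_delta, *_ = np.linalg.lstsq(A, y, rcond=None)
    phi, delta = phi_delta
    return float(phi / 2 + delta)


def pairwise_relatedness_matrix(g: GenotypeTable) -> np.ndarray:
    """All-pairs Wang relatedness (NaN diagonal)."""
    ref = allele_frequencies(g)
    n = g.n_individuals
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = wang_relatedness(g, i, j, ref)
    return out


def mean_group_relatedness(g: GenotypeTable, groups) -> DistanceMatrix:
    """Mean between-group pairwise relatedness (zero diagonal by
    convention; pairs with no shared typed locus are excluded)."""
    gi = group_indices(groups)
    labels = list(gi)
    rel = pairwise_relatedness_matrix(g)
    k = len(labels)
    vals = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            block = rel[np.ix_(gi[labels[a]], gi[labels[b]])]
            vals[a, b] = vals[b, a] = float(np.nanmean(block))
    return DistanceMatrix(labels, vals, bounded=False)


# ---------------------------------------------------------------------------
# LD-based effective population size
# ---------------------------------------------------------------------------

def _pair_r2(g: GenotypeTable, idx, a: int, b: int, p_crit: float):
    """Mean Burrows' composite r^2 over allele pairs for one locus pair.

    Returns (mean r2, n allele comparisons, S) or None when fewer than
    one usable allele on either side.
    """
    calls_a = g.alleles[idx, a, :]
    calls_b = g.alleles[idx, b, :]
    both = (calls_a[:, 0] >= 0) & (calls_b[:, 0] >= 0)
    ca, cb = calls_a[both], calls_b[both]
    S = ca.shape[0]
    if S < 5:
        return None

    def usable(calls):
        al, cnt = np.unique(calls.ravel(), return_counts=True)
        freq = cnt / cnt.sum()
        keep = al[freq >= p_crit]
        # drop one allele to avoid the redundant complement at biallelic loci
        return keep[:-1] if keep.size > 1 else keep[:0]

    al_a, al_b = usable(ca), usable(cb)
    if al_a.size == 0 or al_b.size == 0:
        return None
    r2s = []
    for A in al_a:
        x = (ca == A).sum(axis=1).astype(float)
        pA = x.mean() / 2
        DA = np.mean(x == 2) - pA**2
        vara = pA * (1 - pA) + DA
        for Bl in al_b:
            y = (cb == Bl).sum(axis=1).astype(float)
            pB = y.mean() / 2
            DB = np.mean(y == 2) - pB**2
            varb = pB * (1 - pB) + DB
            if vara <= 0 or varb <= 0:
                continue
            delta = (S / (S - 1)) * (np.mean(x * y) / 2 - 2 * pA * pB)
            r2s.append(delta**2 / (vara * varb))
    if not r2s:
        return None
    return float(np.mean(r2s)), len(r2s), S


def _expected_r2(S: float) -> float:
    if S >= 30:
        return 1 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def _ne_from_r2drift(r2d: float, S: float) -> float:
    if r2d <= 0:
        return np.inf
    if S >= 30:
        disc = max(1 / 9 - 2.76 * r2d, 0.0)
        return (1 / 3 + np.sqrt(disc)) / (2 * r2d)
    disc = max(0.308**2 - 2.08 * r2d, 0.0)
    return (0.308 + np.sqrt(disc)) / (2 * r2d)


def ld_ne(g: GenotypeTable, group_idx, p_crit: float = 0.02) -> dict:
    """LD effective population size (Waples 2006, random mating).

    Burrows' composite disequilibrium over all locus pairs after
    filtering alleles below ``p_crit``; duplicated (perfectly linked)
    locus pairs are excluded; jackknife over locus pairs gives the CI.
    Non-positive drift r^2 is reported as infinity.
    """
    idx = np.asarray(group_idx)
    stats = []
    for a in range(g.n_loci):
        for b in range(a + 1, g.n_loci):
            res = _pair_r2(g, idx, a, b, p_crit)
            if res is None:
                continue
            r2, k, S = res
            # perfect-linkage guard: duplicated loci produce r2 ~= 1
            if r2 > 0.98:
                continue
            stats.append((r2, k, S))
    if len(stats) < 2:
        return {"Ne": np.nan, "ci": (np.nan, np.nan), "defined": False}
    r2 = np.array([s[0] for s in stats])
    wk = np.array([s[1] for s in stats], dtype=float)
    S = np.array([s[2] for s in stats], dtype=float)

    def estimate(mask) -> tuple[float, float]:
        w = wk[mask]
        rbar = np.sum(w * r2[mask]) / w.sum()
        s_harm = w.sum() / np.sum(w / S[mask])
        r2d = rbar - _expected_r2(s_harm)
        return r2d, s_harm

    r2d, s_harm = estimate(np.ones(len(stats), bool))
    ne = _ne_from_r2drift(r2d, s_harm)
    # delete-one jackknife on the drift r^2
    n = len(stats)
    jack = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        jack[i], _ = estimate(mask)
    var_j = (n - 1) / n * np.sum((jack - jack.mean()) ** 2)
    half = 1.96 * np.sqrt(var_j)
    lo_r2, hi_r2 = r2d - half, r2d + half
    ci = (_ne_from_r2drift(hi_r2, s_harm), _ne_from_r2drift(lo_r2, s_harm))
    return {"Ne": ne, "ci": ci, "defined": True, "r2_drift": r2d,
            "n_pairs": n, "S": s_harm}
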