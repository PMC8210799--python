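"""Sequence-level (mtDNA) statistics.

Haplotype collapsing and site classification, p/JC69/TN93 distances,
haplotype and nucleotide diversity, Tajima's D and Fu & Li's D*
neutrality tests, Hudson's F_ST with the Snn nearest-neighbour
permutation test, AMOVA Phi_ST on model distances, Nei's net divergence
d_A, and a median-joining haplotype network.

Missing-data conventions follow the standard sequence-analysis tools:
pairwise deletion for distances, complete deletion (columns containing
any N or gap dropped, count reported) for the site-frequency statistics
S, pi, theta_W, D and D*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._util import group_indices, perm_pvalue, rng_from
from .datatypes import DistanceMatrix, SequenceAlignment

VALID = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# site handling and haplotypes
# ---------------------------------------------------------------------------

def _clean_matrix(a: SequenceAlignment) -> tuple[np.ndarray, int]:
    """Complete deletion: drop columns with any non-ACGT state.

    Returns (matrix restricted to clean columns, number dropped).
    """
    m = a.to_matrix()
    ok = np.isin(m, VALID).all(axis=0)
    return m[:, ok], int((~ok).sum())


@dataclass
class HaplotypeSet:
    """Unique haplotypes with per-group counts and site classification."""

    haplotypes: list[str]
    assignments: np.ndarray          # sequence index -> haplotype index
    counts: pd.DataFrame             # haplotype x group counts
    n_segregating: int
    n_singleton_mutations: int
    n_parsimony_informative: int
    n_mutations: int                 # eta: sum over sites of (alleles - 1)
    length: int                      # clean alignment length
    n_sites_dropped: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def classify_sites(m: np.ndarray) -> dict:
    """S, eta, singleton mutations and parsimony-informative count.

    A singleton mutation is a variant allele observed exactly once
    (capped at alleles-1 per site when every allele is unique); a
    parsimony-informative site has >= 2 alleles each in >= 2 copies.
    """
    S = eta = singletons = pars_inf = 0
    for j in range(m.shape[1]):
        _, cnt = np.unique(m[:, j], return_counts=True)
        k = cnt.size
        if k < 2:
            continue
        S += 1
        eta += k - 1
        singletons += min(int(np.sum(cnt == 1)), k - 1)
        if np.sum(cnt >= 2) >= 2:
            pars_inf += 1
    return dict(S=S, eta=eta, singletons=singletons,
                parsimony_informative=pars_inf)


def collapse_haplotypes(
    a: SequenceAlignment, groups=None
) -> HaplotypeSet:
    """Collapse identical sequences (on complete-deletion columns)."""
    if a.n_sequences == 0:
        raise ValueError("empty alignment")
    m, dropped = _clean_matrix(a)
    keys = [bytes(row) for row in m]
    uniq: dict[bytes, int] = {}
    assign = np.empty(a.n_sequences, dtype=int)
    for i, key in enumerate(keys):
        if key not in uniq:
            uniq[key] = len(uniq)
        assign[i] = uniq[key]
    haps = [k.decode() for k in uniq]
    if groups is None:
        groups = np.array(["all"] * a.n_sequences)
    groups = np.asarray(groups)
    counts = pd.crosstab(pd.Series(assign, name="haplotype"),
                         pd.Series(groups, name="group"))
    counts = counts.reindex(range(len(haps)), fill_value=0)
    sites = classify_sites(m)
    return HaplotypeSet(
        haplotypes=haps,
        assignments=assign,
        counts=counts,
        n_segregating=sites["S"],
        n_singleton_mutations=sites["singletons"],
        n_parsimony_informative=sites["parsimony_informative"],
        n_mutations=sites["eta"],
        length=m.shape[1],
        n_sites_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _base_frequencies(m: np.ndarray) -> np.ndarray:
    """Empirical (A, C, G, T) frequencies over all valid cells."""
    flat = m.ravel()
    flat = flat[np.isin(flat, VALID)]
    return np.array([np.mean(flat == b) for b in VALID])


def seq_distance(a: SequenceAlignment, model: str = "JC69") -> DistanceMatrix:
    """Pairwise model distances with pairwise deletion of N/gap sites.

    Models: 'p' (raw proportion), 'JC69' (-3/4 ln(1-4p/3); infinite and
    flagged when p >= 3/4), 'TN93' (empirical base frequencies, separate
    purine and pyrimidine transition classes).
    """
    m = a.to_matrix()
    n = a.n_sequences
    valid = np.isin(m, VALID)
    is_a, is_c = m == b"A", m == b"C"
    is_g, is_t = m == b"G", m == b"T"
    purine = is_a | is_g
    d = np.zeros((n, n))
    if model == "TN93":
        pi = _base_frequencies(m)
        pa, pc, pg, pt = pi
        pr, py = pa + pg, pc + pt
        k1 = 2 * pa * pg / pr
        k2 = 2 * pt * pc / py
        k3 = 2 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        L = both.sum(axis=1).astype(float)
        diff = (m[i] != m[i + 1:]) & both
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(L > 0, diff.sum(axis=1) / L, np.nan)
            if model == "p":
                dist = p
            elif model == "JC69":
                dist = np.where(
                    p < 0.75, -0.75 * np.log(1 - 4 * np.minimum(p, 0.749999) / 3),
                    np.inf,
                )
                dist = np.where(p == 0, 0.0, dist)
            elif model == "TN93":
                ts = diff & (purine[i] == purine[i + 1:])
                p1 = (ts & purine[i]).sum(axis=1) / L
                p2 = (ts & ~purine[i]).sum(axis=1) / L
                q = (diff & (purine[i] != purine[i + 1:])).sum(axis=1) / L
                # degenerate base classes: a transition class with zero
                # stationary mass cannot occur; its term vanishes
                w1 = 1 - (p1 / k1 if k1 > 0 else 0.0) - (
                    q / (2 * pr) if pr > 0 else 0.0
                )
                w2 = 1 - (p2 / k2 if k2 > 0 else 0.0) - (
                    q / (2 * py) if py > 0 else 0.0
                )
                w3 = (
                    1 - q / (2 * pr * py) if pr > 0 and py > 0 else np.ones_like(q)
                )
                bad = (w1 <= 0) | (w2 <= 0) | (w3 <= 0)
                bad |= (p1 > 0) & (k1 == 0)
                bad |= (p2 > 0) & (k2 == 0)
                dist = np.where(
                    bad,
                    np.inf,
                    -k1 * np.log(np.where(w1 > 0, w1, 1))
                    - k2 * np.log(np.where(w2 > 0, w2, 1))
                    - k3 * np.log(np.where(w3 > 0, w3, 1)),
                )
            else:
                raise ValueError(f"unknown model '{model}'")
        d[i, i + 1:] = d[i + 1:, i] = dist
    return DistanceMatrix(list(a.sequence_ids), d)


def raw_difference_matrix(a: SequenceAlignment) -> np.ndarray:
    """Pairwise count of differences on complete-deletion columns."""
    m, _ = _clean_matrix(a)
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1:] = d[i + 1:, i] = (m[i] != m[i + 1:]).sum(axis=1)
    return d


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def harmonic(n: int, power: int = 1) -> float:
    return float(np.sum(1.0 / np.arange(1, n) ** power)) if n > 1 else 0.0


def seq_diversity(a: SequenceAlignment) -> dict:
    """Hd, per-site pi and theta_W for one group of sequences.

    Hd uses the unbiased (n/(n-1)) correction; pi is the mean pairwise
    difference divided by the complete-deletion length; theta_W is
    S/(a1 L).  Undefined (flagged) for n < 2.
    """
    n = a.n_sequences
    if n < 2:
        return dict(Hd=np.nan, pi=np.nan, thetaW=np.nan, S=0, defined=False)
    m, dropped = _clean_matrix(a)
    L = m.shape[1]
    hs = collapse_haplotypes(a)
    f = hs.counts.sum(axis=1).to_numpy(float) / n
    hd = (n / (n - 1)) * (1 - np.sum(f**2))
    diffs = raw_difference_matrix(a)
    iu = np.triu_indices(n, k=1)
    pi = float(diffs[iu].mean() / L) if L else 0.0
    sites = classify_sites(m)
    theta = sites["S"] / (harmonic(n) * L) if L else 0.0
    return dict(
        Hd=float(hd), pi=pi, thetaW=float(theta), S=sites["S"],
        eta=sites["eta"], singletons=sites["singletons"],
        L=L, n_sites_dropped=dropped, defined=True,
    )


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------

def tajimas_d(n: int, S: int, pi_total: float) -> float:
    """Tajima (1989) D from sample size, segregating sites and the mean
    pairwise difference (per sequence, not per site)."""
    if S == 0 or n < 4:
        return np.nan
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / np.sqrt(var))


def tajima_confint(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Nominal two-sided confidence limits for Tajima's D under
    neutrality, from the scaled-beta approximation (mean 0, variance 1
    on the attainable range [Dmin, Dmax])."""
    from scipy import stats as sps

    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e2 = c2 / (a1**2 + a2)
    dmin = (2 / n - 1 / a1) / np.sqrt(e2)
    dmax = (n / (2 * (n - 1)) - 1 / a1) / np.sqrt(e2)
    rng_ = dmax - dmin
    m = (0 - dmin) / rng_
    v = 1 / rng_**2
    k = m * (1 - m) / v - 1
    dist = sps.beta(m * k, (1 - m) * k, loc=dmin, scale=rng_)
    return float(dist.ppf(alpha / 2)), float(dist.ppf(1 - alpha / 2))


def fu_li_d_star(n: int, eta: int, eta_s: int) -> float:
    """Fu & Li (1993) D* (no outgroup) from total mutations eta and
    singleton mutations eta_s, with the corrected variance constants."""
    if eta == 0 or n < 4:
        return np.nan
    an = harmonic(n)
    bn = harmonic(n, 2)
    an1 = an + 1.0 / n
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    v = (
        (n / (n - 1)) ** 2 * bn
        + an**2 * dn
        - 2 * (n * an * (an + 1)) / (n - 1) ** 2
    ) / (an**2 + bn)
    u = (n / (n - 1)) * (an - n / (n - 1)) - v
    num = (n / (n - 1)) * eta - an * eta_s
    return float(num / np.sqrt(u * eta + v * eta**2))


def neutrality_tests(a: SequenceAlignment) -> dict:
    """Tajima's D and Fu & Li's D* for one group (NaN-flagged at S=0)."""
    n = a.n_sequences
    m, _ = _clean_matrix(a)
    sites = classify_sites(m)
    if sites["S"] == 0:
        return dict(TajimaD=np.nan, FuLiDstar=np.nan, defined=False)
    diffs = raw_difference_matrix(a)
    iu = np.triu_indices(n, k=1)
    pi_total = float(diffs[iu].mean())
    return dict(
        TajimaD=tajimas_d(n, sites["S"], pi_total),
        FuLiDstar=fu_li_d_star(n, sites["eta"], sites["singletons"]),
        defined=True,
    )


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _within_between(d: np.ndarray, ia, ib) -> tuple[float, float, float]:
    def mean_within(ix):
        if len(ix) < 2:
            return np.nan
        sub = d[np.ix_(ix, ix)]
        iu = np.triu_indices(len(ix), k=1)
        return float(sub[iu].mean())

    hw_a, hw_b = mean_within(ia), mean_within(ib)
    hb = float(d[np.ix_(ia, ib)].mean())
    return hw_a, hw_b, hb


def snn_statistic(d: np.ndarray, labels: np.ndarray) -> float:
    """Hudson's (2000) nearest-neighbour statistic with fractional ties."""
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        row = d[i].copy()
        row[i] = np.inf
        nearest = row == row.min()
        total += np.sum(nearest & (labels == labels[i])) / np.sum(nearest)
    return total / n


def hudson_fst(
    a: SequenceAlignment, labels, group_a, group_b,
    n_perm: int = 1000, seed=None,
) -> dict:
    """Hudson F_ST = 1 - Hw/Hb on raw differences, with the Snn
    permutation test for significance (ties split fractionally)."""
    labels = np.asarray(labels)
    ia = np.flatnonzero(labels == group_a)
    ib = np.flatnonzero(labels == group_b)
    sub = a.subset(np.concatenate([ia, ib]).tolist())
    lab = np.array([0] * ia.size + [1] * ib.size)
    d = raw_difference_matrix(sub)
    hw_a, hw_b, hb = _within_between(d, np.flatnonzero(lab == 0),
                                     np.flatnonzero(lab == 1))
    if np.isnan(hw_a) or np.isnan(hw_b):
        fst = np.nan
    else:
        hw = (hw_a + hw_b) / 2
        fst = 1 - hw / hb if hb > 0 else np.nan
    obs = snn_statistic(d, lab)
    rng = rng_from(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = snn_statistic(d, rng.permutation(lab))
    return dict(FST=fst, Snn=float(obs), p=perm_pvalue(null, obs),
                defined=not (np.isnan(hw_a) or np.isnan(hw_b)))


def amova_phi_st(d: np.ndarray, labels: np.ndarray) -> float:
    """Two-level AMOVA on a (squared-)distance matrix.

    Model distances are treated as squared Euclidean distances in the
    sums of squares (the sequence-AMOVA convention).  Negative variance
    components are reported as computed.
    """
    labels = np.asarray(labels)
    n = d.shape[0]
    groups = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    G = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d[iu].sum() / n
    ss_within = 0.0
    for ix in groups:
        if len(ix) < 2:
            continue
        sub = d[np.ix_(ix, ix)]
        ss_within += sub[np.triu_indices(len(ix), k=1)].sum() / len(ix)
    if not np.isfinite(ss_total) or not np.isfinite(ss_within):
        return np.nan
    ss_among = ss_total - ss_within
    df_a, df_w = G - 1, n - G
    if df_w <= 0 or df_a <= 0:
        return np.nan
    ms_w = ss_within / df_w
    ms_a = ss_among / df_a
    sizes = np.array([len(ix) for ix in groups], dtype=float)
    n_prime = (n - np.sum(sizes**2) / n) / df_a
    sigma_a = (ms_a - ms_w) / n_prime
    denom = sigma_a + ms_w
    return float(sigma_a / denom) if denom != 0 else np.nan


def phi_st(
    a: SequenceAlignment, labels, group_a, group_b,
    model: str = "TN93", n_perm: int = 1000, seed=None,
) -> dict:
    """Pairwise AMOVA Phi_ST on model distances with permutation p."""
    labels = np.asarray(labels)
    ia = np.flatnonzero(labels == group_a)
    ib = np.flatnonzero(labels == group_b)
    sub = a.subset(np.concatenate([ia, ib]).tolist())
    lab = np.array([0] * ia.size + [1] * ib.size)
    d = seq_distance(sub, model=model).values
    obs = amova_phi_st(d, lab)
    rng = rng_from(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = amova_phi_st(d, rng.permutation(lab))
    return dict(PhiST=float(obs), p=perm_pvalue(null, obs))


def phi_st_matrix(
    a: SequenceAlignment, labels, model: str = "TN93",
    min_size: int = 2,
) -> DistanceMatrix:
    """Pairwise Phi_ST matrix over all groups with >= min_size members."""
    labels = np.asarray(labels)
    gi = {l: ix for l, ix in group_indices(labels).items()
          if ix.size >= min_size}
    names = list(gi)
    d_all = seq_distance(a, model=model).values
    k = len(names)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ix = np.concatenate([gi[names[i]], gi[names[j]]])
            lab = np.array([0] * gi[names[i]].size + [1] * gi[names[j]].size)
            vals[i, j] = vals[j, i] = amova_phi_st(d_all[np.ix_(ix, ix)], lab)
    return DistanceMatrix(names, vals, bounded=False)


def net_divergence(
    a: SequenceAlignment, labels, model: str = "JC69"
) -> DistanceMatrix:
    """Nei's d_A = d_between - (d_within_A + d_within_B)/2.

    Singleton groups contribute within-distance 0 by convention.
    """
    labels = np.asarray(labels)
    d = seq_distance(a, model=model).values
    gi = group_indices(labels)
    names = list(gi)
    k = len(names)
    vals = np.zeros((k, k))
    within = {}
    for name, ix in gi.items():
        hw, _, _ = _within_between(d, ix, ix)
        within[name] = 0.0 if np.isnan(hw) else hw
    for i in range(k):
        for j in range(i + 1, k):
            hb = float(d[np.ix_(gi[names[i]], gi[names[j]])].mean())
            vals[i, j] = vals[j, i] = hb - (
                within[names[i]] + within[names[j]]
            ) / 2
    return DistanceMatrix(names, vals, bounded=False)


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------

def _hamming(x: np.ndarray, y: np.ndarray) -> int:
    return int(np.sum(x != y))


def _msn_edges(vecs: list[np.ndarray]) -> list[tuple[int, int, int]]:
    """Minimum spanning network (epsilon = 0): Kruskal by distance rank,
    admitting every edge of a rank that joins components still separate
    when the rank is opened."""
    n = len(vecs)
    edges = sorted(
        (( _hamming(vecs[i], vecs[j])), i, j)
        for i in range(n) for j in range(i + 1, n)
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    k = 0
    while k < len(edges):
        w = edges[k][0]
        batch = []
        while k < len(edges) and edges[k][0] == w:
            batch.append(edges[k])
            k += 1
        admitted = [(w, i, j) for w, i, j in batch if find(i) != find(j)]
        for w_, i, j in admitted:
            out.append((i, j, w_))
        for w_, i, j in admitted:
            parent[find(i)] = find(j)
    return out


def median_joining_network(
    h: HaplotypeSet, epsilon: int = 0, max_haplotypes: int = 5000
) -> nx.Graph:
    """Median-joining network (Bandelt et al. 1999 scheme, epsilon=0).

    Median (Steiner) vectors are added from majority consensus of
    connected triplets whenever they shorten the spanning structure;
    medians that end up with degree <= 2 are pruned.  Nodes carry
    ``is_median`` and per-group counts.
    """
    if h.n_haplotypes > max_haplotypes:
        raise ValueError(f"refusing network with > {max_haplotypes} haplotypes")
    if epsilon != 0:
        raise NotImplementedError("only epsilon = 0 is supported")
    vecs = [np.frombuffer(s.encode(), dtype="S1").copy() for s in h.haplotypes]
    n_obs = len(vecs)
    seen = {bytes(v) for v in vecs}

    def mst_weight(vs):
        tree = nx.minimum_spanning_tree(_to_graph(vs, _msn_edges(vs)))
        return tree.size(weight="weight")

    def _to_graph(vs, edges):
        g = nx.Graph()
        g.add_nodes_from(range(len(vs)))
        g.add_weighted_edges_from(edges)
        return g

    for _ in range(20):
        edges = _msn_edges(vecs)
        graph = _to_graph(vecs, edges)
        base = mst_weight(vecs)
        added = False
        triples = set()
        for u in graph.nodes:
            nbrs = list(graph.neighbors(u))
            for ii in range(len(nbrs)):
                for jj in range(ii + 1, len(nbrs)):
                    triples.add(tuple(sorted((u, nbrs[ii], nbrs[jj]))))
        candidates = []
        for (u, v, w) in triples:
            cols = np.stack([vecs[u], vecs[v], vecs[w]])
            med = vecs[u].copy()
            for col in range(cols.shape[1]):
                vals, cnts = np.unique(cols[:, col], return_counts=True)
                med[col] = vals[np.argmax(cnts)]
            key = bytes(med)
            if key not in seen:
                candidates.append(med)
                seen.add(key)
        for med in candidates:
            trial = vecs + [med]
            if mst_weight(trial) < base:
                vecs.append(med)
                added = True
            else:
                seen.discard(bytes(med))
        if not added:
            break

    # prune medians of degree <= 2, iteratively
    while True:
        edges = _msn_edges(vecs)
        graph = _to_graph(vecs, edges)
        prune = [
            i for i in range(n_obs, len(vecs)) if graph.degree(i) <= 2
        ]
        if not prune:
            break
        keep = [i for i in range(len(vecs)) if i not in set(prune)]
        vecs = [vecs[i] for i in keep]

    edges = _msn_edges(vecs)
    net = nx.Graph()
    group_cols = list(h.counts.columns)
    for i, v in enumerate(vecs):
        is_median = i >= n_obs
        attrs = dict(is_median=is_median, sequence=bytes(v).decode())
        if not is_median:
            attrs["counts"] = {
                g: int(h.counts.iloc[i][g]) for g in group_cols
            }
        net.add_node(i, **attrs)
    for i, j, w in edges:
        net.add_edge(i, j, weight=w)
    return net
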