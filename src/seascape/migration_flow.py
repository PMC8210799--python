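"""Directional relative migration and percolation-threshold networks.

Follows the divMigrate logic (Sundqvist et al. 2016): for each ordered
pair of demes a hypothetical pool of their allele frequencies is built;
the G_ST of each deme against the pool measures how much that deme has
diverged from the shared migrant pool, and its Wright-island transform
((1/G) - 1)/4 is read as the relative number of migrants INTO the deme.
All directed values are divided by the global maximum, so the strongest
edge is 1.  Bootstrapping genotypes within demes yields percentile CIs;
an edge pair is significantly asymmetric when the two CIs do not
overlap.  Networks are thresholded at the percolation threshold - the
largest cutoff that keeps the (undirected) graph connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._util import group_indices, rng_from
from .datatypes import GenotypeTable


@dataclass
class MigrationNetwork:
    labels: list
    m: np.ndarray                  # directed relative migration, [0, 1]
    m_raw: np.ndarray              # pre-normalisation values
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    percolation_threshold: float | None = None

    def asymmetry_significant(self) -> np.ndarray:
        """True where m[i,j] and m[j,i] bootstrap CIs do not overlap."""
        if self.ci_low is None:
            raise ValueError("run with bootstraps to get CIs")
        k = len(self.labels)
        out = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                out[i, j] = (
                    self.ci_low[i, j] > self.ci_high[j, i]
                    or self.ci_high[i, j] < self.ci_low[j, i]
                )
        return out

    def to_graph(self, threshold: float = 0.0) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        k = len(self.labels)
        for i in range(k):
            for j in range(k):
                if i != j and np.isfinite(self.m[i, j]) and self.m[i, j] >= threshold:
                    g.add_edge(self.labels[i], self.labels[j],
                               weight=float(self.m[i, j]))
        return g


def _locus_freqs(alleles: np.ndarray) -> dict[int, float]:
    col = alleles.ravel()
    col = col[col >= 0]
    if col.size == 0:
        return {}
    vals, cnt = np.unique(col, return_counts=True)
    return dict(zip(vals.tolist(), (cnt / col.size).tolist()))


def _nei_gst(freqs_a: dict, freqs_b: dict) -> float:
    """Nei's G_ST between two frequency vectors (equal weight)."""
    alleles = set(freqs_a) | set(freqs_b)
    pa = np.array([freqs_a.get(x, 0.0) for x in sorted(alleles)])
    pb = np.array([freqs_b.get(x, 0.0) for x in sorted(alleles)])
    hs = 1 - 0.5 * (np.sum(pa**2) + np.sum(pb**2))
    pbar = (pa + pb) / 2
    ht = 1 - np.sum(pbar**2)
    if ht <= 0:
        return np.nan
    return (ht - hs) / ht


def _multilocus_gst(ga: list[dict], gb: list[dict]) -> float:
    """G_ST from heterozygosities summed over loci (Nei's formulation)."""
    hs_tot = ht_tot = 0.0
    for fa, fb in zip(ga, gb):
        if not fa or not fb:
            continue
        alleles = sorted(set(fa) | set(fb))
        pa = np.array([fa.get(x, 0.0) for x in alleles])
        pb = np.array([fb.get(x, 0.0) for x in alleles])
        hs_tot += 1 - 0.5 * (np.sum(pa**2) + np.sum(pb**2))
        pbar = (pa + pb) / 2
        ht_tot += 1 - np.sum(pbar**2)
    if ht_tot <= 0:
        return np.nan
    return (ht_tot - hs_tot) / ht_tot


def _group_locus_freqs(g: GenotypeTable, idx) -> list[dict]:
    return [_locus_freqs(g.alleles[idx, j, :]) for j in range(g.n_loci)]


def _pool(fa: dict, fb: dict) -> dict:
    alleles = set(fa) | set(fb)
    return {x: (fa.get(x, 0.0) + fb.get(x, 0.0)) / 2 for x in alleles}


def _raw_directional(g: GenotypeTable, gi: dict) -> np.ndarray:
    """Unnormalised directed migration for all ordered deme pairs."""
    labels = list(gi)
    freqs = {lab: _group_locus_freqs(g, gi[lab]) for lab in labels}
    k = len(labels)
    raw = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            fa, fb = freqs[labels[i]], freqs[labels[j]]
            pool = [_pool(x, y) for x, y in zip(fa, fb)]
            gst_in = _multilocus_gst(fb, pool)  # receiver j vs pair pool
            if not np.isfinite(gst_in):
                continue
            gst_in = max(gst_in, 1e-12)
            raw[i, j] = ((1.0 / gst_in) - 1.0) / 4.0
    return raw


def directional_migration(
    g: GenotypeTable,
    groups,
    min_size: int = 10,
    n_boot: int = 0,
    seed=None,
) -> MigrationNetwork:
    """divMigrate-style directional relative migration (G_ST based).

    Groups below ``min_size`` individuals are excluded.  ``n_boot`` > 0
    resamples individuals (diploid genotypes, not alleles) within
    groups for 95% percentile CIs per directed edge.  Monomorphic pairs
    yield undefined (NaN) edges.
    """
    gi = {l: ix for l, ix in group_indices(groups).items()
          if ix.size >= min_size}
    labels = list(gi)
    raw = _raw_directional(g, gi)
    mx = np.nanmax(raw)
    m = raw / mx if mx and np.isfinite(mx) else raw.copy()
    net = MigrationNetwork(labels, m, raw)
    if n_boot > 0:
        rng = rng_from(seed)
        k = len(labels)
        boots = np.empty((n_boot, k, k))
        for b in range(n_boot):
            gi_b = {}
            parts, labs = [], []
            for lab in labels:
                take = rng.choice(gi[lab], size=gi[lab].size, replace=True)
                parts.append(take)
                labs.extend([lab] * take.size)
            sub = g.subset(np.concatenate(parts))
            gi_sub = group_indices(np.asarray(labs, dtype=object))
            raw_b = _raw_directional(sub, gi_sub)
            mx_b = np.nanmax(raw_b)
            boots[b] = raw_b / mx_b if mx_b and np.isfinite(mx_b) else raw_b
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # NaN diagonal
            net.ci_low = np.nanpercentile(boots, 2.5, axis=0)
            net.ci_high = np.nanpercentile(boots, 97.5, axis=0)
    return net


def percolation_threshold(net: MigrationNetwork) -> float:
    """Largest cutoff t keeping the undirected graph connected.

    Undirected edge weight = mean of the two directed weights.  Equals
    the bottleneck of the maximum-bottleneck spanning tree, hence
    invariant under monotone transforms of the weights.  NaN when the
    full network is already disconnected.
    """
    k = len(net.labels)
    gr = nx.Graph()
    gr.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            vals = [v for v in (net.m[i, j], net.m[j, i]) if np.isfinite(v)]
            if vals:
                gr.add_edge(i, j, weight=float(np.mean(vals)))
    if gr.number_of_edges() == 0 or not nx.is_connected(gr):
        return np.nan
    mst = nx.maximum_spanning_tree(gr, weight="weight")
    return float(min(d["weight"] for _, _, d in mst.edges(data=True)))


def percolation_network(net: MigrationNetwork) -> tuple[nx.DiGraph, float]:
    """Directed network pruned at the percolation threshold."""
    t = percolation_threshold(net)
    if np.isnan(t):
        return net.to_graph(0.0), t
    net.percolation_threshold = t
    return net.to_graph(t), t


def effective_migrants(
    ne: dict, net: MigrationNetwork
) -> pd.DataFrame:
    """2*Ne*m per directed edge: for a->b, 2 * Ne(a) * m(a->b).

    Infinite Ne propagates to infinity; demes without an Ne estimate
    are flagged (NaN).
    """
    rows = []
    k = len(net.labels)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            src, dst = net.labels[i], net.labels[j]
            ne_src = ne.get(src, np.nan)
            m = net.m[i, j]
            rows.append(
                dict(source=src, dest=dst, m=m, Ne_source=ne_src,
                     two_Ne_m=2 * ne_src * m)
            )
    return pd.DataFrame(rows)
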