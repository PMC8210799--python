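"""Ordination of genotype data: PCA, DAPC, spatial PCA and nMDS.

Genotypes are coded as an individuals x allele-indicator dosage matrix
(0/1/2 copies per allele column), centred to zero mean.  PCA mean-
imputes missing calls; DAPC and sPCA use complete cases only.  The
spatial PCA decomposes the covariance between the genotype matrix and
its spatial lag over a connection network (Delaunay by default):
positive eigenvalues capture global (cline/patch) structure, negative
ones local heterogeneity, and permutation tests shuffle individuals
over locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, distance_matrix as _distmat
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from ._util import rng_from
from .datatypes import DistanceMatrix, GenotypeTable


@dataclass
class OrdinationResult:
    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray | None = None
    membership: np.ndarray | None = None      # DAPC posteriors
    global_p: float | None = None             # sPCA
    local_p: float | None = None
    stress: float | None = None               # nMDS


# ---------------------------------------------------------------------------
# allele-indicator matrix
# ---------------------------------------------------------------------------

def allele_matrix(
    g: GenotypeTable, missing: str = "mean"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, kept_rows, column names): centred allele-dosage matrix.

    ``missing='mean'`` imputes missing calls with the column mean
    (PCA convention); ``missing='drop'`` keeps complete cases only.
    """
    cols = []
    names = []
    mask = g.missing_mask()
    for j, locus in enumerate(g.locus_names):
        col = g.alleles[:, j, :]
        alleles = np.unique(col[col >= 0])
        for a in alleles:
            dose = (col == a).sum(axis=1).astype(float)
            dose[mask[:, j]] = np.nan
            cols.append(dose)
            names.append(f"{locus}.{a}")
    X = np.stack(cols, axis=1)
    if missing == "drop":
        keep = np.flatnonzero(~np.isnan(X).any(axis=1))
        X = X[keep]
    else:
        keep = np.arange(g.n_individuals)
        mu = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(mu, inds[1])
    X = X - X.mean(axis=0)
    return X, keep, names


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(X: np.ndarray, n_axes: int | None = None) -> OrdinationResult:
    """Eigendecomposition of the covariance of the centred matrix."""
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / n
    rank = int(np.sum(s > 1e-10))
    if n_axes is None:
        n_axes = rank
    if n_axes > rank:
        import warnings

        warnings.warn(f"requested {n_axes} axes; rank is {rank}")
        n_axes = rank
    scores = U[:, :n_axes] * s[:n_axes]
    return OrdinationResult(scores, eig[:n_axes], loadings=Vt[:n_axes].T)


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

def dapc(
    X: np.ndarray, groups, n_pca: int = 30
) -> OrdinationResult:
    """PCA reduction then LDA on groups; Gaussian posteriors with equal
    priors give per-individual membership probabilities."""
    groups = np.asarray(groups)
    classes = np.unique(groups)
    if classes.size < 2:
        raise ValueError("DAPC needs at least two groups")
    if n_pca >= X.shape[0] - classes.size:
        raise ValueError("n_pca too large for the number of individuals")
    pc = pca(X, n_axes=n_pca)
    lda = LinearDiscriminantAnalysis(priors=np.full(classes.size, 1 / classes.size))
    lda.fit(pc.scores, groups)
    df_scores = lda.transform(pc.scores)
    membership = lda.predict_proba(pc.scores)
    eig = np.asarray(lda.explained_variance_ratio_)
    return OrdinationResult(df_scores, eig, membership=membership)


def alpha_score(
    X: np.ndarray, groups, n_pca_grid, seed=None, n_rep: int = 10
) -> dict[int, float]:
    """Observed minus random reassignment rate over a grid of n_pca."""
    rng = rng_from(seed)
    groups = np.asarray(groups)
    out = {}
    for n_pca in n_pca_grid:
        try:
            res = dapc(X, groups, n_pca=n_pca)
        except ValueError:
            continue
        classes = np.unique(groups)
        pred = classes[np.argmax(res.membership, axis=1)]
        obs = float(np.mean(pred == groups))
        rand = []
        for _ in range(n_rep):
            perm = rng.permutation(groups)
            r = dapc(X, perm, n_pca=n_pca)
            pr = np.unique(perm)[np.argmax(r.membership, axis=1)]
            rand.append(float(np.mean(pr == perm)))
        out[n_pca] = obs - float(np.mean(rand))
    return out


# ---------------------------------------------------------------------------
# spatial PCA
# ---------------------------------------------------------------------------

def connection_network(
    coords: np.ndarray, kind: str = "delaunay", k: int = 5,
    jitter: float = 0.0, seed=None,
) -> np.ndarray:
    """Row-normalised spatial weight matrix L.

    'delaunay' (default, the study's choice), 'gabriel' (Delaunay edges
    whose diameter-circle holds no third point) or 'knn'.  Duplicate
    coordinates break the triangulation; pass ``jitter`` > 0 to add
    uniform noise, otherwise an error is raised.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if jitter > 0:
        coords = coords + rng_from(seed).uniform(-jitter, jitter, coords.shape)
    W = np.zeros((n, n))
    if kind in ("delaunay", "gabriel"):
        uniq = np.unique(coords, axis=0)
        if uniq.shape[0] < n:
            raise ValueError(
                "duplicate coordinates break the triangulation; use jitter"
            )
        tri = Delaunay(coords)
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = simplex[a], simplex[b]
                    W[i, j] = W[j, i] = 1.0
        if kind == "gabriel":
            D = _distmat(coords, coords)
            for i in range(n):
                for j in range(i + 1, n):
                    if W[i, j] == 0:
                        continue
                    mid = (coords[i] + coords[j]) / 2
                    rad = D[i, j] / 2
                    others = np.delete(np.arange(n), [i, j])
                    dd = np.linalg.norm(coords[others] - mid, axis=1)
                    if (dd < rad - 1e-12).any():
                        W[i, j] = W[j, i] = 0.0
    elif kind == "knn":
        D = _distmat(coords, coords)
        np.fill_diagonal(D, np.inf)
        for i in range(n):
            for j in np.argsort(D[i])[:k]:
                W[i, j] = W[j, i] = 1.0
    else:
        raise ValueError(kind)
    rows = W.sum(axis=1)
    rows[rows == 0] = 1.0
    return W / rows[:, None]


def spca(
    X: np.ndarray, coords: np.ndarray, network: str = "delaunay",
    n_perm: int = 10_000, seed=None, n_axes: int | None = None,
) -> OrdinationResult:
    """Spatial PCA with global/local permutation tests.

    Eigenanalysis of (1/2n) X^T (L + L^T) X with L the row-normalised
    connection network; the permutation statistic is the sum of
    positive (global) resp. |negative| (local) eigenvalues under row
    shuffles of X over locations.
    """
    if np.isnan(X).any():
        raise ValueError("sPCA requires complete cases (no missing data)")
    n = X.shape[0]
    L = connection_network(coords, kind=network)
    sym = (L + L.T) / (2 * n)

    def eigvals(mat_x):
        H = mat_x.T @ sym @ mat_x
        H = (H + H.T) / 2
        w, v = np.linalg.eigh(H)
        return w[::-1], v[:, ::-1]

    w, v = eigvals(X)
    if n_axes is None:
        n_axes = w.size
    scores = X @ v[:, :n_axes]
    obs_global = float(w[w > 0].sum())
    obs_local = float(-w[w < 0].sum())
    rng = rng_from(seed)
    null_g = np.empty(n_perm)
    null_l = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        wb, _ = eigvals(X[perm])
        null_g[b] = wb[wb > 0].sum()
        null_l[b] = -wb[wb < 0].sum()
    from ._util import perm_pvalue

    return OrdinationResult(
        scores,
        w[:n_axes],
        loadings=v[:, :n_axes],
        global_p=perm_pvalue(null_g, obs_global),
        local_p=perm_pvalue(null_l, obs_local),
    )


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------

def kruskal_stress(d_obs: np.ndarray, embedding: np.ndarray) -> float:
    """Stress-1 with the optimal monotone (isotonic) disparity fit."""
    n = embedding.shape[0]
    iu = np.triu_indices(n, k=1)
    d_fit = _distmat(embedding, embedding)[iu]
    order = np.argsort(d_obs[iu])
    iso = IsotonicRegression().fit_transform(
        np.arange(order.size), d_fit[order]
    )
    disparity = np.empty_like(d_fit)
    disparity[order] = iso
    denom = np.sum(d_fit**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_fit - disparity) ** 2) / denom))


def classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centred
    squared distance matrix (used to seed the nonmetric iteration)."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    wk = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(wk)


def nmds(
    d: DistanceMatrix, k: int = 2, n_starts: int = 8, seed=None
) -> OrdinationResult:
    """Nonmetric MDS (Kruskal stress-1), classical-scaling start plus
    ``n_starts - 1`` random restarts; the best embedding wins."""
    n = d.n
    if k >= n - 1:
        raise ValueError("k must be < n - 1")
    if np.allclose(d.values, 0):
        return OrdinationResult(np.zeros((n, k)), np.zeros(k), stress=0.0)
    rng = rng_from(seed)
    inits = [classical_mds(d.values, k)]
    inits += [rng.normal(size=(n, k)) for _ in range(max(n_starts - 1, 0))]
    best, best_stress = None, np.inf
    import warnings as _w

    for init in inits:
        with _w.catch_warnings():
            _w.simplefilter("ignore", FutureWarning)
            mds = MDS(
                n_components=k,
                metric=False,
                dissimilarity="precomputed",
                n_init=1,
                random_state=0,
                normalized_stress=False,
                max_iter=1000,
                eps=1e-9,
            )
            emb = mds.fit(d.values, init=init).embedding_
        s = kruskal_stress(d.values, emb)
        if s < best_stress:
            best, best_stress = emb, s
    return OrdinationResult(best, np.zeros(k), stress=best_stress)
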