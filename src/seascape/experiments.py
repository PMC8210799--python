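"""Replicated simulation studies tying the simulator to the estimators.

These are the package's calibration experiments: the mtDNA-vs-nuclear
isolation-by-distance contrast under female philopatry, neutrality-test
calibration on panmictic forward simulations, and LD-Ne recovery on
isolated Wright-Fisher populations.  The analysis drivers, the test
suite and the acceptance script all call these entry points so the
numbers they report come from one code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats as sps

from . import popgen_mtdna as pm
from . import popgen_nuclear as pn
from ._util import rng_from
from .datatypes import GenotypeTable, SequenceAlignment
from .synth import (
    SimulationParams,
    SimulationResult,
    contrast_params,
    simulate_metapopulation,
)


# ---------------------------------------------------------------------------
# IBD contrast
# ---------------------------------------------------------------------------

def ibd_r_squared_pair(res: SimulationResult) -> tuple[float, float]:
    """(mtDNA r^2, nuclear r^2) of linearised differentiation on
    between-group distance for one simulated data set.

    Mirrors the two-level sampling design: nuclear WC F_ST between
    fine subgroups (where a weak biparental signal is best detected),
    AMOVA Phi_ST on TN93 distances between regions (pooling subgroups
    stabilises the single-locus haplotype frequencies).  Distance is
    the along-corridor great-circle proxy (degrees of longitude), exact
    up to a constant factor on the simulated transect, which leaves
    r^2 unchanged.
    """
    from .seascape_ibd import linearised

    def r2(dm, lon):
        iu = np.triu_indices(dm.n, k=1)
        x = np.array([abs(lon[dm.labels[i]] - lon[dm.labels[j]])
                      for i, j in zip(*iu)])
        y = linearised(np.clip(dm.values[iu], None, 0.999))
        return float(sps.linregress(x, y).rvalue ** 2)

    g, meta = res.genotypes, res.metadata
    labels = meta.group_labels(g.individual_ids, "subgroup")
    fst, _ = pn.fst_matrix(g, labels, min_size=5)
    lon_sg = dict(zip(res.truth["deme_coords"]["subgroup"],
                      res.truth["deme_coords"]["lon"]))
    r2_nuc = r2(fst, lon_sg)

    a, mmeta = res.alignment, res.mt_metadata
    rlabs = mmeta.group_labels(a.sequence_ids, "region")
    phist = pm.phi_st_matrix(a, rlabs, model="TN93")
    lon_rg = mmeta.table.groupby("region")["lon"].mean().to_dict()
    r2_mt = r2(phist, lon_rg)
    return r2_mt, r2_nuc


def ibd_contrast_replicates(
    n_reps: int = 100, sigma_ratio: float = 0.2, seed: int = 0
) -> dict:
    """Replicate the philopatry IBD contrast.

    Returns per-replicate r^2 pairs and the fraction of replicates in
    which the mtDNA r^2 exceeds the nuclear r^2.
    """
    base = int(seed) % (2**31 - 10**6)
    pairs = []
    for rep in range(n_reps):
        res = simulate_metapopulation(
            contrast_params(seed=base + rep, sigma_ratio=sigma_ratio)
        )
        pairs.append(ibd_r_squared_pair(res))
    pairs = np.asarray(pairs)
    return dict(
        r2_mt=pairs[:, 0],
        r2_nuc=pairs[:, 1],
        fraction_mt_stronger=float(np.mean(pairs[:, 0] > pairs[:, 1])),
        n_reps=n_reps,
        sigma_ratio=sigma_ratio,
    )


# ---------------------------------------------------------------------------
# neutrality calibration
# ---------------------------------------------------------------------------

def neutrality_calibration(
    n_reps: int = 500,
    sample_size: int = 20,
    deme_size: int = 100,
    generations: int = 1000,
    mt_length: int = 500,
    mu: float = 1e-4,
    seed: int = 0,
) -> dict:
    """Tajima's D on panmictic neutral forward simulations.

    A single-deme run gives a haploid Wright-Fisher mtDNA population of
    size ``deme_size``; D is computed on ``sample_size`` sequences per
    replicate, with the rejection rate at the nominal two-sided 5%
    beta-approximation cutoffs.
    """
    base = int(seed) % (2**31 - 10**6)
    lo, hi = pm.tajima_confint(sample_size, alpha=0.05)
    ds, rejected, skipped = [], 0, 0
    for rep in range(n_reps):
        p = SimulationParams(
            n_demes_x=1, deme_size=deme_size, generations=generations,
            sigma_f=0.5, sigma_m=0.5, n_loci=1, mu_nuclear=0.0,
            mt_length=mt_length, mu_mt=mu,
            sample_per_deme=sample_size, mt_sample_per_deme=sample_size,
            missing_rate=0.0, n_regions=1, seed=base + rep,
        )
        res = simulate_metapopulation(p)
        nt = pm.neutrality_tests(res.alignment)
        if not nt["defined"]:
            skipped += 1
            continue
        ds.append(nt["TajimaD"])
        if nt["TajimaD"] < lo or nt["TajimaD"] > hi:
            rejected += 1
    ds = np.asarray(ds)
    return dict(
        mean_D=float(ds.mean()),
        rejection_rate=rejected / max(len(ds), 1),
        n_effective=len(ds),
        n_skipped=skipped,
        cutoffs=(lo, hi),
    )


# ---------------------------------------------------------------------------
# LD-Ne recovery
# ---------------------------------------------------------------------------

def simulate_wright_fisher_genotypes(
    ne: int, generations: int, n_loci: int, mu: float, seed,
    sample_size: int,
) -> GenotypeTable:
    """Isolated diploid Wright-Fisher population, stepwise mutation."""
    p = SimulationParams(
        n_demes_x=1, deme_size=ne, generations=generations,
        sigma_f=0.5, sigma_m=0.5, n_loci=n_loci, mu_nuclear=mu,
        mt_length=10, mu_mt=0.0, sample_per_deme=sample_size,
        mt_sample_per_deme=1, missing_rate=0.0, n_regions=1, seed=seed,
        init_allele_spread=10,
    )
    return simulate_metapopulation(p).genotypes


def ldne_recovery(
    n_reps: int = 50,
    true_ne: int = 100,
    sample_size: int = 50,
    n_loci: int = 12,
    generations: int = 100,
    mu: float = 5e-4,
    seed: int = 0,
) -> dict:
    """Jackknife-CI coverage of the LD-Ne estimator at known true Ne."""
    base = int(seed) % (2**31 - 10**6)
    covered, estimates = 0, []
    for rep in range(n_reps):
        g = simulate_wright_fisher_genotypes(
            true_ne, generations, n_loci, mu, base + rep, sample_size
        )
        est = pn.ld_ne(g, np.arange(g.n_individuals))
        estimates.append(est["Ne"])
        lo, hi = est["ci"]
        if est["defined"] and lo <= true_ne <= hi:
            covered += 1
    return dict(
        coverage=covered / n_reps,
        estimates=np.asarray(estimates),
        median_ne=float(np.nanmedian(
            np.where(np.isfinite(estimates), estimates, np.nan))),
        true_ne=true_ne,
        n_reps=n_reps,
    )
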