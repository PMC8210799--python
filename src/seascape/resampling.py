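"""Sample-size standardisation by individual-level rarefaction.

Groups of unequal size bias most diversity estimators, so each statistic
is recomputed on 1000 random subsamples of a fixed number of individuals
(14 for microsatellite statistics, 5 for mtDNA in the porpoise design)
and summarised by the mean and the SD across replicates (reported as the
standard error of the rarefied statistic).  Replicates on which a
statistic is undefined (e.g. no segregating site) are dropped and
counted rather than resampled, to avoid biasing toward polymorphic
subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import group_indices, rng_from


@dataclass
class RarefiedStat:
    group: object
    statistic: str
    mean: float
    se: float
    n_resampled: int
    n_reps: int
    n_dropped: int


def rarefy_statistic(
    items,
    groups,
    stat_fn,
    n_individuals: int,
    n_reps: int = 1000,
    seed=None,
    stat_name: str = "stat",
) -> list[RarefiedStat]:
    """Rarefy a named statistic over groups by subsampling individuals.

    ``items`` is any container indexable by an integer array (a
    GenotypeTable/SequenceAlignment via its ``subset``, or an ndarray);
    ``stat_fn(items, indices)`` returns a float (NaN = undefined on that
    replicate).  Groups smaller than ``n_individuals`` are excluded.
    When a group is exactly ``n_individuals`` the mean equals the
    full-sample statistic and the SE is zero.
    """
    rng = rng_from(seed)
    out = []
    for label, idx in group_indices(groups).items():
        if idx.size < n_individuals:
            continue
        if idx.size == n_individuals:
            val = float(stat_fn(items, idx))
            out.append(RarefiedStat(label, stat_name, val, 0.0,
                                    n_individuals, 1, 0))
            continue
        vals = np.empty(n_reps)
        for r in range(n_reps):
            sub = rng.choice(idx, size=n_individuals, replace=False)
            vals[r] = stat_fn(items, sub)
        ok = vals[np.isfinite(vals)]
        out.append(
            RarefiedStat(
                label,
                stat_name,
                float(ok.mean()) if ok.size else np.nan,
                float(ok.std(ddof=1)) if ok.size > 1 else np.nan,
                n_individuals,
                n_reps,
                int(n_reps - ok.size),
            )
        )
    return out


def rarefied_frame(records: list[RarefiedStat]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def compare_groups(
    per_locus_values: dict, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests between groups.

    ``per_locus_values`` maps group -> vector of paired values (one per
    locus).  The exact signed-rank null is used for <= 15 pairs, the
    normal approximation beyond.  Bonferroni correction across the
    pairwise tests.
    """
    names = list(per_locus_values)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x = np.asarray(per_locus_values[names[i]], dtype=float)
            y = np.asarray(per_locus_values[names[j]], dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if x.size < 5:
                warnings.warn(
                    f"{names[i]} vs {names[j]}: fewer than 5 pairs, low power"
                )
            if x.size == 0 or np.allclose(x, y):
                p = 1.0
            else:
                method = "exact" if x.size <= 15 else "approx"
                p = float(
                    sps.wilcoxon(x, y, zero_method="wilcox", method=method).pvalue
                )
            rows.append((names[i], names[j], x.size, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "n_pairs", "p"])
    n_tests = len(df)
    if correction == "bonferroni" and n_tests:
        df["p_adjusted"] = np.minimum(df["p"] * n_tests, 1.0)
    else:
        df["p_adjusted"] = df["p"]
    return df
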