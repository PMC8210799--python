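"""Small shared helpers: seeded RNG streams and permutation p-values."""

from __future__ import annotations

import numpy as np


def rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def perm_pvalue(
    null: np.ndarray, observed: float, tail: str = "greater",
    ties: str = "conservative",
) -> float:
    """Permutation p-value, never exactly 0.

    ``ties='conservative'``: (# null >= obs + 1)/(B + 1).
    ``ties='mid'``: Lancaster mid-p, giving tied permutations half
    weight - restores calibration for discrete statistics whose
    permutation distribution carries substantial tie mass (e.g. |F_IS|
    under genotype reshuffling at small n).
    """
    null = np.asarray(null, dtype=float)
    if tail == "greater":
        strict = int(np.sum(null > observed + 1e-12))
    elif tail == "less":
        strict = int(np.sum(null < observed - 1e-12))
    else:
        raise ValueError(tail)
    eq = int(np.sum(np.isclose(null, observed, atol=1e-12)))
    if ties == "conservative":
        return (strict + eq + 1) / (null.size + 1)
    if ties == "mid":
        return (strict + 0.5 * (eq + 1)) / (null.size + 1)
    raise ValueError(ties)


def group_indices(labels) -> dict:
    """Label -> index array, preserving first-appearance order."""
    labels = np.asarray(labels)
    out = {}
    for lab in labels:
        if lab not in out:
            out[lab] = None
    for lab in out:
        out[lab] = np.flatnonzero(labels == lab)
    return out
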