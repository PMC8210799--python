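"""Core in-memory containers shared by every analysis stage.

The pipeline works with four kinds of data: diploid microsatellite
genotypes, aligned mtDNA sequences, per-sample geographic metadata, and
regular lat/lon rasters (bathymetry, environmental layers).  Distance
matrices (genetic or marine-geographic) are the common currency between
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing locus call (both alleles of the call).
MISSING = -1


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele-size matrix.

    ``alleles`` has shape (n_individuals, n_loci, 2) with non-negative
    integer allele sizes; a missing locus call is ``MISSING`` in both
    slots (single-allele missingness is promoted to whole-call missing,
    since every downstream estimator needs complete calls).  The order
    of the two alleles within a call carries no meaning.
    """

    individual_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        n, l = len(self.individual_ids), len(self.locus_names)
        if self.alleles.shape != (n, l, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {l}, 2)"
            )
        # promote half-missing calls to fully missing
        half = (self.alleles < 0).any(axis=2)
        self.alleles[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask, True where the call is missing."""
        return (self.alleles < 0).all(axis=2)

    def typed_loci_per_individual(self) -> np.ndarray:
        return (~self.missing_mask()).sum(axis=1)

    def subset(self, indices) -> "GenotypeTable":
        indices = np.asarray(indices)
        return GenotypeTable(
            [self.individual_ids[i] for i in indices],
            list(self.locus_names),
            self.alleles[indices].copy(),
        )

    def subset_loci(self, locus_indices) -> "GenotypeTable":
        locus_indices = np.asarray(locus_indices)
        return GenotypeTable(
            list(self.individual_ids),
            [self.locus_names[i] for i in locus_indices],
            self.alleles[:, locus_indices].copy(),
        )


@dataclass
class SequenceAlignment:
    """Equal-length DNA sequences over {A, C, G, T, N, -}."""

    sequence_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("duplicate sequence ids")
        self.sequences = [s.upper().replace("U", "T") for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            bad = [
                sid
                for sid, s in zip(self.sequence_ids, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise ValueError(f"unequal sequence lengths for ids: {bad}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_matrix(self) -> np.ndarray:
        """(n, L) byte matrix; ambiguous/gap states kept verbatim."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n_sequences, self.length)

    def subset(self, indices) -> "SequenceAlignment":
        return SequenceAlignment(
            [self.sequence_ids[i] for i in indices],
            [self.sequences[i] for i in indices],
        )


@dataclass
class SampleMetadata:
    """id / lat / lon / region / subgroup (+ optional sex) table.

    ``region`` (coarse, 10-level in the porpoise study) must be a strict
    coarsening of ``subgroup`` (30-level): each subgroup maps to exactly
    one region.
    """

    table: pd.DataFrame

    REQUIRED = ("id", "lat", "lon", "region", "subgroup")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        t = self.table
        if ((t["lat"] < -90) | (t["lat"] > 90)).any():
            bad = t.loc[(t["lat"] < -90) | (t["lat"] > 90), "id"].tolist()
            raise ValueError(f"latitude out of [-90, 90] for: {bad}")
        if ((t["lon"] < -180) | (t["lon"] > 180)).any():
            raise ValueError("longitude out of [-180, 180]")
        # normalise lon to [-180, 180)
        self.table = t.assign(lon=((t["lon"] + 180.0) % 360.0) - 180.0)
        mapping = self.table.groupby("subgroup")["region"].nunique()
        if (mapping > 1).any():
            bad = mapping[mapping > 1].index.tolist()
            raise ValueError(f"subgroup mapped to multiple regions: {bad}")

    def coords_for(self, ids) -> np.ndarray:
        t = self.table.set_index("id")
        return t.loc[list(ids), ["lat", "lon"]].to_numpy(float)

    def group_labels(self, ids, level: str = "region") -> np.ndarray:
        t = self.table.set_index("id")
        return t.loc[list(ids), level].to_numpy()

    def group_coords(self, level: str = "region") -> pd.DataFrame:
        """Mean sample coordinate per group (label-indexed lat/lon frame)."""
        return self.table.groupby(level)[["lat", "lon"]].mean()


@dataclass
class RasterGrid:
    """Regular lat/lon grid; row 0 is the northernmost row (ESRI ASCII order).

    Bathymetry convention: metres, negative below sea level.
    """

    values: np.ndarray
    cell_size: float
    xllcorner: float
    yllcorner: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        return self.values == self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lats, lons) of cell centres; lats descend with row index."""
        lats = (
            self.yllcorner
            + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell_size
        )
        lons = self.xllcorner + (np.arange(self.n_cols) + 0.5) * self.cell_size
        return lats, lons

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
        )


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix over labelled groups or individuals.

    ``bounded=False`` flags differentiation matrices whose entries may be
    slightly negative (unbiased FST estimates).
    """

    labels: list[str]
    values: np.ndarray
    bounded: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        finite = np.isfinite(self.values)
        sym = self.values.copy()
        sym[~finite] = 0.0
        if not np.allclose(sym, sym.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if self.bounded and np.nanmin(self.values) < -1e-12:
            raise ValueError("negative entries in a bounded distance matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def align_to(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.bounded
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)
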