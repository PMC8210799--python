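"""Readers/writers for the external formats and the QC filters.

Formats: Genepop-dialect genotype files (2- or 3-digit allele encoding),
a long-form CSV genotype dialect (canonical for fixtures), FASTA
alignments, CSV sample metadata, and ESRI ASCII grids.  The quality
filter mirrors the study design: individuals typed at fewer than
``min_loci`` microsatellite loci are dropped.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    MISSING,
    DistanceMatrix,
    GenotypeTable,
    RasterGrid,
    SampleMetadata,
    SequenceAlignment,
)

log = logging.getLogger("seascape")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def filter_min_loci(g: GenotypeTable, min_loci: int) -> GenotypeTable:
    """Drop individuals with fewer than ``min_loci`` non-missing calls.

    Idempotent; the number of dropped individuals is logged.
    """
    keep = np.flatnonzero(g.typed_loci_per_individual() >= min_loci)
    dropped = g.n_individuals - keep.size
    if dropped:
        log.info("QC: dropped %d individuals with < %d typed loci", dropped, min_loci)
    return g.subset(keep)


def read_genotypes_genepop(
    path, missing_code: str = "000000", min_loci: int = 0,
    digits: int | None = None,
) -> tuple[GenotypeTable, np.ndarray]:
    """Parse a Genepop-dialect file.

    Returns the QC-filtered table and the 'Pop' block label per kept
    individual (pop labels are the first individual's name in each block,
    the common Genepop convention).  ``digits`` resolves the 2- vs
    3-digit allele encoding; inferred from call width when omitted.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    # header line 1 = title; then locus names until first 'pop'
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names may be comma-separated on one line
        loci.extend(
            tok.strip() for tok in lines[i].split(",") if tok.strip()
        )
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no 'Pop' line found")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    current_pop = None
    for ln, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            current_pop = None
            continue
        if "," not in line:
            raise ParseError(f"{path}:{ln}: expected 'name , genotypes'")
        name, geno = line.split(",", 1)
        name = name.strip()
        calls = geno.split()
        if len(calls) != len(loci):
            raise ParseError(
                f"{path}:{ln}: {len(calls)} calls for {len(loci)} loci"
            )
        if current_pop is None:
            current_pop = name
        row = []
        for tok in calls:
            d = digits
            if d is None:
                if len(tok) not in (4, 6):
                    raise ParseError(f"{path}:{ln}: bad allele token '{tok}'")
                d = len(tok) // 2
            if len(tok) != 2 * d or not tok.isdigit():
                raise ParseError(f"{path}:{ln}: bad allele token '{tok}'")
            if tok == missing_code or tok == "0" * 2 * d:
                row.append((MISSING, MISSING))
            else:
                a, b = int(tok[:d]), int(tok[d:])
                if a == 0 or b == 0:  # half-missing -> whole call missing
                    row.append((MISSING, MISSING))
                else:
                    row.append((a, b))
        ids.append(name)
        pops.append(current_pop)
        rows.append(row)

    if not rows:
        warnings.warn(f"{path}: no individuals in any Pop block")
        table = GenotypeTable([], loci, np.empty((0, len(loci), 2), int))
        return table, np.array([], dtype=object)
    alleles = np.array(rows, dtype=np.int32)
    table = GenotypeTable(ids, loci, alleles)
    keep = np.flatnonzero(table.typed_loci_per_individual() >= min_loci)
    dropped = table.n_individuals - keep.size
    if dropped:
        log.info("QC: dropped %d individuals with < %d typed loci", dropped, min_loci)
    return table.subset(keep), np.asarray(pops, dtype=object)[keep]


def write_genotypes_genepop(
    g: GenotypeTable, path, pops=None, title: str = "seascape export",
    digits: int = 3,
) -> None:
    """Write a Genepop file; individuals grouped by ``pops`` labels."""
    if pops is None:
        pops = np.array(["POP1"] * g.n_individuals, dtype=object)
    pops = np.asarray(pops, dtype=object)
    out = [title]
    out.extend(g.locus_names)
    fmt = f"%0{digits}d"
    for pop in pd.unique(pops):
        out.append("Pop")
        for i in np.flatnonzero(pops == pop):
            calls = []
            for a, b in g.alleles[i]:
                if a < 0:
                    calls.append("0" * 2 * digits)
                else:
                    calls.append(fmt % a + fmt % b)
            out.append(f"{g.individual_ids[i]} , " + " ".join(calls))
    Path(path).write_text("\n".join(out) + "\n")


def read_genotypes_csv(path, min_loci: int = 0) -> GenotypeTable:
    """Long-form CSV dialect: columns id, locus, allele1, allele2.

    Missing calls are empty/NA cells or non-positive alleles.
    """
    df = pd.read_csv(path)
    need = {"id", "locus", "allele1", "allele2"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(need)}")
    ids = list(pd.unique(df["id"]))
    loci = list(pd.unique(df["locus"]))
    alleles = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int32)
    id_ix = {v: i for i, v in enumerate(ids)}
    loc_ix = {v: i for i, v in enumerate(loci)}
    a1 = df["allele1"].fillna(MISSING).to_numpy(float).astype(np.int32)
    a2 = df["allele2"].fillna(MISSING).to_numpy(float).astype(np.int32)
    for row, v1, v2 in zip(df.itertuples(index=False), a1, a2):
        i, j = id_ix[row.id], loc_ix[row.locus]
        alleles[i, j] = (v1, v2) if (v1 > 0 and v2 > 0) else (MISSING, MISSING)
    table = GenotypeTable([str(x) for x in ids], [str(x) for x in loci], alleles)
    return filter_min_loci(table, min_loci)


def write_genotypes_csv(g: GenotypeTable, path) -> None:
    recs = []
    for i, ind in enumerate(g.individual_ids):
        for j, locus in enumerate(g.locus_names):
            a, b = g.alleles[i, j]
            recs.append(
                (ind, locus, a if a >= 0 else np.nan, b if b >= 0 else np.nan)
            )
    pd.DataFrame(recs, columns=["id", "locus", "allele1", "allele2"]).to_csv(
        path, index=False
    )


def read_genotypes(path, missing_code: str = "000000", min_loci: int = 6):
    """Dispatch on extension: .csv -> long-form CSV, else Genepop."""
    if str(path).endswith(".csv"):
        return read_genotypes_csv(path, min_loci=min_loci)
    table, _ = read_genotypes_genepop(path, missing_code, min_loci)
    return table


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignment(path) -> SequenceAlignment:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ParseError(f"{path}: no FASTA records")
    return SequenceAlignment(ids, seqs)


def write_alignment(a: SequenceAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(a.sequence_ids, a.sequences)
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path)
    df["id"] = df["id"].astype(str)
    return SampleMetadata(df)


def write_metadata(m: SampleMetadata, path) -> None:
    m.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII rasters
# ---------------------------------------------------------------------------

def read_raster(path) -> RasterGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(f"{path}: missing header key '{key}'")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(
            f"{path}: grid shape {values.shape} does not match header"
        )
    return RasterGrid(
        values,
        cell_size=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_raster(r: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {r.n_cols}\n")
        fh.write(f"nrows {r.n_rows}\n")
        fh.write(f"xllcorner {float(r.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(r.yllcorner)!r}\n")
        fh.write(f"cellsize {float(r.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(r.nodata)!r}\n")
        for row in r.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def read_distance_csv(path, bounded: bool = True) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(
        [str(c) for c in df.columns], df.to_numpy(float), bounded
    )


def write_distance_csv(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path)
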