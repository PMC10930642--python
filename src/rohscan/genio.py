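"""Readers and writers for PLINK genotype files and phenotype tables.

Supports PLINK text (.ped/.map) and binary SNP-major (.bed/.bim/.fam)
dialects.  The text reader recodes genotypes as dosage of the minor allele
(frequency ties broken lexicographically, so coding is deterministic); the
binary reader counts the .bim A1 allele, which is what the writer emits, so
text -> binary -> text round trips are exact.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MILK_TRAITS,
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    PhenotypeTable,
    chrom_sort_key,
    normalize_chrom,
)

log = logging.getLogger(__name__)

_BED_MAGIC = b"\x6c\x1b\x01"

# 2-bit PLINK codes (SNP-major), A1 = allele_b: 00 hom A1, 01 missing,
# 10 het, 11 hom A2 -> dosage of allele_b 2 / MISSING / 1 / 0.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised on malformed PLINK input."""


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise PlinkFormatError(
                    f"{map_path}: line {lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, marker_id, _cm, pos = fields
            rows.append((normalize_chrom(chrom), marker_id, int(pos)))
    df = pd.DataFrame(rows, columns=["chrom", "marker_id", "pos_bp"])
    dup = df["marker_id"].duplicated()
    if dup.any():
        raise PlinkFormatError(
            f"{map_path}: duplicate marker_id {df['marker_id'][dup].iloc[0]!r}"
        )
    return df


def read_plink_text(ped_path, map_path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PLINK .ped/.map pair into a minor-allele dosage matrix.

    Dosage counts the minor allele per marker (allele-frequency ties broken by
    lexicographic allele order); ``0 0`` genotypes become missing. Monomorphic
    markers keep the observed allele as allele_a and record allele_b as ``"0"``.
    Markers observed with >2 alleles are coded on their two most frequent
    alleles (other calls set missing) and flagged via ``n_alleles`` so QC can
    drop them.
    """
    mapdf = _read_map(map_path)
    m = len(mapdf)
    samples: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(fields)}"
                )
            samples.append(fields[1])
            geno = fields[6:]
            allele_rows.append([(geno[2 * j], geno[2 * j + 1]) for j in range(m)])
    if not samples:
        raise PlinkFormatError(f"{ped_path}: no samples")

    n = len(samples)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    n_alleles = np.zeros(m, dtype=np.int64)
    for j in range(m):
        counts: Counter = Counter()
        for i in range(n):
            for a in allele_rows[i][j]:
                if a != "0":
                    counts[a] += 1
        n_alleles[j] = len(counts)
        if not counts:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        if len(counts) == 1:
            (only,) = counts
            allele_a[j], allele_b[j] = only, "0"
            continue
        # two most frequent alleles; minor = lower count, ties lexicographic
        top2 = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
        (a_major, _), (a_minor, _) = top2
        if counts[a_major] == counts[a_minor]:
            a_major, a_minor = sorted((a_major, a_minor))
        allele_a[j], allele_b[j] = a_major, a_minor
        for i in range(n):
            x, y = allele_rows[i][j]
            if x == "0" or y == "0":
                continue
            if {x, y} <= {a_major, a_minor}:
                dosage[i, j] = (x == a_minor) + (y == a_minor)
    # monomorphic / all-missing markers: observed homozygotes -> dosage 0
    for j in np.where(n_alleles <= 1)[0]:
        for i in range(n):
            x, y = allele_rows[i][j]
            if x != "0" and y != "0":
                dosage[i, j] = 0

    order = np.asarray(
        sorted(
            range(m),
            key=lambda j: (chrom_sort_key(mapdf["chrom"][j]), mapdf["pos_bp"][j]),
        ),
        dtype=np.int64,
    )
    mmap = MarkerMap(
        mapdf["marker_id"].to_numpy()[order],
        mapdf["chrom"].to_numpy()[order],
        mapdf["pos_bp"].to_numpy()[order],
        allele_a[order],
        allele_b[order],
    )
    g = GenotypeMatrix(samples, dosage[:, order], n_alleles[order])
    return g, mmap


def read_plink_bed(bed, bim, fam) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read SNP-major PLINK binary files; dosage counts the .bim A1 allele."""
    bimdf = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos_bp", "a1", "a2"],
        dtype=str,
    )
    famdf = pd.read_csv(
        fam,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(famdf), len(bimdf)
    raw = Path(bed).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: not SNP-major PLINK bed")
    bytes_per_marker = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_marker * m:
        raise PlinkFormatError(f"{bed}: truncated or oversized payload")
    blocks = body.reshape(m, bytes_per_marker)
    # unpack 2-bit codes, sample i in bits 2*(i % 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_marker * 4)[:, :n]
    dosage = _CODE_TO_DOSAGE[codes].T  # samples x markers
    mmap = MarkerMap(
        bimdf["marker_id"].to_numpy(),
        bimdf["chrom"].to_numpy(),
        bimdf["pos_bp"].astype(np.int64).to_numpy(),
        bimdf["a2"].to_numpy(),
        bimdf["a1"].to_numpy(),
    )
    g = GenotypeMatrix(list(famdf["iid"]), dosage)
    return g, mmap


def write_plink_bed(g: GenotypeMatrix, m: MarkerMap, out_prefix) -> dict:
    """Write SNP-major .bed/.bim/.fam; A1 = allele_b, sex coded 2 (female)."""
    if g.n_markers != m.n_markers:
        raise ValueError("genotype/marker-map dimension mismatch")
    if m.n_markers == 0:
        raise ValueError("cannot write an empty marker set")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n = g.n_samples
    bytes_per_marker = (n + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for dose, code in _DOSAGE_TO_CODE.items():
        code_lut[dose % 4] = code  # MISSING=-1 -> index 3
    codes = code_lut[g.dosage.T % 4].astype(np.uint8)  # m x n
    padded = np.zeros((m.n_markers, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n] = codes
    padded[:, n:] = _DOSAGE_TO_CODE[0]  # pad bits with hom-A2 (ignored on read)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (
        (padded.reshape(m.n_markers, bytes_per_marker, 4) << shifts[None, None, :])
        .sum(axis=2)
        .astype(np.uint8)
    )
    bed_path = prefix.with_suffix(".bed")
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim_path = prefix.with_suffix(".bim")
    with open(bim_path, "w") as fh:
        for j in range(m.n_markers):
            fh.write(
                f"{m.chrom[j]}\t{m.marker_id[j]}\t0\t{m.pos_bp[j]}"
                f"\t{m.allele_b[j]}\t{m.allele_a[j]}\n"
            )
    fam_path = prefix.with_suffix(".fam")
    with open(fam_path, "w") as fh:
        for s in g.samples:
            fh.write(f"{s}\t{s}\t0\t0\t2\t-9\n")
    return {"bed": bed_path, "bim": bim_path, "fam": fam_path}


def write_plink_text(g: GenotypeMatrix, m: MarkerMap, out_prefix) -> dict:
    """Write a .ped/.map pair mirroring the matrix (missing -> ``0 0``)."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for j in range(m.n_markers):
            fh.write(f"{m.chrom[j]}\t{m.marker_id[j]}\t0\t{m.pos_bp[j]}\n")
    ped_path = prefix.with_suffix(".ped")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples):
            parts = [str(s), str(s), "0", "0", "2", "-9"]
            for j in range(m.n_markers):
                d = g.dosage[i, j]
                a, b = m.allele_a[j], m.allele_b[j]
                if d == MISSING:
                    parts += ["0", "0"]
                elif d == 0:
                    parts += [a, a]
                elif d == 1:
                    parts += [a, b]
                else:
                    parts += [b, b]
            fh.write(" ".join(parts) + "\n")
    return {"ped": ped_path, "map": map_path}


def read_phenotypes(
    path, trait_names=MILK_TRAITS, genotype_samples=None
) -> PhenotypeTable:
    """Read a tab-delimited phenotype table (header: sample_id + traits).

    ``NA``/empty cells become missing.  Trait columns outside ``trait_names``
    are kept with a warning.  If ``genotype_samples`` is given, phenotype
    samples absent from it are flagged (kept), and zero overlap is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", "na", ""])
    if df.columns[0] != "sample_id":
        df = df.rename(columns={df.columns[0]: "sample_id"})
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    df = df.set_index("sample_id")
    for col in df.columns:
        if col not in trait_names:
            log.warning("phenotype column %r not in the declared trait dictionary", col)
        df[col] = pd.to_numeric(df[col], errors="coerce")
    unknown: list[str] = []
    if genotype_samples is not None:
        gset = set(genotype_samples)
        unknown = [s for s in df.index if s not in gset]
        if len(unknown) == len(df):
            raise ValueError(f"{path}: no phenotype samples overlap the genotypes")
    return PhenotypeTable(df, unknown_samples=unknown)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
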