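"""Core in-memory containers for SNP-array pipelines.

The central object is a samples x markers dosage matrix (:class:`GenotypeMatrix`)
paired with a :class:`MarkerMap` describing marker coordinates and alleles.
Dosage counts copies of ``allele_b`` (the minor allele when data come from the
text reader); missing calls are coded :data:`MISSING`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

#: Chromosome label used for the X chromosome after normalization.
CHROM_X = "X"

#: Bovine autosome labels BTA1..BTA29.
AUTOSOMES = tuple(str(i) for i in range(1, 30))

#: The twelve milk traits the phenotype table may carry (lactation 1 and 2;
#: yields and concentrations, raw and 305-day adjusted).
MILK_TRAITS = (
    "milk_yield_lact1",
    "milk_yield_lact2",
    "protein_conc_lact1",
    "protein_conc_lact2",
    "fat_conc_lact1",
    "fat_conc_lact2",
    "milk_yield_305d_lact1",
    "milk_yield_305d_lact2",
    "protein_conc_305d_lact1",
    "protein_conc_305d_lact2",
    "fat_conc_305d_lact1",
    "fat_conc_305d_lact2",
)


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip a ``chr`` prefix, map ``30`` to ``X``."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in ("30", "x", "X"):
        return CHROM_X
    return c


def chrom_sort_key(chrom: str):
    """Sort key placing numeric autosomes first (numerically), then X etc."""
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass
class MarkerMap:
    """Per-marker chromosome, 1-based position and allele labels.

    Markers must be sorted by (chromosome, position) with strictly increasing
    positions within each chromosome, and marker identifiers must be unique.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self):
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray([normalize_chrom(c) for c in self.chrom], dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.marker_id)
        for name in ("chrom", "pos_bp", "allele_a", "allele_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} length mismatch")
        if len(set(self.marker_id)) != n:
            raise ValueError("duplicate marker_id in MarkerMap")
        if np.any(self.pos_bp < 1):
            raise ValueError("marker positions must be >= 1 (1-based)")
        for c in self.chroms():
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chroms(self) -> list[str]:
        """Chromosome labels in genome order."""
        return sorted(set(self.chrom), key=chrom_sort_key)

    def autosome_mask(self) -> np.ndarray:
        return np.asarray([c != CHROM_X for c in self.chrom], dtype=bool)

    def take(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            self.marker_id[idx],
            self.chrom[idx],
            self.pos_bp[idx],
            self.allele_a[idx],
            self.allele_b[idx],
        )

    def sort_order(self) -> np.ndarray:
        """Index array sorting markers by (chromosome, position)."""
        order = sorted(
            range(self.n_markers),
            key=lambda i: (chrom_sort_key(self.chrom[i]), self.pos_bp[i]),
        )
        return np.asarray(order, dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix counting copies of ``allele_b``.

    Entries are 0/1/2 or :data:`MISSING`.  ``n_alleles`` optionally records the
    number of distinct alleles observed per marker at read time (markers seen
    with more than two alleles are flagged here so QC can remove them; their
    dosage columns are coded on the two most frequent alleles).
    """

    samples: list
    dosage: np.ndarray
    n_alleles: np.ndarray | None = None

    def __post_init__(self):
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x markers)")
        if self.dosage.shape[0] != len(self.samples):
            raise ValueError("dosage row count != number of samples")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")
        if self.n_alleles is not None:
            self.n_alleles = np.asarray(self.n_alleles, dtype=np.int64)
            if len(self.n_alleles) != self.dosage.shape[1]:
                raise ValueError("n_alleles length != marker count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask().mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_b_freq(self) -> np.ndarray:
        """Frequency of allele_b among observed calls (NaN if all missing)."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, missing calls excluded."""
        p = self.allele_b_freq()
        return np.minimum(p, 1.0 - p)

    def mean_imputed(self) -> np.ndarray:
        """Float dosage matrix with missing calls replaced by the marker mean."""
        d = self.dosage.astype(np.float64)
        miss = self.dosage == MISSING
        d[miss] = np.nan
        col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        idx = np.where(miss)
        d[idx] = col_mean[idx[1]]
        return d

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.dosage[idx, :], self.n_alleles
        )

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        na = self.n_alleles[idx] if self.n_alleles is not None else None
        return GenotypeMatrix(self.samples, self.dosage[:, idx], na)


@dataclass
class PhenotypeTable:
    """Per-sample trait values (NaN = missing), indexed by unique sample id."""

    data: pd.DataFrame
    unknown_samples: list = field(default_factory=list)

    def __post_init__(self):
        if not self.data.index.is_unique:
            raise ValueError("duplicate sample_id in phenotype table")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def trait_names(self) -> list:
        return list(self.data.columns)

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"trait {name!r} not in phenotype table")
        return self.data[name]

    def aligned_to(self, samples: list) -> pd.DataFrame:
        """Trait table reindexed to the genotype sample order (NaN where absent)."""
        return self.data.reindex(samples)
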