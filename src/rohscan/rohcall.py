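"""Runs-of-homozygosity (ROH) detection and length-class summaries.

A ROH is called when at least ``min_snp`` consecutive homozygous markers span
at least ``min_length_bp``.  Heterozygous calls always break a run; up to
``max_missing`` unread markers are tolerated inside one run.  Segments are
trimmed so they begin and end on homozygous markers, and their length is
``pos(last) - pos(first) + 1`` (1-based inclusive coordinates).

Within a heterozygote-free stretch the caller enumerates the maximal windows
compatible with the missing-call budget with a two-pointer sweep, keeps those
satisfying the SNP-count and length rules, and selects them disjointly from
the left, so reported segments of one sample never overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CHROM_X, MISSING, GenotypeMatrix, MarkerMap, chrom_sort_key

log = logging.getLogger(__name__)

#: Length-class labels (Mbp): [1,2), [2,4), [4,8), [8,16), [16, inf).
CLASS_LABELS = ("1-2", "2-4", "4-8", "8-16", ">16")
_CLASS_EDGES_BP = (1_000_000, 2_000_000, 4_000_000, 8_000_000, 16_000_000)


@dataclass(frozen=True)
class ROHParams:
    """Calling rule: SNP count, physical span, heterozygote and missing budgets."""

    min_snp: int = 25
    min_length_bp: int = 1_000_000
    max_het: int = 0
    max_missing: int = 5

    def __post_init__(self):
        if min(self.min_snp, self.max_het, self.max_missing) < 0:
            raise ValueError("ROHParams counts must be >= 0")
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one sample (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_hom: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_class(self) -> str:
        return classify_length(self.length_bp)


def classify_length(length_bp: int) -> str:
    """Map a segment length to its class: 1-2, 2-4, 4-8, 8-16 or >16 Mbp.

    Bins are half-open on the left edge, so 2,000,000 bp falls in "2-4".
    """
    if length_bp < _CLASS_EDGES_BP[0]:
        raise ValueError(f"length {length_bp} bp below the 1 Mbp class floor")
    for label, lo, hi in zip(
        CLASS_LABELS[:-1], _CLASS_EDGES_BP[:-1], _CLASS_EDGES_BP[1:]
    ):
        if lo <= length_bp < hi:
            return label
    return CLASS_LABELS[-1]


def call_roh_sample(
    dosage: np.ndarray,
    positions: np.ndarray,
    params: ROHParams = ROHParams(),
    sample_id: str = "",
    chrom: str = "",
) -> list[ROHSegment]:
    """Call ROH segments for one sample on one chromosome.

    ``dosage`` holds per-marker codes (0/2 homozygous, 1 heterozygous,
    MISSING unread); ``positions`` are the matching base-pair coordinates,
    strictly increasing.
    """
    dosage = np.asarray(dosage)
    positions = np.asarray(positions, dtype=np.int64)
    if len(dosage) != len(positions):
        raise ValueError("dosage/position length mismatch")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")

    het = dosage == 1
    segments: list[ROHSegment] = []
    # split into heterozygote-free stretches
    breakpoints = np.flatnonzero(het)
    starts = np.concatenate(([0], breakpoints + 1))
    ends = np.concatenate((breakpoints, [len(dosage)]))  # exclusive of het
    for a, b in zip(starts, ends):
        if b - a <= 0:
            continue
        segments.extend(
            _call_stretch(dosage[a:b], positions[a:b], params, sample_id, chrom)
        )
    return segments


def _call_stretch(dosage, positions, params, sample_id, chrom) -> list[ROHSegment]:
    """Maximal-window sweep over one heterozygote-free stretch."""
    hom_idx = np.flatnonzero(dosage != MISSING)
    if len(hom_idx) == 0:
        return []
    miss_cum = np.concatenate(([0], np.cumsum(dosage == MISSING)))

    def miss_between(i, j):  # missing calls inside [hom_idx[i], hom_idx[j]]
        return int(miss_cum[hom_idx[j] + 1] - miss_cum[hom_idx[i]])

    out: list[ROHSegment] = []
    n_hom_total = len(hom_idx)
    j = 0
    prev_j = -1
    last_end_hom = -1  # index into hom_idx of last accepted segment end
    for i in range(n_hom_total):
        if j < i:
            j = i
        while j + 1 < n_hom_total and miss_between(i, j + 1) <= params.max_missing:
            j += 1
        if j == prev_j:  # window not maximal (contained in the previous one)
            continue
        prev_j = j
        n_hom = j - i + 1
        span = int(positions[hom_idx[j]] - positions[hom_idx[i]]) + 1
        if n_hom < params.min_snp or span < params.min_length_bp:
            continue
        if i <= last_end_hom:  # overlaps an accepted segment
            continue
        out.append(
            ROHSegment(
                sample_id=sample_id,
                chrom=chrom,
                start_bp=int(positions[hom_idx[i]]),
                end_bp=int(positions[hom_idx[j]]),
                n_hom=n_hom,
                n_missing=miss_between(i, j),
            )
        )
        last_end_hom = j
    return out


def call_roh_all(
    g: GenotypeMatrix, m: MarkerMap, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Call ROH for every sample on every autosome, in (sample, chrom, start) order.

    The input must be a ROH-profile dataset: the X chromosome is rejected.
    """
    if CHROM_X in set(m.chrom):
        raise ValueError("ROH calling expects autosomes only (X present)")
    segments: list[ROHSegment] = []
    chrom_order = m.chroms()
    chrom_idx = {c: np.flatnonzero(m.chrom == c) for c in chrom_order}
    for i, sample in enumerate(g.samples):
        for c in chrom_order:
            idx = chrom_idx[c]
            segments.extend(
                call_roh_sample(
                    g.dosage[i, idx], m.pos_bp[idx], params, str(sample), c
                )
            )
    sample_rank = {str(s): i for i, s in enumerate(g.samples)}
    segments.sort(
        key=lambda s: (sample_rank.get(s.sample_id, 0), chrom_sort_key(s.chrom), s.start_bp)
    )
    return segments


def segments_to_dataframe(segments: list[ROHSegment]) -> pd.DataFrame:
    cols = ["sample_id", "chrom", "start_bp", "end_bp", "n_hom", "n_missing",
            "length_bp", "length_class"]
    if not segments:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [
            (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_hom, s.n_missing,
             s.length_bp, s.length_class)
            for s in segments
        ],
        columns=cols,
    )


def segments_from_dataframe(df: pd.DataFrame) -> list[ROHSegment]:
    return [
        ROHSegment(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_hom=int(r.n_hom),
            n_missing=int(r.n_missing),
        )
        for r in df.itertuples()
    ]


def segments_to_bed(segments: list[ROHSegment], path) -> None:
    """Export segments as BED (0-based half-open) for external annotation."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\n")


def mean_roh_length_mbp(total_length_mbp: float, n_segments: float) -> float:
    """Grand mean segment length: total ROH length over segment count (Mbp)."""
    if n_segments <= 0:
        raise ValueError("segment count must be positive")
    return total_length_mbp / n_segments


@dataclass
class ROHSummary:
    """Cohort summary: per-animal class totals and population statistics.

    ``class_stats`` follows the convention that per-class mean/SD/median/
    min/max are computed over animals that have at least one ROH of that
    class; ``pct_animals_without_class`` reports how common absence is.
    """

    per_animal: pd.DataFrame
    class_stats: pd.DataFrame
    pct_animals_without_class: pd.Series
    n_segments: int
    n_animals: int
    mean_segments_per_animal: float
    grand_mean_length_mbp: float


def summarize_roh(segments: list[ROHSegment], samples: list) -> ROHSummary:
    """Summarize called segments per animal and per length class."""
    samples = [str(s) for s in samples]
    if not segments:
        warnings.warn("no ROH segments: summary is all zeros", stacklevel=2)
    df = segments_to_dataframe(segments)

    per_animal = pd.DataFrame(0.0, index=samples,
                              columns=[f"n_{c}" for c in CLASS_LABELS]
                              + [f"mbp_{c}" for c in CLASS_LABELS])
    if len(df):
        counts = df.pivot_table(index="sample_id", columns="length_class",
                                values="start_bp", aggfunc="count", fill_value=0)
        lengths = df.pivot_table(index="sample_id", columns="length_class",
                                 values="length_bp", aggfunc="sum", fill_value=0)
        for c in CLASS_LABELS:
            if c in counts.columns:
                per_animal.loc[counts.index, f"n_{c}"] = counts[c].astype(float)
                per_animal.loc[lengths.index, f"mbp_{c}"] = lengths[c] / 1e6
    per_animal["n_total"] = per_animal[[f"n_{c}" for c in CLASS_LABELS]].sum(axis=1)
    per_animal["mbp_total"] = per_animal[[f"mbp_{c}" for c in CLASS_LABELS]].sum(axis=1)

    rows = []
    pct_without = {}
    for c in CLASS_LABELS:
        have = per_animal[per_animal[f"n_{c}"] > 0]
        pct_without[c] = int(round(100.0 * (len(samples) - len(have)) / len(samples))) \
            if samples else 0
        for what, col in (("total_length_mbp", f"mbp_{c}"), ("count", f"n_{c}")):
            v = have[col]
            rows.append(
                {
                    "length_class": c,
                    "quantity": what,
                    "n_animals_with_class": len(have),
                    "mean": v.mean() if len(v) else 0.0,
                    "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                    "median": v.median() if len(v) else 0.0,
                    "min": v.min() if len(v) else 0.0,
                    "max": v.max() if len(v) else 0.0,
                }
            )
    class_stats = pd.DataFrame(rows)

    n_seg = len(segments)
    total_mbp = float(per_animal["mbp_total"].sum())
    return ROHSummary(
        per_animal=per_animal,
        class_stats=class_stats,
        pct_animals_without_class=pd.Series(pct_without),
        n_segments=n_seg,
        n_animals=len(samples),
        mean_segments_per_animal=n_seg / len(samples) if samples else 0.0,
        grand_mean_length_mbp=mean_roh_length_mbp(total_mbp, n_seg) if n_seg else 0.0,
    )
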