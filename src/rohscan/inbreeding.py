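"""Genomic inbreeding coefficients from ROH coverage (F_ROH).

F_ROH for one animal is the fraction of the autosomal genome lying inside its
ROH segments.  The default denominator is the published *Bos taurus*
autosome length, 2,512,082,506 bp; simulated genomes pass their own length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rohcall import CLASS_LABELS, ROHSegment

#: Bos taurus autosomal genome length (bp) used as the F_ROH denominator.
BOS_TAURUS_AUTOSOME_BP: int = 2_512_082_506


def _check_non_overlapping(segments: list[ROHSegment]) -> None:
    by_chrom_sample: dict = {}
    for s in segments:
        by_chrom_sample.setdefault((s.sample_id, s.chrom), []).append(s)
    for segs in by_chrom_sample.values():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping ROH segments on chromosome {a.chrom} "
                    f"({a.start_bp}-{a.end_bp} vs {b.start_bp}-{b.end_bp})"
                )


def froh(
    segments: list[ROHSegment], autosome_length_bp: int = BOS_TAURUS_AUTOSOME_BP
) -> float:
    """Total ROH length of one animal divided by the autosome length."""
    if autosome_length_bp <= 0:
        raise ValueError("autosome_length_bp must be positive")
    _check_non_overlapping(segments)
    return sum(s.length_bp for s in segments) / autosome_length_bp


def froh_by_class(
    segments: list[ROHSegment], autosome_length_bp: int = BOS_TAURUS_AUTOSOME_BP
) -> dict:
    """Class-partitioned F_ROH over the same denominator (missing classes -> 0)."""
    if autosome_length_bp <= 0:
        raise ValueError("autosome_length_bp must be positive")
    _check_non_overlapping(segments)
    out = {c: 0.0 for c in CLASS_LABELS}
    for s in segments:
        out[s.length_class] += s.length_bp / autosome_length_bp
    return out


@dataclass
class InbreedingResult:
    sample_id: str
    f_roh_total: float
    f_roh_by_class: dict
    autosome_length_bp: int


def froh_per_animal(
    segments: list[ROHSegment],
    samples: list,
    autosome_length_bp: int = BOS_TAURUS_AUTOSOME_BP,
) -> pd.DataFrame:
    """Per-animal F_ROH table: total plus one column per length class."""
    by_sample: dict = {str(s): [] for s in samples}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    rows = {}
    for sid in (str(s) for s in samples):
        segs = by_sample.get(sid, [])
        by_class = froh_by_class(segs, autosome_length_bp)
        rows[sid] = {"f_roh_total": froh(segs, autosome_length_bp),
                     **{f"f_roh_{c}": v for c, v in by_class.items()}}
    return pd.DataFrame.from_dict(rows, orient="index")


def froh_population_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/median/min/max of F_ROH, overall and per class, across animals.

    SD is the sample standard deviation (n-1); with a single animal it is
    reported as NaN (missing).
    """
    if len(results) == 0:
        raise ValueError("need at least one animal")
    stats = {}
    for col in results.columns:
        v = results[col]
        stats[col] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
            "median": float(v.median()),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    return pd.DataFrame(stats).T
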