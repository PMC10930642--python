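"""ROH islands: population SNP-in-ROH frequency and island calling.

For every marker the fraction of animals whose ROH covers it is computed
("SNP-in-ROH frequency", in percent).  Maximal runs of consecutive markers at
or above the threshold (default 30% of the population) are reported as ROH
islands — candidate selection signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MarkerMap, chrom_sort_key
from .rohcall import ROHSegment


def snp_in_roh_frequency(
    segments: list[ROHSegment], m: MarkerMap, n_samples: int
) -> pd.DataFrame:
    """Per-marker percentage of animals with a ROH covering the marker.

    Each animal contributes at most once per marker even if (erroneously)
    overlapping segments cover it twice.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    counts = np.zeros(m.n_markers, dtype=np.int64)
    chrom_idx = {c: np.flatnonzero(m.chrom == c) for c in m.chroms()}
    by_sample_chrom: dict = {}
    for s in segments:
        by_sample_chrom.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sid, chrom), segs in by_sample_chrom.items():
        idx = chrom_idx.get(chrom)
        if idx is None:
            continue
        pos = m.pos_bp[idx]
        covered = np.zeros(len(idx), dtype=bool)
        for s in segs:
            lo = np.searchsorted(pos, s.start_bp, side="left")
            hi = np.searchsorted(pos, s.end_bp, side="right")
            covered[lo:hi] = True
        counts[idx[covered]] += 1
    return pd.DataFrame(
        {
            "chrom": m.chrom,
            "pos_bp": m.pos_bp,
            "marker_id": m.marker_id,
            "pct_in_roh": 100.0 * counts / n_samples,
        }
    )


@dataclass(frozen=True)
class Island:
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    peak_pct: float
    peak_marker_ids: tuple


def detect_islands(
    track: pd.DataFrame, threshold_pct: float = 30.0, min_markers: int = 1
) -> list[Island]:
    """Maximal runs of consecutive markers with pct_in_roh >= threshold.

    The threshold is inclusive ("at least 30% of the population"); island
    coordinates span the first and last member markers.
    """
    islands: list[Island] = []
    for chrom in sorted(track["chrom"].unique(), key=chrom_sort_key):
        sub = track[track["chrom"] == chrom].sort_values("pos_bp")
        above = (sub["pct_in_roh"].to_numpy() >= threshold_pct).astype(np.int8)
        if not above.any():
            continue
        edges = np.diff(np.concatenate(([0], above, [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)  # exclusive
        pos = sub["pos_bp"].to_numpy()
        pct = sub["pct_in_roh"].to_numpy()
        ids = sub["marker_id"].to_numpy()
        for a, b in zip(starts, ends):
            if b - a < min_markers:
                continue
            peak = pct[a:b].max()
            peak_ids = tuple(ids[a:b][pct[a:b] == peak])
            islands.append(
                Island(
                    chrom=str(chrom),
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b - 1]),
                    n_markers=int(b - a),
                    peak_pct=float(peak),
                    peak_marker_ids=peak_ids,
                )
            )
    return islands


def island_report(islands: list[Island]) -> pd.DataFrame:
    """Tabular island report (one row per island, Manhattan-plot ready)."""
    cols = ["chrom", "start_bp", "end_bp", "length_bp", "n_markers",
            "peak_pct", "peak_marker_ids"]
    if not islands:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [
            (i.chrom, i.start_bp, i.end_bp, i.end_bp - i.start_bp + 1,
             i.n_markers, i.peak_pct, ",".join(map(str, i.peak_marker_ids)))
            for i in islands
        ],
        columns=cols,
    )


def islands_to_bed(islands: list[Island], path) -> None:
    """Export islands as BED (0-based half-open) for external gene annotation."""
    with open(path, "w") as fh:
        for i in islands:
            fh.write(f"{i.chrom}\t{i.start_bp - 1}\t{i.end_bp}\t{i.peak_pct:.1f}\n")
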