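"""SNP-array quality control and construction of analysis-ready marker sets.

Two profiles are produced from the same raw chip data:

* ``gwas`` — sample call-rate filter, marker call-rate / biallelic / MAF
  filters, then greedy windowed LD pruning; autosomes plus X retained.
* ``roh`` — sample call-rate filter and marker call-rate / biallelic filters
  only (no MAF filter, no LD pruning); autosomes only, X dropped.

Sample boundary is "remove if call rate <= threshold"; markers are kept when
call rate >= the marker threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, MarkerMap

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    sample_call_rate_min: float = 0.90   # remove sample if call rate <= this
    marker_call_rate_min: float = 0.95   # keep marker if call rate >= this
    maf_min: float = 0.01
    ld_r2_max: float = 0.5
    ld_window_snps: int = 50
    ld_window_step: int = 5
    profile: str = "gwas"

    def __post_init__(self):
        for name in ("sample_call_rate_min", "marker_call_rate_min",
                     "maf_min", "ld_r2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.profile not in ("gwas", "roh"):
            raise ValueError(f"unknown QC profile {self.profile!r}")


@dataclass
class QCReport:
    profile: str
    samples_in: int
    samples_out: int
    markers_in: int
    markers_out: int
    removals: dict = field(default_factory=dict)
    removed_samples: list = field(default_factory=list)

    def validate(self) -> None:
        if self.markers_in - sum(self.removals.values()) != self.markers_out:
            raise ValueError("QCReport marker arithmetic inconsistent")
        if min(self.removals.values(), default=0) < 0:
            raise ValueError("negative removal count")

    def to_dict(self) -> dict:
        return {
            "profile": self.profile,
            "samples_in": self.samples_in,
            "samples_out": self.samples_out,
            "markers_in": self.markers_in,
            "markers_out": self.markers_out,
            "removals": dict(self.removals),
            "removed_samples": list(self.removed_samples),
        }


def sample_call_rate_filter(
    g: GenotypeMatrix, threshold: float = 0.90
) -> tuple[GenotypeMatrix, list]:
    """Remove samples whose genotyping call rate is <= ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    rates = g.sample_call_rate()
    keep = rates > threshold
    if not keep.any():
        raise ValueError("sample call-rate filter removed every sample")
    removed = [g.samples[i] for i in np.flatnonzero(~keep)]
    return g.take_samples(np.flatnonzero(keep)), removed


def marker_filter(
    g: GenotypeMatrix,
    m: MarkerMap,
    call_rate_min: float = 0.95,
    maf_min: float | None = 0.01,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, MarkerMap, dict]:
    """Keep markers with call rate >= threshold, <=2 alleles, MAF >= minimum.

    Removal reasons are tallied with precedence call_rate -> multiallelic ->
    maf (each marker counted once).  ``maf_min=None`` skips the MAF filter.
    """
    fail_cr = g.marker_call_rate() < call_rate_min
    if biallelic_only and g.n_alleles is not None:
        fail_multi = g.n_alleles > 2
    else:
        fail_multi = np.zeros(g.n_markers, dtype=bool)
    if maf_min is not None:
        maf = g.maf()
        fail_maf = ~(maf >= maf_min)  # NaN (all-missing) also fails
    else:
        fail_maf = np.zeros(g.n_markers, dtype=bool)

    removals = {
        "call_rate": int(fail_cr.sum()),
        "multiallelic": int((fail_multi & ~fail_cr).sum()),
        "maf": int((fail_maf & ~fail_cr & ~fail_multi).sum()),
    }
    keep = ~(fail_cr | fail_multi | fail_maf)
    if not keep.any():
        raise ValueError("marker filters removed every marker")
    idx = np.flatnonzero(keep)
    return g.take_markers(idx), m.take(idx), removals


def _window_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise genotype correlation r^2 of mean-imputed dosage columns."""
    x = d - d.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # constant columns correlate with nothing
    x = x / sd
    r = (x.T @ x) / x.shape[0]
    return r**2


def ld_prune(
    g: GenotypeMatrix,
    m: MarkerMap,
    r2_max: float = 0.5,
    window_snps: int = 50,
    step: int = 5,
) -> tuple[list, list]:
    """Greedy windowed LD pruning (indep-pairwise style), per chromosome.

    Within each window of ``window_snps`` markers, while any pair of kept
    markers has r^2 > ``r2_max``, the pair member with the lower MAF is
    dropped (tie: the later position); the window then slides by ``step``.
    Returns (kept marker ids, removed marker ids).
    """
    maf = g.maf()
    dose = g.mean_imputed()
    removed_mask = np.zeros(g.n_markers, dtype=bool)
    for chrom in m.chroms():
        cidx = np.flatnonzero(m.chrom == chrom)
        for start in range(0, len(cidx), step):
            win = cidx[start : start + window_snps]
            win = win[~removed_mask[win]]
            if len(win) < 2:
                if start + window_snps >= len(cidx):
                    break
                continue
            r2 = _window_r2(dose[:, win])
            np.fill_diagonal(r2, 0.0)
            while True:
                jj, kk = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[jj, kk] <= r2_max:
                    break
                a, b = win[jj], win[kk]
                # drop lower MAF; tie -> later position
                if (maf[a], -m.pos_bp[a]) < (maf[b], -m.pos_bp[b]):
                    drop_local, drop = jj, a
                else:
                    drop_local, drop = kk, b
                removed_mask[drop] = True
                r2[drop_local, :] = 0.0
                r2[:, drop_local] = 0.0
            if start + window_snps >= len(cidx):
                break
    kept = [m.marker_id[i] for i in np.flatnonzero(~removed_mask)]
    removed = [m.marker_id[i] for i in np.flatnonzero(removed_mask)]
    return kept, removed


def build_dataset(
    g: GenotypeMatrix, m: MarkerMap, cfg: QCConfig
) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Run the full QC chain for the configured profile."""
    samples_in, markers_in = g.n_samples, g.n_markers
    g, removed_samples = sample_call_rate_filter(g, cfg.sample_call_rate_min)
    removals: dict = {}

    if cfg.profile == "roh":
        x_mask = ~m.autosome_mask()
        removals["x_chromosome"] = int(x_mask.sum())
        idx = np.flatnonzero(~x_mask)
        g, m = g.take_markers(idx), m.take(idx)
        maf_min = None
    else:
        maf_min = cfg.maf_min

    g, m, mk_removals = marker_filter(
        g, m, call_rate_min=cfg.marker_call_rate_min, maf_min=maf_min
    )
    removals.update(mk_removals)

    if cfg.profile == "gwas":
        # iterate pruning to a fixed point: removals re-window the remaining
        # markers, so a single pass is not idempotent
        removals["ld"] = 0
        while True:
            kept, removed = ld_prune(
                g, m, cfg.ld_r2_max, cfg.ld_window_snps, cfg.ld_window_step
            )
            if not removed:
                break
            removals["ld"] += len(removed)
            keep_set = set(kept)
            idx = np.flatnonzero([mid in keep_set for mid in m.marker_id])
            g, m = g.take_markers(idx), m.take(idx)

    report = QCReport(
        profile=cfg.profile,
        samples_in=samples_in,
        samples_out=g.n_samples,
        markers_in=markers_in,
        markers_out=g.n_markers,
        removals=removals,
        removed_samples=removed_samples,
    )
    report.validate()
    log.info(
        "QC (%s): left %d out of %d markers in %d animals",
        cfg.profile, report.markers_out, report.markers_in, report.samples_out,
    )
    return g, m, report
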