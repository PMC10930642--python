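"""Forward pedigree simulator with founder-tracked autozygosity.

Every chromosome of every individual is represented as a mosaic of founder
haplotype segments.  Identity by descent is therefore bookkeeping, not
inference: an interval is truly autozygous exactly when both gametes carry
the same founder haplotype, and that truth is what downstream ROH and F_ROH
estimates are judged against.

Founder haplotypes carry a U-shaped allele-frequency spectrum with
first-order copying LD; gametes recombine at 1 cM/Mbp (Poisson crossovers);
a configurable fraction of matings are between (half/full) sibs, which
populates all five ROH length classes; genotyping missingness and
heterozygote error are applied last and never touch the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import CHROM_X, MISSING, GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    The default genome is deliberately scaled down (5 autosomes x 50 Mbp,
    1,000 markers each, i.e. 20 markers/Mbp) so tests run quickly;
    :func:`chip_like_config` approximates the 29-autosome, ~63k-marker array.
    """

    n_samples: int = 334
    n_chrom: int = 5
    markers_per_chrom: int = 1000
    chrom_length_bp: int = 50_000_000
    include_x: bool = False
    founder_haplotypes: int = 40
    generations: int = 6
    mating: str = "random"               # "random" or "circular"
    inbred_mating_fraction: float = 0.3  # fraction of sib matings per generation
    ld_rho: float = 0.5                  # neighbor-copying probability
    maf_bounds: tuple = (0.05, 0.95)
    recomb_cm_per_mbp: float = 1.0
    missing_rate: float = 0.01
    het_error_rate: float = 0.001
    sweep_regions: tuple = ()            # (chrom, start_bp, end_bp, carrier_fraction)
    seed: int = 0

    def __post_init__(self):
        for name in ("inbred_mating_fraction", "ld_rho", "missing_rate",
                     "het_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mating not in ("random", "circular"):
            raise ValueError(f"unknown mating scheme {self.mating!r}")
        if self.founder_haplotypes < 2 or self.n_samples < 1:
            raise ValueError("need >= 2 founder haplotypes and >= 1 sample")

    @property
    def chrom_names(self) -> list:
        names = [str(i + 1) for i in range(self.n_chrom)]
        if self.include_x:
            names.append(CHROM_X)
        return names

    @property
    def autosome_bp(self) -> int:
        return self.n_chrom * self.chrom_length_bp


def chip_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Preset approximating a 29-autosome, ~63k-marker medium-density chip."""
    base = SimConfig(
        n_samples=334, n_chrom=29, markers_per_chrom=2195,
        chrom_length_bp=86_500_000, include_x=True, seed=seed,
    )
    return replace(base, **overrides)


@dataclass
class FounderPool:
    """Founder haplotypes and marker coordinates per chromosome."""

    positions: dict      # chrom -> int64 positions (sorted, unique)
    frequencies: dict    # chrom -> allele-1 frequency per marker
    haplotypes: dict     # chrom -> (n_haplotypes, n_markers) int8 alleles {0,1}

    @property
    def n_haplotypes(self) -> int:
        return next(iter(self.haplotypes.values())).shape[0]


@dataclass
class SimTruth:
    """Ground truth: per-sample autozygous intervals and genome-wide fraction."""

    intervals: dict               # sample_id -> list of (chrom, start_bp, end_bp)
    genome_bp: int
    sweep_regions: list = field(default_factory=list)
    qtl: dict | None = None

    def autozygosity(self, sample_id: str) -> float:
        return sum(e - s + 1 for _, s, e in self.intervals[sample_id]) / self.genome_bp

    def autozygosity_all(self) -> dict:
        return {sid: self.autozygosity(sid) for sid in self.intervals}


def simulate_founder_haplotypes(cfg: SimConfig, rng=None) -> FounderPool:
    """Draw the founder haplotype pool.

    Allele frequencies follow a Beta(0.5, 0.5) (U-shaped) spectrum truncated
    to ``maf_bounds``; linkage disequilibrium comes from a first-order
    copying process: with probability ``ld_rho`` a haplotype copies its
    allele at the previous marker, otherwise it draws from the marker's
    frequency.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.maf_bounds
    positions, freqs, haps = {}, {}, {}
    for chrom in cfg.chrom_names:
        m = cfg.markers_per_chrom
        pos = np.sort(
            rng.choice(
                np.arange(1, cfg.chrom_length_bp + 1, dtype=np.int64),
                size=m, replace=False,
            )
        )
        p = np.empty(m)
        filled = 0
        while filled < m:
            draw = rng.beta(0.5, 0.5, size=m - filled)
            ok = draw[(draw >= lo) & (draw <= hi)]
            p[filled : filled + len(ok)] = ok
            filled += len(ok)
        h = np.empty((cfg.founder_haplotypes, m), dtype=np.int8)
        h[:, 0] = rng.random(cfg.founder_haplotypes) < p[0]
        for j in range(1, m):
            copy = rng.random(cfg.founder_haplotypes) < cfg.ld_rho
            fresh = (rng.random(cfg.founder_haplotypes) < p[j]).astype(np.int8)
            h[:, j] = np.where(copy, h[:, j - 1], fresh)
        positions[chrom], freqs[chrom], haps[chrom] = pos, p, h
    return FounderPool(positions, freqs, haps)


# A gamete on one chromosome: (starts, hap_ids); segment k covers
# [starts[k], starts[k+1]-1], the last runs to the chromosome end.

def _meiosis(hap_a, hap_b, length_bp, expected_crossovers, rng):
    n_x = rng.poisson(expected_crossovers)
    if n_x == 0:
        return hap_a if rng.integers(2) == 0 else hap_b
    cuts = np.sort(rng.integers(2, length_bp, size=n_x))
    current = int(rng.integers(2))
    parents = (hap_a, hap_b)
    starts: list[int] = []
    ids: list[int] = []
    bounds = np.concatenate(([1], cuts, [length_bp + 1]))
    for k in range(len(bounds) - 1):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        if hi <= lo:
            current = 1 - current
            continue
        s, i = parents[current]
        j0 = int(np.searchsorted(s, lo, side="right")) - 1
        j1 = int(np.searchsorted(s, hi - 1, side="right"))
        for j in range(j0, j1):
            seg_start = max(int(s[j]), lo)
            if ids and ids[-1] == int(i[j]):
                pass  # merge with previous segment
            else:
                starts.append(seg_start)
                ids.append(int(i[j]))
        current = 1 - current
    return np.asarray(starts, dtype=np.int64), np.asarray(ids, dtype=np.int64)


def _autozygous_intervals(hap1, hap2, length_bp):
    """Intervals where both gametes carry the same founder haplotype."""
    s1, i1 = hap1
    s2, i2 = hap2
    cuts = np.unique(np.concatenate((s1, s2)))
    out = []
    for k, lo in enumerate(cuts):
        hi = int(cuts[k + 1]) - 1 if k + 1 < len(cuts) else length_bp
        a = int(i1[np.searchsorted(s1, lo, side="right") - 1])
        b = int(i2[np.searchsorted(s2, lo, side="right") - 1])
        if a == b:
            if out and out[-1][1] == lo - 1:
                out[-1] = (out[-1][0], hi)
            else:
                out.append((int(lo), hi))
    return out


def simulate_pedigree(
    cfg: SimConfig, pool: FounderPool, rng=None
) -> tuple[GenotypeMatrix, MarkerMap, SimTruth]:
    """Run the forward pedigree and emit genotypes plus autozygosity truth."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = cfg.n_samples
    chroms = cfg.chrom_names
    L = cfg.chrom_length_bp
    expected_x = L * cfg.recomb_cm_per_mbp * 1e-8

    # generation 0: two distinct founder haplotypes per individual
    def founder_individual():
        a, b = rng.choice(pool.n_haplotypes, size=2, replace=False)
        return {
            c: (
                (np.array([1], dtype=np.int64), np.array([a], dtype=np.int64)),
                (np.array([1], dtype=np.int64), np.array([b], dtype=np.int64)),
            )
            for c in chroms
        }

    population = [founder_individual() for _ in range(n)]
    parents = [(None, None)] * n

    for _gen in range(cfg.generations):
        sib_map: dict = {}
        for i, (pa, ma) in enumerate(parents):
            for par in (pa, ma):
                if par is not None:
                    sib_map.setdefault(par, []).append(i)
        new_pop, new_parents = [], []
        for child in range(n):
            if cfg.mating == "circular":
                p1, p2 = child % n, (child + 1) % n
            else:
                p1 = int(rng.integers(n))
                p2 = None
                if rng.random() < cfg.inbred_mating_fraction:
                    sibs = set()
                    for par in parents[p1]:
                        if par is not None:
                            sibs.update(sib_map.get(par, ()))
                    sibs.discard(p1)
                    if sibs:
                        p2 = int(rng.choice(sorted(sibs)))
                if p2 is None:
                    p2 = int(rng.integers(n))
                    while n > 1 and p2 == p1:
                        p2 = int(rng.integers(n))
            indiv = {}
            for c in chroms:
                g1 = _meiosis(*population[p1][c], L, expected_x, rng)
                g2 = _meiosis(*population[p2][c], L, expected_x, rng)
                indiv[c] = (g1, g2)
            new_pop.append(indiv)
            new_parents.append((p1, p2))
        population, parents = new_pop, new_parents

    samples = [f"cow{i:04d}" for i in range(n)]
    m_total = sum(len(pool.positions[c]) for c in chroms)
    dosage = np.empty((n, m_total), dtype=np.int8)
    col_of: dict = {}
    col = 0
    for c in chroms:
        col_of[c] = slice(col, col + len(pool.positions[c]))
        col += len(pool.positions[c])

    truth_intervals: dict = {}
    for i, indiv in enumerate(population):
        intervals = []
        for c in chroms:
            h1, h2 = indiv[c]
            pos = pool.positions[c]
            a1 = _alleles_on_markers(h1, pos, pool.haplotypes[c])
            a2 = _alleles_on_markers(h2, pos, pool.haplotypes[c])
            dosage[i, col_of[c]] = a1 + a2
            if c != CHROM_X:  # truth is autosomal, matching F_ROH's scope
                intervals.extend((c, s, e) for s, e in _autozygous_intervals(h1, h2, L))
        truth_intervals[samples[i]] = intervals

    # genotyping noise, applied after truth is frozen
    if cfg.het_error_rate > 0:
        hom = dosage != 1
        flip = (rng.random(dosage.shape) < cfg.het_error_rate) & hom
        dosage[flip] = 1
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING

    marker_id, chrom_lab, pos_all = [], [], []
    for c in chroms:
        pos = pool.positions[c]
        marker_id.extend(f"AX-{c}-{p}" for p in pos)
        chrom_lab.extend([c] * len(pos))
        pos_all.extend(pos)
    mmap = MarkerMap(
        np.asarray(marker_id, dtype=object),
        np.asarray(chrom_lab, dtype=object),
        np.asarray(pos_all, dtype=np.int64),
        np.asarray(["A"] * m_total, dtype=object),
        np.asarray(["B"] * m_total, dtype=object),
    )
    g = GenotypeMatrix(samples, dosage, np.full(m_total, 2, dtype=np.int64))
    truth = SimTruth(intervals=truth_intervals, genome_bp=cfg.autosome_bp)
    return g, mmap, truth


def _alleles_on_markers(hap, positions, founder_haps):
    starts, ids = hap
    out = np.empty(len(positions), dtype=np.int8)
    seg = np.searchsorted(starts, positions, side="right") - 1
    for k in np.unique(seg):
        sel = seg == k
        out[sel] = founder_haps[ids[k], np.flatnonzero(sel)]
    return out


def plant_sweep(
    g: GenotypeMatrix,
    m: MarkerMap,
    truth: SimTruth,
    region: tuple,
    carrier_fraction: float,
    pool: FounderPool | None = None,
    rng=None,
    min_length_bp: int = 1_000_000,
):
    """Plant a homozygosity island: carriers become homozygous for one
    founder haplotype across ``region`` = (chrom, start_bp, end_bp).

    Returns the updated (genotypes, truth); carrier truth intervals absorb
    the region.  A region shorter than the ROH length rule triggers a warning.
    """
    chrom, start_bp, end_bp = region
    if end_bp - start_bp + 1 < min_length_bp:
        warnings.warn("sweep region shorter than the minimum ROH length",
                      stacklevel=2)
    rng = np.random.default_rng(0) if rng is None else rng
    idx = np.flatnonzero((m.chrom == chrom)
                         & (m.pos_bp >= start_bp) & (m.pos_bp <= end_bp))
    if len(idx) == 0:
        raise ValueError("sweep region contains no markers")
    if pool is not None:
        hap = pool.haplotypes[chrom][0]
        local = np.searchsorted(pool.positions[chrom], m.pos_bp[idx])
        hom_dosage = (2 * hap[local]).astype(np.int8)
    else:
        hom_dosage = np.zeros(len(idx), dtype=np.int8)

    n_carriers = int(round(carrier_fraction * g.n_samples))
    carriers = rng.choice(g.n_samples, size=n_carriers, replace=False)
    dosage = g.dosage.copy()
    for i in carriers:
        dosage[i, idx] = hom_dosage
        sid = str(g.samples[i])
        merged = _merge_interval(truth.intervals[sid], (chrom, start_bp, end_bp))
        truth.intervals[sid] = merged
    truth.sweep_regions.append(
        {"chrom": chrom, "start_bp": start_bp, "end_bp": end_bp,
         "carrier_fraction": carrier_fraction}
    )
    return GenotypeMatrix(g.samples, dosage, g.n_alleles), truth


def _merge_interval(intervals, new):
    chrom, s, e = new
    keep, overl = [], []
    for iv in intervals:
        if iv[0] == chrom and iv[1] <= e + 1 and iv[2] >= s - 1:
            overl.append(iv)
        else:
            keep.append(iv)
    if overl:
        s = min(s, min(iv[1] for iv in overl))
        e = max(e, max(iv[2] for iv in overl))
    keep.append((chrom, s, e))
    return sorted(keep, key=lambda iv: (iv[0], iv[1]))


@dataclass(frozen=True)
class QTLSpec:
    """Additive single-SNP QTL on top of a polygenic + residual background.

    ``qtl_var`` is the fraction of total phenotypic variance the QTL explains;
    the background (variance 1) is split ``h2_polygenic`` to the kinship-
    structured polygenic term and the rest to i.i.d. residual.  ``mu`` sets
    the trait scale (default near a milk-protein concentration of ~3.2%).
    """

    marker_index: int
    qtl_var: float = 0.05
    h2_polygenic: float = 0.3
    mu: float = 3.2

    def __post_init__(self):
        if not 0.0 <= self.qtl_var < 1.0 or not 0.0 <= self.h2_polygenic <= 1.0:
            raise ValueError("variance fractions must lie in [0, 1)")


def simulate_phenotype(
    g: GenotypeMatrix, qtl: QTLSpec, seed: int, K=None
) -> tuple[np.ndarray, dict]:
    """Draw ``y = mu + beta * dosage + u + e`` and report realized components."""
    from .assoc import compute_kinship

    rng = np.random.default_rng(seed)
    n = g.n_samples
    sigma_g2 = qtl.h2_polygenic
    sigma_e2 = 1.0 - qtl.h2_polygenic
    if K is None and sigma_g2 > 0:
        K = compute_kinship(g)
    if qtl.qtl_var > 0:
        d = g.mean_imputed()[:, qtl.marker_index]
        vd = d.var()
        if vd <= 0:
            raise ValueError("QTL marker is monomorphic")
        beta = np.sqrt(qtl.qtl_var / (1.0 - qtl.qtl_var) / vd)
        qtl_term = beta * d
    else:
        beta, qtl_term = 0.0, np.zeros(n)
    u = np.zeros(n)
    if sigma_g2 > 0:
        Kv = K.values + 1e-8 * np.eye(n)
        u = np.linalg.cholesky(Kv) @ rng.standard_normal(n) * np.sqrt(sigma_g2)
    e = rng.standard_normal(n) * np.sqrt(sigma_e2)
    y = qtl.mu + qtl_term + u + e
    realized = {
        "beta": float(beta),
        "sigma_g2": sigma_g2,
        "sigma_e2": sigma_e2,
        "qtl_variance_share": float(np.var(qtl_term) / np.var(y)) if n > 1 else 0.0,
        "realized_h2": float(
            (np.var(qtl_term) + np.var(u)) / np.var(y)
        ) if n > 1 else 0.0,
    }
    return y, realized


def simulate_dataset(cfg: SimConfig):
    """One-call generator: founders -> pedigree -> sweeps; fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    pool = simulate_founder_haplotypes(cfg, rng)
    g, m, truth = simulate_pedigree(cfg, pool, rng)
    for region in cfg.sweep_regions:
        chrom, start_bp, end_bp, frac = region
        g, truth = plant_sweep(
            g, m, truth, (str(chrom), int(start_bp), int(end_bp)), float(frac),
            pool=pool, rng=rng,
        )
    return g, m, truth, pool
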