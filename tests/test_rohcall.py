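"""ROH caller: rule boundaries, brute-force oracle agreement, summaries."""

import numpy as np
import pytest

from rohscan import MISSING, ROHParams, call_roh_all, call_roh_sample, classify_length, summarize_roh
from rohscan.rohcall import ROHSegment, segments_to_dataframe
from rohscan.simdata import SimConfig, simulate_dataset

from conftest import make_matrix, uniform_map

HOM, HET = 0, 1


def brute_force_roh(dosage, positions, p: ROHParams):
    """Independent quadratic oracle: test every subinterval against the rules,
    keep qualifying intervals that are maximal (not contained in another
    qualifying interval), then select them disjointly from the left."""
    n = len(dosage)
    qualifying = []
    for i in range(n):
        if dosage[i] in (HET, MISSING):
            continue
        for j in range(i, n):
            window = dosage[i : j + 1]
            if dosage[j] in (HET, MISSING):
                continue
            if (window == HET).sum() > p.max_het:
                continue
            if (window == MISSING).sum() > p.max_missing:
                continue
            n_hom = int(((window == 0) | (window == 2)).sum())
            span = int(positions[j] - positions[i]) + 1
            if n_hom >= p.min_snp and span >= p.min_length_bp:
                qualifying.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in qualifying
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in qualifying)
    ]
    maximal.sort()
    chosen, last_end = [], -1
    for i, j in maximal:
        if i > last_end:
            chosen.append((i, j))
            last_end = j
    return [
        (
            int(positions[i]),
            int(positions[j]),
            int(((dosage[i : j + 1] == 0) | (dosage[i : j + 1] == 2)).sum()),
            int((dosage[i : j + 1] == MISSING).sum()),
        )
        for i, j in chosen
    ]


def as_tuples(segments):
    return [(s.start_bp, s.end_bp, s.n_hom, s.n_missing) for s in segments]


class TestCallRohSample:
    def test_clean_run_coordinates_and_counts(self):
        pos = np.linspace(1_000_000, 2_500_000, 30).astype(np.int64)
        segs = call_roh_sample(np.zeros(30, dtype=np.int8), pos)
        assert as_tuples(segs) == brute_force_roh(np.zeros(30, dtype=np.int8), pos,
                                                  ROHParams())
        (s,) = segs
        assert (s.n_hom, s.n_missing, s.length_bp) == (30, 0, 1_500_001)

    def test_too_few_snps_rejected(self):
        pos = np.linspace(1_000_000, 3_000_000, 24).astype(np.int64)
        assert call_roh_sample(np.zeros(24, dtype=np.int8), pos) == []

    def test_too_short_span_rejected(self):
        pos = np.linspace(1_000_000, 1_900_000, 30).astype(np.int64)
        assert call_roh_sample(np.zeros(30, dtype=np.int8), pos) == []

    def test_heterozygote_splits_run(self):
        # two sub-1 Mbp halves around a het -> nothing qualifies
        pos = np.concatenate(
            [np.linspace(1_000_000, 1_900_000, 20), np.linspace(2_000_000, 2_900_000, 21)]
        ).astype(np.int64)
        dosage = np.zeros(41, dtype=np.int8)
        dosage[20] = HET
        assert call_roh_sample(dosage, pos) == []
        assert brute_force_roh(dosage, pos, ROHParams()) == []

    def test_five_missing_tolerated(self):
        pos = np.linspace(1_000_000, 2_200_000, 40).astype(np.int64)
        dosage = np.zeros(40, dtype=np.int8)
        dosage[[7, 13, 19, 25, 31]] = MISSING
        segs = call_roh_sample(dosage, pos)
        assert len(segs) == 1 and segs[0].n_missing == 5 and segs[0].n_hom == 35
        assert as_tuples(segs) == brute_force_roh(dosage, pos, ROHParams())

    def test_sixth_missing_splits_run(self):
        pos = (1_000_000 + 50_000 * np.arange(80)).astype(np.int64)
        dosage = np.zeros(80, dtype=np.int8)
        dosage[[5, 12, 18, 24, 30, 36]] = MISSING  # six unread calls
        segs = call_roh_sample(dosage, pos)
        assert as_tuples(segs) == brute_force_roh(dosage, pos, ROHParams())
        assert all(s.n_missing <= 5 for s in segs)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            call_roh_sample(np.zeros(3, dtype=np.int8), np.array([5, 3, 9]))

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_agreement_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        pos = np.sort(rng.choice(np.arange(1, 6_000_000), size=n, replace=False))
        dosage = rng.choice(
            [0, 2, HET, MISSING], size=n, p=[0.45, 0.4, 0.05, 0.1]
        ).astype(np.int8)
        p = ROHParams(
            min_snp=int(rng.integers(5, 30)),
            min_length_bp=int(rng.integers(100_000, 2_000_000)),
            max_missing=int(rng.integers(0, 8)),
        )
        assert as_tuples(call_roh_sample(dosage, pos, p)) == brute_force_roh(
            dosage, pos, p
        )

    def test_monotone_in_min_snp_and_length(self):
        rng = np.random.default_rng(99)
        pos = np.sort(rng.choice(np.arange(1, 8_000_000), size=150, replace=False))
        dosage = rng.choice([0, 2, HET, MISSING], size=150,
                            p=[0.46, 0.44, 0.03, 0.07]).astype(np.int8)
        base = len(call_roh_sample(dosage, pos, ROHParams(min_snp=10,
                                                          min_length_bp=200_000)))
        for min_snp, min_len in [(15, 200_000), (10, 500_000), (20, 800_000)]:
            stricter = len(
                call_roh_sample(dosage, pos,
                                ROHParams(min_snp=min_snp, min_length_bp=min_len))
            )
            assert stricter <= base


class TestClassify:
    @pytest.mark.parametrize(
        "length_bp, label",
        [
            (65_310_000, ">16"),   # longest reported segment
            (2_000_000, "2-4"),    # left edge is inclusive
            (1_500_000, "1-2"),
            (16_000_000, ">16"),
            (15_999_999, "8-16"),
        ],
    )
    def test_bins(self, length_bp, label):
        assert classify_length(length_bp) == label

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError):
            classify_length(999_999)


class TestCallAll:
    def test_x_chromosome_rejected(self):
        m = uniform_map(30, chrom="X")
        g = make_matrix(np.zeros((2, 30)))
        with pytest.raises(ValueError, match="autosomes"):
            call_roh_all(g, m)

    def test_all_heterozygous_empty(self):
        m = uniform_map(50)
        g = make_matrix(np.ones((3, 50)))
        assert call_roh_all(g, m) == []

    def test_fully_homozygous_single_segment_per_sample(self):
        m = uniform_map(1000, spacing=30_000)  # 30 Mbp chromosome
        g = make_matrix(np.zeros((4, 1000)))
        segs = call_roh_all(g, m)
        assert len(segs) == 4
        assert {s.sample_id for s in segs} == {"s0", "s1", "s2", "s3"}

    def test_sample_permutation_permutes_rows_only(self):
        cfg = SimConfig(n_samples=12, n_chrom=2, markers_per_chrom=400,
                        chrom_length_bp=20_000_000, missing_rate=0.0,
                        het_error_rate=0.0, seed=21)
        g, m, _, _ = simulate_dataset(cfg)
        perm = np.arange(g.n_samples)[::-1]
        segs_a = segments_to_dataframe(call_roh_all(g, m))
        segs_b = segments_to_dataframe(call_roh_all(g.take_samples(perm), m))
        key = ["sample_id", "chrom", "start_bp"]
        a = segs_a.sort_values(key).reset_index(drop=True)
        b = segs_b.sort_values(key).reset_index(drop=True)
        assert a.equals(b)

    def test_simulated_truth_recovered(self):
        cfg = SimConfig(n_samples=20, n_chrom=3, markers_per_chrom=1000,
                        chrom_length_bp=40_000_000, missing_rate=0.0,
                        het_error_rate=0.0, seed=13)
        g, m, truth, _ = simulate_dataset(cfg)
        segs = call_roh_all(g, m)
        # chance homozygosity can extend a call past the true tract ends, so
        # require that true autozygous intervals cover >= 80% of each long call
        n_checked = 0
        for s in segs:
            if s.length_bp < 2_000_000:
                continue
            n_checked += 1
            covered = sum(
                max(0, min(s.end_bp, iv[2]) - max(s.start_bp, iv[1]) + 1)
                for iv in truth.intervals[s.sample_id]
                if iv[0] == s.chrom
            )
            assert covered >= 0.8 * s.length_bp, s
        assert n_checked > 0


class TestSummarize:
    def test_hand_computed_two_animals(self):
        segs = [
            ROHSegment("A", "1", 1_000_000, 2_499_999, 30, 0),   # 1.5 Mbp
            ROHSegment("A", "2", 1_000_000, 3_999_999, 60, 0),   # 3.0 Mbp
            ROHSegment("B", "1", 5_000_000, 6_199_999, 28, 0),   # 1.2 Mbp
        ]
        summ = summarize_roh(segs, ["A", "B"])
        counts_12 = summ.class_stats.query(
            "length_class == '1-2' and quantity == 'count'"
        ).iloc[0]
        assert counts_12["n_animals_with_class"] == 2
        assert counts_12["mean"] == 1.0
        counts_24 = summ.class_stats.query(
            "length_class == '2-4' and quantity == 'count'"
        ).iloc[0]
        assert counts_24["n_animals_with_class"] == 1
        assert summ.n_segments == 3

    def test_single_segment_grand_mean(self):
        segs = [ROHSegment("A", "1", 1_000_000, 3_499_999, 50, 0)]
        summ = summarize_roh(segs, ["A"])
        assert summ.grand_mean_length_mbp == pytest.approx(2.5)

    def test_summary_totals_match_truth_totals(self):
        cfg = SimConfig(n_samples=25, n_chrom=3, markers_per_chrom=600,
                        chrom_length_bp=30_000_000, missing_rate=0.0,
                        het_error_rate=0.0, seed=31)
        g, m, truth, _ = simulate_dataset(cfg)
        segs = call_roh_all(g, m)
        summ = summarize_roh(segs, g.samples)
        per_class_counts = summ.per_animal[[f"n_{c}" for c in
                                            ("1-2", "2-4", "4-8", "8-16", ">16")]]
        assert per_class_counts.to_numpy().sum() == summ.n_segments

    def test_empty_segments_warn(self):
        with pytest.warns(UserWarning, match="no ROH"):
            summ = summarize_roh([], ["A"])
        assert summ.n_segments == 0
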