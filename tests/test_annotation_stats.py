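"""Summary statistics: rates, support, repeats, composition, pair matrix,
sex-chromosome accounting, gap histogram, and shuffled gene coverage."""

import numpy as np
import pytest

from microchimera.annotation_stats import (
    SampleSexStats,
    annotate_repeats,
    chromosome_pair_matrix,
    composition,
    events_per_billion,
    gap_distribution,
    gene_body_coverage,
    nonchimeric_support,
    sex_chromosome_accounting,
)
from microchimera.chimera_detection import ChimeraEvent, JunctionCall
from microchimera.io_core import Interval


def make_event(read_id, chrom_a, a_start, chrom_b, b_start, gap=0, w=200):
    jt = "dual" if gap < 0 else "base_to_base" if gap == 0 else "gapped"
    junction = JunctionCall(
        last_a_window_start=0,
        first_b_window_start=gap + w,
        gap=gap,
        junction_type=jt,
        homology_len=-gap if gap < 0 else 0,
        genomic_a=Interval(chrom_a, a_start, a_start + w, strand="+"),
        genomic_b=Interval(chrom_b, b_start, b_start + w, strand="+"),
    )
    ev = ChimeraEvent(read_id, chrom_a, chrom_b, 1, (200, 400), junction)
    ev.classify_hemizygosity()
    return ev


class TestRates:
    def test_zero_events(self):
        assert events_per_billion(0, 10_000) == 0.0

    def test_zero_bases_rejected(self):
        with pytest.raises(ValueError):
            events_per_billion(5, 0)

    def test_rate_linearity(self):
        assert events_per_billion(30, 3_000_000) == events_per_billion(10, 1_000_000)


class TestSupport:
    def test_toy_overlap_enumeration(self, detection_run):
        """One event flanked by hand-placed non-chimeric reads: counts
        match exhaustive enumeration of window overlaps."""
        from microchimera.binning_alignment import Bin, BinAlignment, BinAlignmentVector
        from microchimera.chimera_detection import ReadClass

        ev = make_event("e1", "chr1", 10_000, "chr2", 30_000)
        # two reads overlapping the A flank +/- one bin, one on the B flank,
        # one far away
        vectors = {}
        classes = []
        placements = {
            "n1": ("chr1", 9_900),
            "n2": ("chr1", 10_350),
            "n3": ("chr2", 29_850),
            "n4": ("chr1", 50_000),
        }
        for rid, (chrom, pos) in placements.items():
            b = Bin(rid, 0, 0, 200, "A" * 200)
            vectors[rid] = BinAlignmentVector(
                rid, [BinAlignment(b, "unique", chrom, pos, "+", 0)]
            )
            classes.append(ReadClass(rid, "non_chimeric"))
        support, summary = nonchimeric_support([ev], vectors, classes, window=200)
        assert support == [3]
        assert summary["median"] == 3

    def test_no_overlapping_reads(self):
        ev = make_event("e1", "chr1", 10_000, "chr2", 30_000)
        support, _ = nonchimeric_support([ev], {}, [], window=200)
        assert support == [0]

    def test_uniform_coverage_poisson_oracle(self, detection_run):
        """Uniform background coverage: mean support per event sits within
        3 SD of the Lander-Waterman expectation for two flank windows."""
        run = detection_run
        support, summary = nonchimeric_support(
            run.result.events, run.result.vectors, run.result.classes, window=200
        )
        genome_len = sum(g.length for g in run.genome)
        n_bg = sum(1 for c in run.result.classes if c.label == "non_chimeric")
        read_len = 1000
        window_span = 600  # 200 bp footprint padded by 200 each side
        lam_per_flank = n_bg * (window_span + read_len) / genome_len
        expected = 2 * lam_per_flank
        sd_mean = np.sqrt(expected / len(support))
        assert abs(summary["mean"] - expected) < 3 * sd_mean + 0.2


class TestRepeatAnnotation:
    def test_footprint_inside_planted_repeat(self):
        repeats = [Interval("chr1", 9_000, 12_000, "LINE/L1Sim")]
        ev = make_event("e1", "chr1", 9_500, "chr2", 30_000)
        anns, fractions = annotate_repeats([ev], repeats)
        assert anns[0].primary_class == "LINE/L1Sim"
        assert fractions["LINE/L1Sim"] == 100.0

    def test_repeat_free_event(self):
        repeats = [Interval("chr1", 50_000, 50_300, "SINE/AluSim")]
        ev = make_event("e1", "chr1", 9_500, "chr2", 30_000)
        anns, fractions = annotate_repeats([ev], repeats)
        assert anns[0].primary_class == "repeat_free"
        assert fractions["repeat_free"] == 100.0

    def test_max_overlap_wins_and_both_listed(self):
        repeats = [
            Interval("chr1", 9_650, 9_700, "SINE/AluSim"),  # 50 bp of A flank
            Interval("chr2", 29_980, 30_100, "LINE/L1Sim"),  # 120 bp of B side
        ]
        ev = make_event("e1", "chr1", 9_500, "chr2", 30_000)
        anns, _ = annotate_repeats([ev], repeats)
        assert anns[0].primary_class == "LINE/L1Sim"
        assert dict(anns[0].classes_hit) == {"SINE/AluSim": 50, "LINE/L1Sim": 120}

    def test_fractions_sum_to_100(self, detection_run):
        events = detection_run.result.events
        _, fractions = annotate_repeats(events, detection_run.repeats)
        assert fractions.sum() == pytest.approx(100.0)

    def test_chrom_mismatch_rejected(self):
        repeats = [Interval("weird", 0, 100, "SINE/AluSim")]
        ev = make_event("e1", "chr1", 9_500, "chr2", 30_000)
        with pytest.raises(ValueError, match="weird"):
            annotate_repeats([ev], repeats, chrom_names={"chr1", "chr2"})


class TestComposition:
    @pytest.mark.parametrize(
        "seq,gc,skew",
        [("GGGG", 100.0, 1.0), ("ATAT", 0.0, 0.0), ("CCCC", 100.0, -1.0)],
    )
    def test_gc_and_skew(self, seq, gc, skew):
        stats = composition(seq)
        assert stats.gc_percent == gc
        assert stats.gc_skew == skew

    def test_cpg_dinucleotide_count(self):
        stats = composition("GCGC")
        assert stats.gc_skew == 0.0
        assert stats.cpg_percent == pytest.approx(100 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composition("")

    def test_reverse_complement_properties(self):
        from microchimera.binning_alignment import reverse_complement

        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        fwd, rev = composition(seq), composition(reverse_complement(seq))
        assert fwd.gc_percent == pytest.approx(rev.gc_percent)
        assert fwd.gc_skew == pytest.approx(-rev.gc_skew)


class TestPairMatrix:
    def test_symmetry_and_single_pair(self):
        events = [make_event("e1", "chr1", 100, "chr2", 200)] * 3
        matrix, _, _ = chromosome_pair_matrix(
            events, {"chr1": 1000, "chr2": 2000, "chr3": 3000}
        )
        assert matrix.loc["chr1", "chr2"] == matrix.loc["chr2", "chr1"] == 3
        assert matrix.loc["chr3"].sum() == 0

    def test_too_few_chromosomes(self):
        matrix, r, p = chromosome_pair_matrix([], {"chr1": 1000, "chr2": 2000})
        assert r is None and p is None

    def test_length_proportional_sampling_gives_high_r(self):
        """Events drawn proportional to chromosome length correlate with
        length (r > 0.9 at n = 3000)."""
        rng = np.random.default_rng(5)
        lengths = {"chr1": 100_000, "chr2": 200_000, "chr3": 300_000, "chr4": 150_000}
        names = list(lengths)
        probs = np.array([lengths[c] for c in names], dtype=float)
        probs /= probs.sum()
        events = []
        for i in range(3000):
            a, b = rng.choice(len(names), size=2, replace=False, p=probs)
            events.append(make_event(f"e{i}", names[a], 100, names[b], 100))
        _, r, p = chromosome_pair_matrix(events, lengths)
        assert r > 0.9
        assert p < 0.05


class TestSexAccounting:
    def test_equal_fractions_expected_equals_observed(self):
        s = SampleSexStats(1000, 100, 8, 100)
        out = sex_chromosome_accounting(s, s)
        assert out["expected_pct_test"] == out["observed_pct_test"] == 8.0

    def test_halved_capture_halves_expectation(self):
        ref = SampleSexStats(1000, 100, 8, 100)
        test = SampleSexStats(1000, 50, 8, 100)
        out = sex_chromosome_accounting(test, ref)
        assert out["expected_pct_test"] == pytest.approx(4.0)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            sex_chromosome_accounting(
                SampleSexStats(0, 0, 0, 1), SampleSexStats(10, 1, 1, 1)
            )


class TestGapDistribution:
    def test_all_base_to_base_single_bin(self):
        events = [make_event(f"e{i}", "chr1", 100, "chr2", 200, gap=0) for i in range(5)]
        hist = gap_distribution(events, bin_width=5)
        assert list(hist["gap_bin"]) == [0]
        assert list(hist["percent"]) == [100.0]

    def test_negative_mass_equals_dual_fraction(self, detection_run):
        events = detection_run.result.events
        hist = gap_distribution(events, bin_width=1)
        neg = hist.loc[hist["gap_bin"] < 0, "percent"].sum()
        dual_frac = sum(
            1 for e in events if e.junction.junction_type == "dual"
        ) / len(events) * 100
        assert neg == pytest.approx(dual_frac)

    def test_dual_gaps_within_configured_homology_range(self, detection_run):
        for ev in detection_run.result.events:
            j = ev.junction
            if j.junction_type == "dual":
                assert -60 <= j.gap <= -20
            elif j.junction_type == "gapped":
                assert 10 <= j.gap < 40


@pytest.fixture(scope="module")
def transcripts():
    rng = np.random.default_rng(17)
    out = []
    for i in range(40):
        chrom = f"chr{1 + i % 2}"
        start = int(rng.integers(0, 90_000))
        out.append(Interval(chrom, start, start + 2_000, f"tx{i}"))
    return out


class TestGeneBodyCoverage:
    CHROM_LENGTHS = {"chr1": 100_000, "chr2": 100_000}

    def test_uniform_events_observed_matches_expected(self, transcripts):
        rng = np.random.default_rng(23)
        events = []
        for i in range(150):
            chrom = f"chr{1 + i % 2}"
            start = int(rng.integers(0, 99_000))
            events.append(Interval(chrom, start, start + 200))
        out = gene_body_coverage(
            events, transcripts, self.CHROM_LENGTHS, seed=3, n_shuffles=20
        )
        band = 4 * max(out["expected_sd"], 1.0)
        assert abs(out["observed"] - out["expected"]) < band

    def test_transcript_avoiding_events_depleted(self, transcripts):
        import intervaltree

        trees = {}
        for t in transcripts:
            trees.setdefault(t.chrom, intervaltree.IntervalTree()).addi(t.start, t.end)
        rng = np.random.default_rng(29)
        events = []
        while len(events) < 100:
            chrom = f"chr{1 + len(events) % 2}"
            start = int(rng.integers(0, 99_000))
            if not trees[chrom].overlap(start, start + 200):
                events.append(Interval(chrom, start, start + 200))
        out = gene_body_coverage(
            events, transcripts, self.CHROM_LENGTHS, seed=5, n_shuffles=10
        )
        assert out["observed"] == 0
        assert out["expected"] > 0

    def test_zero_events(self, transcripts):
        out = gene_body_coverage([], transcripts, self.CHROM_LENGTHS, seed=1)
        assert out["observed"] == out["expected"] == 0

    def test_shuffle_preserves_lengths_and_is_seeded(self, transcripts):
        events = [Interval("chr1", 0, 500), Interval("chr2", 10, 1_010)]
        a = gene_body_coverage(events, transcripts, self.CHROM_LENGTHS, seed=9)
        b = gene_body_coverage(events, transcripts, self.CHROM_LENGTHS, seed=9)
        assert a == b
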