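"""Event annotation and the per-sample summary statistics of the pipeline.

Covers: events-per-billion-bases rates, non-chimeric support per event,
repeat-class annotation by BED intersection, sequence composition
(GC/CpG/skew), chromosome-pair distribution vs chromosome length,
sex-chromosome accounting with representation normalisation, the signed
gap-metric histogram, and observed-vs-expected gene-body coverage under a
seeded genome-wide shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sp_stats

from microchimera.binning_alignment import BinAlignmentVector
from microchimera.chimera_detection import NON_CHIMERIC, ChimeraEvent, ReadClass
from microchimera.io_core import Interval


# ---------------------------------------------------------------------------
# Rates and simple summaries


def events_per_billion(aub_events: int, total_bases: int) -> float:
    """Chimeric DNA events per billion bases sequenced, to 2 decimals."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    return round(aub_events / total_bases * 1e9, 2)


def mean_read_length(total_bases: int, total_reads: int) -> float:
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return round(total_bases / total_reads, 2)


def percent_mapped(reads_mapped: int, total_reads: int) -> float:
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return round(reads_mapped / total_reads * 100, 2)


def fold_change(rate_test: float, rate_reference: float) -> float:
    if rate_reference <= 0:
        raise ValueError("reference rate must be positive")
    return round(rate_test / rate_reference, 1)


@dataclass
class SampleSummary:
    total_reads: int
    total_bases: int
    aub_events: int
    support_mean: Optional[float] = None
    support_sd: Optional[float] = None
    support_median: Optional[float] = None
    pct_mapped: Optional[float] = None

    @property
    def events_per_billion_bases(self) -> float:
        return events_per_billion(self.aub_events, self.total_bases)


# ---------------------------------------------------------------------------
# Non-chimeric support


def nonchimeric_support(
    events: Sequence[ChimeraEvent],
    vectors: dict[str, BinAlignmentVector],
    classes: Sequence[ReadClass],
    window: int = 200,
) -> tuple[list[int], dict[str, float]]:
    """Non-chimeric reads supporting each event's two flank regions.

    A non-chimeric read supports an event when one of its uniquely
    aligned bins overlaps either refined flank footprint padded by
    ``window`` (one bin size by default).  Returns per-event counts and
    mean/SD/median over events (sample SD, matching a mean +/- SD report).
    """
    trees: dict[str, IntervalTree] = {}
    for idx, ev in enumerate(events):
        if ev.junction is None:
            continue
        for fp in (ev.junction.genomic_a, ev.junction.genomic_b):
            trees.setdefault(fp.chrom, IntervalTree()).addi(
                max(0, fp.start - window), fp.end + window, idx
            )
    non_chimeric_ids = {rc.read_id for rc in classes if rc.label == NON_CHIMERIC}
    support = [0] * len(events)
    for read_id in non_chimeric_ids:
        vec = vectors.get(read_id)
        if vec is None:
            continue
        hit: set[int] = set()
        for aln in vec.alignments:
            if aln.status != "unique" or aln.chrom not in trees:
                continue
            for iv in trees[aln.chrom].overlap(aln.pos, aln.pos + len(aln.bin.sequence)):
                hit.add(iv.data)
        for idx in hit:
            support[idx] += 1
    arr = np.asarray(support, dtype=float)
    summary = {
        "mean": float(arr.mean()) if len(arr) else float("nan"),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "median": float(np.median(arr)) if len(arr) else float("nan"),
    }
    return support, summary


# ---------------------------------------------------------------------------
# Repeat annotation


@dataclass
class RepeatAnnotation:
    event_id: str
    classes_hit: list[tuple[str, int]] = field(default_factory=list)
    primary_class: str = "repeat_free"


def _event_footprints(ev: ChimeraEvent, bin_size: int) -> list[Interval]:
    """The two refined flank footprints plus the unaligned transition
    region projected onto each donor chromosome (one bin beyond the
    junction-side end of each flank, strand-aware)."""
    j = ev.junction
    if j is None:
        return []
    out = [j.genomic_a, j.genomic_b]
    a, b = j.genomic_a, j.genomic_b
    if a.strand == "-":
        ua = (max(0, a.start - bin_size), a.start)
    else:
        ua = (a.end, a.end + bin_size)
    if b.strand == "-":
        ub = (b.end, b.end + bin_size)
    else:
        ub = (max(0, b.start - bin_size), b.start)
    if ua[0] < ua[1]:
        out.append(Interval(a.chrom, ua[0], ua[1]))
    if ub[0] < ub[1]:
        out.append(Interval(b.chrom, ub[0], ub[1]))
    return out


def annotate_repeats(
    events: Sequence[ChimeraEvent],
    repeats: Sequence[Interval],
    bin_size: int = 200,
    chrom_names: Optional[set[str]] = None,
) -> tuple[list[RepeatAnnotation], pd.Series]:
    """Intersect event footprints with a repeat BED and tally classes.

    Returns per-event annotations (all classes hit with overlap bases,
    and the max-overlap primary class, ``repeat_free`` if none) plus the
    percentage of events per primary class (sums to 100).
    """
    if chrom_names is not None:
        offenders = sorted({r.chrom for r in repeats} - chrom_names)
        if offenders:
            raise ValueError(
                f"repeat BED chromosomes absent from genome: {offenders}"
            )
    trees: dict[str, IntervalTree] = {}
    for r in repeats:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.name)

    annotations: list[RepeatAnnotation] = []
    for ev in events:
        overlap_by_class: dict[str, int] = {}
        for fp in _event_footprints(ev, bin_size):
            tree = trees.get(fp.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(fp.start, fp.end):
                ov = min(fp.end, iv.end) - max(fp.start, iv.begin)
                if ov > 0:
                    overlap_by_class[iv.data] = overlap_by_class.get(iv.data, 0) + ov
        ann = RepeatAnnotation(ev.read_id, sorted(overlap_by_class.items()))
        if overlap_by_class:
            ann.primary_class = min(
                overlap_by_class, key=lambda c: (-overlap_by_class[c], c)
            )
        annotations.append(ann)

    counts = pd.Series([a.primary_class for a in annotations]).value_counts()
    fractions = (counts / max(len(annotations), 1) * 100).sort_index()
    return annotations, fractions


def subfamily_tallies(annotations: Sequence[RepeatAnnotation]) -> pd.Series:
    """Primary-class counts at the RepeatMasker "class/subfamily" level."""
    return pd.Series(
        [a.primary_class for a in annotations if a.primary_class != "repeat_free"]
    ).value_counts()


# ---------------------------------------------------------------------------
# Sequence composition


@dataclass(frozen=True)
class CompositionStats:
    gc_percent: float
    cpg_percent: float
    gc_skew: float


def composition(seq: str) -> CompositionStats:
    """GC %, CpG dinucleotide % (CG count / (L-1) x 100) and G/C skew
    (G-C)/(G+C).  Case-insensitive; N bases are excluded from both the
    numerator and the denominator; skew is defined 0 when G+C = 0."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    g, c = s.count("G"), s.count("C")
    denom = len(s) - s.count("N")
    gc_percent = 100.0 * (g + c) / denom if denom else 0.0
    cpg = s.count("CG")
    cpg_percent = 100.0 * cpg / (len(s) - 1) if len(s) > 1 else 0.0
    skew = (g - c) / (g + c) if (g + c) else 0.0
    return CompositionStats(gc_percent, cpg_percent, skew)


# ---------------------------------------------------------------------------
# Chromosome-pair distribution


def chromosome_pair_matrix(
    events: Sequence[ChimeraEvent], chrom_lengths: dict[str, int]
) -> tuple[pd.DataFrame, Optional[float], Optional[float]]:
    """Symmetric pair-count matrix and Pearson r of per-chromosome event
    counts against chromosome lengths (None when fewer than 3 chromosomes)."""
    chroms = sorted(chrom_lengths)
    matrix = pd.DataFrame(0, index=chroms, columns=chroms, dtype=int)
    for ev in events:
        matrix.loc[ev.chrom_a, ev.chrom_b] += 1
        matrix.loc[ev.chrom_b, ev.chrom_a] += 1
    marginal = matrix.sum(axis=1)
    if len(chroms) < 3:
        return matrix, None, None
    lengths = np.asarray([chrom_lengths[c] for c in chroms], dtype=float)
    r, p = sp_stats.pearsonr(marginal.to_numpy(dtype=float), lengths)
    return matrix, float(r), float(p)


# ---------------------------------------------------------------------------
# Sex-chromosome accounting


@dataclass(frozen=True)
class SampleSexStats:
    reads_mapped: int
    reads_mapped_x: int
    x_u_a_events: int
    total_events: int

    @property
    def x_fraction(self) -> float:
        return self.reads_mapped_x / self.reads_mapped

    @property
    def observed_pct(self) -> float:
        return self.x_u_a_events / self.total_events * 100


def sex_chromosome_accounting(
    test: SampleSexStats, reference: SampleSexStats
) -> dict[str, float]:
    """Observed and representation-normalised expected X-U-A percentages.

    The expected percentage rescales the test sample's observed value by
    the ratio of X-mapped read fractions (test over reference), so a
    lower X capture in the test sample lowers what would be expected of
    it; with equal X fractions, expected equals observed.
    """
    if test.reads_mapped <= 0 or reference.reads_mapped <= 0:
        raise ValueError("reads_mapped must be positive")
    if test.total_events <= 0 or reference.total_events <= 0:
        raise ValueError("total_events must be positive")
    expected = test.observed_pct * (test.x_fraction / reference.x_fraction)
    return {
        "observed_pct_test": round(test.observed_pct, 2),
        "observed_pct_reference": round(reference.observed_pct, 2),
        "expected_pct_test": round(expected, 2),
    }


# ---------------------------------------------------------------------------
# Gap distribution


def gap_distribution(
    events: Sequence[ChimeraEvent],
    bin_width: int = 5,
    primary_class: Optional[str] = None,
    annotations: Optional[Sequence[RepeatAnnotation]] = None,
) -> pd.DataFrame:
    """Histogram of signed gap values as percentages of events.

    Optionally restricted to events whose primary repeat class matches
    ``primary_class`` (requires ``annotations``).  Columns: ``gap_bin``
    (left edge), ``count``, ``percent`` (sums to 100 over the selection).
    """
    gaps = []
    for i, ev in enumerate(events):
        if ev.junction is None:
            continue
        if primary_class is not None:
            if annotations is None:
                raise ValueError("annotations required for class stratification")
            if annotations[i].primary_class != primary_class:
                continue
        gaps.append(ev.junction.gap)
    if not gaps:
        return pd.DataFrame(columns=["gap_bin", "count", "percent"])
    arr = np.asarray(gaps)
    left = np.floor(arr / bin_width).astype(int) * bin_width
    counts = pd.Series(left).value_counts().sort_index()
    return pd.DataFrame(
        {
            "gap_bin": counts.index,
            "count": counts.to_numpy(),
            "percent": counts.to_numpy() / len(arr) * 100,
        }
    )


# ---------------------------------------------------------------------------
# Gene-body coverage, observed vs shuffled expectation


def _count_covered_transcripts(
    intervals: Iterable[Interval], transcripts: Sequence[Interval]
) -> int:
    trees: dict[str, IntervalTree] = {}
    for i, t in enumerate(transcripts):
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, i)
    covered: set[int] = set()
    for iv in intervals:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            covered.add(hit.data)
    return len(covered)


def gene_body_coverage(
    event_intervals: Sequence[Interval],
    transcripts: Sequence[Interval],
    chrom_lengths: dict[str, int],
    n_normalized: Optional[int] = None,
    seed: int = 0,
    n_shuffles: int = 10,
) -> dict[str, float]:
    """Observed vs expected transcript coverage by event intervals.

    A seeded random subset of ``n_normalized`` event intervals (depth
    normalisation across samples) is intersected with the transcript
    set; the expectation places the same intervals, lengths preserved,
    uniformly at random genome-wide and averages the covered-transcript
    count over ``n_shuffles`` seeded shuffles.
    """
    rng = np.random.default_rng(seed)
    events = list(event_intervals)
    if n_normalized is None or n_normalized >= len(events):
        selected = events
    else:
        idx = rng.choice(len(events), size=n_normalized, replace=False)
        selected = [events[i] for i in sorted(idx)]

    observed = _count_covered_transcripts(selected, transcripts)

    chroms = sorted(chrom_lengths)
    lengths = np.asarray([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    expected_counts = []
    for _ in range(n_shuffles):
        shuffled = []
        for iv in selected:
            L = len(iv)
            for _attempt in range(100):
                ci = int(rng.choice(len(chroms), p=probs))
                max_start = chrom_lengths[chroms[ci]] - L
                if max_start >= 0:
                    start = int(rng.integers(0, max_start + 1))
                    shuffled.append(Interval(chroms[ci], start, start + L))
                    break
            else:
                raise ValueError("interval longer than every chromosome")
        expected_counts.append(_count_covered_transcripts(shuffled, transcripts))

    return {
        "observed": float(observed),
        "expected": float(np.mean(expected_counts)),
        "expected_sd": float(np.std(expected_counts, ddof=1))
        if len(expected_counts) > 1
        else 0.0,
        "n_intervals": float(len(selected)),
    }
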