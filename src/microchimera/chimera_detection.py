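"""A-U-B chimera calling and single-base junction refinement.

A read is an A-U-B chimera when its bin chromosome labels form the pattern
A+ U B+: one or more bins uniquely aligned to chromosome A, exactly one
unmapped transition bin, then one or more bins uniquely aligned to a
different chromosome B, with no multi-mapping bins and no other unmapped
bins anywhere in the read.  The junction is then refined by sliding a
bin-sized window one base at a time across the transition: the signed gap

    gap = first_B_window_start - last_A_window_start - window_size

is negative when the two chromosomal flanks share a microhomology tract
(the window footprints overlap in the read, "dually aligning"), zero for a
base-to-base juxtaposition, and positive when inserted bases align to
neither chromosome ("gapped").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from microchimera.binning_alignment import (
    BinAlignmentVector,
    BinningParams,
    ToyAligner,
    align_read_bins,
    align_sequence,
    default_max_mismatch,
    sliding_windows,
)
from microchimera.io_core import Interval, ReadRecord

NON_CHIMERIC = "non_chimeric"
AUB_CHIMERIC = "aub_chimeric"
ELIMINATED = "eliminated"
UNMAPPED = "unmapped"

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass(frozen=True)
class ReadClass:
    read_id: str
    label: str  # non_chimeric | aub_chimeric | eliminated | unmapped
    reason: str = ""


@dataclass(frozen=True)
class JunctionCall:
    """Refined junction: window starts in read coordinates plus gap metric."""

    last_a_window_start: int
    first_b_window_start: int
    gap: int
    junction_type: str  # dual | base_to_base | gapped
    homology_len: int
    genomic_a: Interval
    genomic_b: Interval


@dataclass
class ChimeraEvent:
    """One called A-U-B chimera between non-homologous chromosomes."""

    read_id: str
    chrom_a: str
    chrom_b: str
    u_bin_index: int
    u_interval_read: tuple[int, int]
    junction: Optional[JunctionCall] = None
    hemizygosity_class: str = ""

    def classify_hemizygosity(self) -> str:
        a_sex = self.chrom_a.lstrip("chr") in {"X", "Y"}
        b_sex = self.chrom_b.lstrip("chr") in {"X", "Y"}
        names = {self.chrom_a.lstrip("chr"), self.chrom_b.lstrip("chr")}
        if a_sex and b_sex:
            cls = "XY"
        elif "X" in names:
            cls = "X_autosome"
        elif "Y" in names:
            cls = "Y_autosome"
        else:
            cls = "autosome_autosome"
        self.hemizygosity_class = cls
        return cls


def _junction_type(gap: int) -> str:
    if gap < 0:
        return "dual"
    if gap == 0:
        return "base_to_base"
    return "gapped"


def classify_read(
    vector: BinAlignmentVector,
) -> tuple[ReadClass, Optional[ChimeraEvent]]:
    """Curate one bin-alignment vector into a read class.

    ``non_chimeric``: every bin unique to one and the same chromosome.
    ``aub_chimeric``: the strict A+ U B+ pattern (single transition bin).
    ``unmapped``: no bin aligns at all.
    ``eliminated``: everything else — multi bins, extra unmapped bins,
    direct A-to-B transitions without a U bin, three or more chromosomes.
    """
    statuses = vector.statuses()
    if all(s == "unmapped" for s in statuses):
        return ReadClass(vector.read_id, UNMAPPED), None

    chroms = [
        a.chrom if a.status == "unique" else a.status for a in vector.alignments
    ]
    unique_chroms = {c for c, s in zip(chroms, statuses) if s == "unique"}

    if all(s == "unique" for s in statuses) and len(unique_chroms) == 1:
        return ReadClass(vector.read_id, NON_CHIMERIC), None

    if "multi" in statuses:
        return ReadClass(vector.read_id, ELIMINATED, "multi_mapping_bin"), None

    n_unmapped = statuses.count("unmapped")
    if n_unmapped != 1:
        reason = "no_transition_bin" if n_unmapped == 0 else "multiple_unmapped_bins"
        return ReadClass(vector.read_id, ELIMINATED, reason), None

    u_idx = statuses.index("unmapped")
    if u_idx == 0 or u_idx == len(statuses) - 1:
        return ReadClass(vector.read_id, ELIMINATED, "terminal_unmapped_bin"), None

    left = {chroms[i] for i in range(u_idx)}
    right = {chroms[i] for i in range(u_idx + 1, len(chroms))}
    if len(left) != 1 or len(right) != 1 or left == right:
        return ReadClass(vector.read_id, ELIMINATED, "not_a_u_b_pattern"), None

    chrom_a, chrom_b = next(iter(left)), next(iter(right))
    u_bin = vector.alignments[u_idx].bin
    event = ChimeraEvent(
        vector.read_id,
        chrom_a,
        chrom_b,
        u_idx,
        (u_bin.read_start, u_bin.read_end),
    )
    event.classify_hemizygosity()
    return ReadClass(vector.read_id, AUB_CHIMERIC), event


def refine_breakpoint(
    read: ReadRecord,
    event: ChimeraEvent,
    aligner: ToyAligner,
    params: BinningParams,
    max_mismatch: int = 0,
) -> Optional[JunctionCall]:
    """Slide a bin-sized window one base at a time from A towards B.

    The search spans from the start of the last A bin through the end of
    the first B bin — the minimal region guaranteed to contain both
    arrowhead windows.  ``last_a`` is the largest window start uniquely
    aligned to chromosome A; ``first_b`` is the smallest start greater
    than ``last_a`` uniquely aligned to chromosome B.  Returns None when
    either side has no unique window or the two interleave
    non-monotonically (the event is then demoted to eliminated).

    Refinement windows are matched exactly by default (``max_mismatch``
    0): tolerated mismatches would let windows overhang the junction by
    a few bases and blur the gap metric.  On error-containing reads a
    nonzero tolerance trades base-exactness for robustness.
    """
    w = params.bin_size
    span_start = (event.u_bin_index - 1) * params.bin_size
    span_stop = min((event.u_bin_index + 2) * params.bin_size, read.length) - w + 1

    last_a: Optional[tuple[int, Interval]] = None
    b_hits: list[tuple[int, Interval]] = []
    for win in sliding_windows(read, w, params.window_step, span_start, span_stop):
        aln = align_sequence(win, aligner, max_mismatch)
        if aln.status != "unique":
            continue
        footprint = Interval(aln.chrom, aln.pos, aln.pos + w, strand=aln.strand)
        if aln.chrom == event.chrom_a:
            last_a = (win.read_start, footprint)
        elif aln.chrom == event.chrom_b:
            b_hits.append((win.read_start, footprint))

    if last_a is None or not b_hits:
        return None
    first_b = next((h for h in b_hits if h[0] > last_a[0]), None)
    if first_b is None:
        return None  # non-monotonic: B windows all precede the last A window

    gap = first_b[0] - last_a[0] - w
    return JunctionCall(
        last_a_window_start=last_a[0],
        first_b_window_start=first_b[0],
        gap=gap,
        junction_type=_junction_type(gap),
        homology_len=-gap if gap < 0 else 0,
        genomic_a=last_a[1],
        genomic_b=first_b[1],
    )


@dataclass
class DetectionResult:
    """Everything one detection run produces, plus conserved tallies."""

    classes: list[ReadClass] = field(default_factory=list)
    events: list[ChimeraEvent] = field(default_factory=list)
    vectors: dict[str, BinAlignmentVector] = field(default_factory=dict)
    tallies: dict[str, int] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {NON_CHIMERIC: 0, AUB_CHIMERIC: 0, ELIMINATED: 0, UNMAPPED: 0}
        for rc in self.classes:
            out[rc.label] += 1
        return out


def call_events(
    reads: Iterable[ReadRecord],
    aligner: ToyAligner,
    params: BinningParams,
    max_mismatch: Optional[int] = None,
    refine: bool = True,
    refine_max_mismatch: int = 0,
) -> DetectionResult:
    """Run the full detection pipeline over a read set.

    Reads shorter than ``min_read_len`` are skipped (counted, not
    classified).  Chimeric events failing refinement are demoted to
    eliminated.  ``total_bases`` sums the lengths of all length-passing
    reads — the denominator for events-per-billion-bases rates.
    Bin alignment tolerates ``max_mismatch`` substitutions (default 2%
    of bin size); refinement windows are matched exactly by default.
    """
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(params.bin_size)
    result = DetectionResult()
    n_short = 0
    total_bases = 0
    for read in reads:
        vec = align_read_bins(read, aligner, params, max_mismatch)
        if vec is None:
            n_short += 1
            continue
        total_bases += read.length
        result.vectors[read.read_id] = vec
        read_class, event = classify_read(vec)
        if event is not None and refine:
            junction = refine_breakpoint(
                read, event, aligner, params, refine_max_mismatch
            )
            if junction is None:
                read_class = ReadClass(read.read_id, ELIMINATED, "refinement_failed")
                event = None
            else:
                event.junction = junction
        result.classes.append(read_class)
        if event is not None:
            result.events.append(event)

    counts = result.counts()
    result.tallies = {
        **counts,
        "reads_processed": len(result.classes),
        "reads_too_short": n_short,
        "total_bases": total_bases,
    }
    return result


def events_to_rows(events: Iterable[ChimeraEvent]) -> list[dict]:
    """Flatten events for TSV output (BED-with-extras layout)."""
    rows = []
    for ev in events:
        j = ev.junction
        rows.append(
            {
                "read_id": ev.read_id,
                "chrom_a": ev.chrom_a,
                "a_start": j.genomic_a.start if j else -1,
                "a_end": j.genomic_a.end if j else -1,
                "chrom_b": ev.chrom_b,
                "b_start": j.genomic_b.start if j else -1,
                "b_end": j.genomic_b.end if j else -1,
                "gap": j.gap if j else 0,
                "junction_type": j.junction_type if j else "",
                "homology_len": j.homology_len if j else 0,
                "hemizygosity_class": ev.hemizygosity_class,
            }
        )
    return rows
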