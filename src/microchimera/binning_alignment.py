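"""Fixed-size read binning, sliding windows, and per-bin alignment.

Reads are split into non-overlapping bins (0.2 kb for long reads, 0.05 kb
for short reads); each bin is aligned independently end-to-end and labeled
``unique``, ``multi`` or ``unmapped``.  Alignments come either from the
built-in seed-and-verify aligner (small genomes) or from an ingested SAM
file produced by an external aligner.

The built-in aligner is exhaustive within its mismatch budget: a query is
cut into ``max_mismatch + 1`` disjoint segments, so any end-to-end placement
with at most ``max_mismatch`` substitutions leaves at least one segment
error-free, and the exact k-mer seed inside that segment finds it.  This
makes the unique/multi/unmapped call provably identical to brute-force
scanning of every offset on both strands.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam

from microchimera.io_core import GenomeSequence, ReadRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BinningParams:
    """Binning geometry.

    ``bin_size`` 200 / ``min_read_len`` 600 for long (ONT-style) reads;
    50 / 150 for short (IonTorrent-style) reads.  A read must supply at
    least three bins: one for each of the A, U and B segments.
    """

    bin_size: int = 200
    min_read_len: int = 600
    window_step: int = 1

    def __post_init__(self) -> None:
        if self.min_read_len < 3 * self.bin_size:
            raise ValueError(
                f"min_read_len {self.min_read_len} < 3 x bin_size {self.bin_size}"
            )

    @classmethod
    def short_read(cls) -> "BinningParams":
        return cls(bin_size=50, min_read_len=150)


@dataclass(frozen=True)
class Bin:
    """One fixed-size fragment of a read (read coordinates, half-open)."""

    read_id: str
    index: int
    read_start: int
    read_end: int
    sequence: str


@dataclass(frozen=True)
class BinAlignment:
    bin: Bin
    status: str  # unique | multi | unmapped
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 0-based genomic start, + strand coordinates
    strand: Optional[str] = None
    mismatches: Optional[int] = None


@dataclass
class BinAlignmentVector:
    """Ordered per-bin alignment labels of one read."""

    read_id: str
    alignments: list[BinAlignment] = field(default_factory=list)

    @property
    def total_bins(self) -> int:
        return len(self.alignments)

    def statuses(self) -> list[str]:
        return [a.status for a in self.alignments]


def split_read_into_bins(read: ReadRecord, params: BinningParams) -> list[Bin]:
    """Non-overlapping bins from position 0; the sub-bin-size 3' residue
    is discarded.  Returns [] for reads shorter than ``min_read_len``
    (the caller counts the skip)."""
    if read.length < params.min_read_len:
        return []
    n = read.length // params.bin_size
    return [
        Bin(
            read.read_id,
            i,
            i * params.bin_size,
            (i + 1) * params.bin_size,
            read.sequence[i * params.bin_size : (i + 1) * params.bin_size],
        )
        for i in range(n)
    ]


def sliding_windows(
    read: ReadRecord, window: int, step: int = 1, start: int = 0, stop: Optional[int] = None
) -> Iterator[Bin]:
    """Windows of size ``window`` at every ``step`` bases, single-base by
    default (EMBOSS splitter ``-size 200 -overlap 199`` geometry).

    ``start``/``stop`` restrict the window *start* positions to
    ``[start, stop)``; by default every start from 0 to len - window.
    """
    last = read.length - window
    if stop is None:
        stop = last + 1
    stop = min(stop, last + 1)
    for s in range(start, stop, step):
        yield Bin(read.read_id, s, s, s + window, read.sequence[s : s + window])


def default_max_mismatch(bin_size: int) -> int:
    """Mismatch budget of the built-in aligner: 2% of the query length."""
    return math.ceil(0.02 * bin_size)


def _encode(seq: str, query: bool) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if query:
        # query N never matches anything, including genome N
        arr[arr == ord("N")] = 1
    return arr


class ToyAligner:
    """Exhaustive end-to-end substitution-only aligner for small genomes.

    Exact k-mer seeds (default k=15) plus full verification; complete
    within ``max_mismatch`` by the pigeonhole argument (see module
    docstring).  N in the genome or query mismatches everything.
    """

    def __init__(self, genome: Iterable[GenomeSequence], seed_len: int = 15):
        self.seed_len = seed_len
        self.chroms: list[str] = []
        self._seqs: dict[str, np.ndarray] = {}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for gs in genome:
            if gs.chrom_name in self._seqs:
                raise ValueError(f"duplicate chromosome {gs.chrom_name!r}")
            self.chroms.append(gs.chrom_name)
            self._seqs[gs.chrom_name] = _encode(gs.sequence, query=False)
            seq = gs.sequence
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((gs.chrom_name, i))

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def _hits_one_strand(
        self, query: str, max_mismatch: int
    ) -> Iterator[tuple[str, int, int]]:
        qarr = _encode(query, query=True)
        qlen = len(query)
        nseg = max_mismatch + 1
        seg = qlen // nseg
        if seg < self.seed_len:
            yield from self._scan_all(qarr, max_mismatch)
            return
        seen: set[tuple[str, int]] = set()
        for si in range(nseg):
            off = si * seg
            kmer = query[off : off + self.seed_len]
            for chrom, gpos in self._index.get(kmer, ()):
                start = gpos - off
                garr = self._seqs[chrom]
                if start < 0 or start + qlen > len(garr) or (chrom, start) in seen:
                    continue
                seen.add((chrom, start))
                nm = int(np.count_nonzero(garr[start : start + qlen] != qarr))
                if nm <= max_mismatch:
                    yield chrom, start, nm

    def _scan_all(
        self, qarr: np.ndarray, max_mismatch: int
    ) -> Iterator[tuple[str, int, int]]:
        # fallback for queries too short for pigeonhole seeding
        qlen = len(qarr)
        for chrom, garr in self._seqs.items():
            if len(garr) < qlen:
                continue
            view = np.lib.stride_tricks.sliding_window_view(garr, qlen)
            nm = np.count_nonzero(view != qarr, axis=1)
            for start in np.nonzero(nm <= max_mismatch)[0]:
                yield chrom, int(start), int(nm[start])

    def find_hits(
        self, query: str, max_mismatch: int
    ) -> list[tuple[str, int, str, int]]:
        """All loci (chrom, start, strand, mismatches) within budget."""
        hits = [
            (c, p, "+", nm) for c, p, nm in self._hits_one_strand(query, max_mismatch)
        ]
        rc = reverse_complement(query)
        fwd_loci = {(c, p) for c, p, _, _ in hits}
        for c, p, nm in self._hits_one_strand(rc, max_mismatch):
            if (c, p) not in fwd_loci:  # a palindromic hit is one locus
                hits.append((c, p, "-", nm))
        return hits

    def align(self, query: str, max_mismatch: Optional[int] = None) -> BinAlignment:
        return align_sequence(query, self, max_mismatch)


def align_sequence(
    query: str | Bin,
    aligner: ToyAligner,
    max_mismatch: Optional[int] = None,
) -> BinAlignment:
    """Align one query end-to-end against the indexed genome.

    ``unique``: exactly one genomic locus within the mismatch budget;
    ``multi``: two or more; ``unmapped``: none.  Default budget is 2% of
    the query length.
    """
    if isinstance(query, Bin):
        bin_ = query
    else:
        bin_ = Bin("query", 0, 0, len(query), query)
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(len(bin_.sequence))
    hits = aligner.find_hits(bin_.sequence, max_mismatch)
    if not hits:
        return BinAlignment(bin_, "unmapped")
    if len(hits) == 1:
        chrom, pos, strand, nm = hits[0]
        return BinAlignment(bin_, "unique", chrom, pos, strand, nm)
    return BinAlignment(bin_, "multi")


def align_read_bins(
    read: ReadRecord,
    aligner: ToyAligner,
    params: BinningParams,
    max_mismatch: Optional[int] = None,
) -> Optional[BinAlignmentVector]:
    """Bin a read and align every bin; None if the read is too short."""
    bins = split_read_into_bins(read, params)
    if not bins:
        return None
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(params.bin_size)
    return BinAlignmentVector(
        read.read_id, [align_sequence(b, aligner, max_mismatch) for b in bins]
    )


_NAME_RE = re.compile(r"^(?P<read>.+)/(?P<bin>\d+)$")


def ingest_alignments(sam_path: str) -> dict[str, BinAlignmentVector]:
    """Build per-read bin-alignment vectors from an external aligner's SAM.

    Query names must encode the bin as ``read_id/bin_index``.  A bin is
    ``unique`` if it has one primary mapped record and no secondary,
    ``unmapped`` if flagged unmapped, ``multi`` otherwise.
    """
    per_bin: dict[str, dict[int, list[pysam.AlignedSegment]]] = {}
    with pysam.AlignmentFile(sam_path, check_sq=False) as sam:
        for rec in sam:
            m = _NAME_RE.match(rec.query_name or "")
            if not m:
                raise ValueError(
                    f"{sam_path}: query name {rec.query_name!r} does not follow "
                    "the read_id/bin_index convention"
                )
            per_bin.setdefault(m["read"], {}).setdefault(int(m["bin"]), []).append(rec)

    out: dict[str, BinAlignmentVector] = {}
    for read_id, bins in per_bin.items():
        vec = BinAlignmentVector(read_id)
        for idx in sorted(bins):
            recs = bins[idx]
            primary = [r for r in recs if not r.is_secondary and not r.is_supplementary]
            rec = primary[0] if primary else recs[0]
            seq = rec.query_sequence or ""
            bin_size = len(seq) if seq else (rec.query_length or 0)
            b = Bin(read_id, idx, idx * bin_size, (idx + 1) * bin_size, seq)
            if all(r.is_unmapped for r in recs):
                vec.alignments.append(BinAlignment(b, "unmapped"))
            elif len(recs) == 1 and not recs[0].is_secondary:
                r = recs[0]
                nm = r.get_tag("NM") if r.has_tag("NM") else None
                vec.alignments.append(
                    BinAlignment(
                        b,
                        "unique",
                        r.reference_name,
                        r.reference_start,
                        "-" if r.is_reverse else "+",
                        int(nm) if nm is not None else None,
                    )
                )
            else:
                vec.alignments.append(BinAlignment(b, "multi"))
        if sorted(bins) != list(range(len(bins))):
            raise ValueError(f"{sam_path}: read {read_id}: missing bin indices")
        out[read_id] = vec
    return out
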