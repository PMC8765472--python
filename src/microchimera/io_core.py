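"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  BED is native in that
convention; SAM and VCF positions are shifted at the I/O boundary only
(a variant at VCF POS ``p`` maps to internal position ``p - 1``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import pysam
from Bio import SeqIO


class FormatError(ValueError):
    """Raised for malformed input files."""


VALID_BASES = frozenset("ACGTN")


@dataclass
class GenomeSequence:
    """One reference chromosome: uppercase DNA (A/C/G/T/N)."""

    chrom_name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """A sequencing read, optionally with per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class VariantSite:
    """A bi-/multi-allelic SNV with genotypes per sample.

    ``pos`` is 0-based.  Genotypes are unordered allele tuples; a
    hemizygous call is a 1-tuple.  Indels are excluded upstream.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    genotypes_by_sample: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def alleles(self) -> set[str]:
        return {self.ref_allele, *self.alt_alleles}


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a FASTA file into a list of uppercase genome sequences.

    Record order is preserved; duplicate sequence names are an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(path: str | os.PathLike, sequences: list[GenomeSequence]) -> None:
    with open(path, "w") as fh:
        for gs in sequences:
            fh.write(f">{gs.chrom_name}\n")
            for i in range(0, gs.length, 70):
                fh.write(gs.sequence[i : i + 70] + "\n")


class FastqStats:
    """Running totals filled in while :func:`read_fastq` is consumed."""

    def __init__(self) -> None:
        self.n_reads = 0
        self.n_bases = 0


def read_fastq(
    path: str | os.PathLike, stats: Optional[FastqStats] = None
) -> Iterator[ReadRecord]:
    """Lazily yield reads from a 4-line-record FASTQ file.

    Pass a :class:`FastqStats` to collect the read/base totals used as
    rate denominators downstream.  Truncated records and quality strings
    of the wrong length raise :class:`FormatError` with the record index.
    """
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus or not qual and not seq:
                raise FormatError(f"{path}: truncated FASTQ record {idx}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"{path}: malformed FASTQ record {idx}")
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}: record {idx}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            read = ReadRecord(
                header[1:].split()[0], seq, [ord(c) - 33 for c in qual]
            )
            if stats is not None:
                stats.n_reads += 1
                stats.n_bases += read.length
            yield read
            idx += 1


def write_fastq(path: str | os.PathLike, reads: list[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = (
                "".join(chr(q + 33) for q in r.qualities)
                if r.qualities is not None
                else "I" * r.length
            )
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read BED3+ into intervals (BED is natively 0-based half-open).

    Column 4, if present, is the name; for repeat annotations it carries
    the RepeatMasker-style "class/subfamily" string.  Column 6 is strand.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(Interval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path: str | os.PathLike, intervals: list[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def _sites_from_vcf(path: str | os.PathLike) -> dict[tuple[str, int], VariantSite]:
    """Load SNV sites from one VCF; indels and missing GTs are skipped."""
    sites: dict[tuple[str, int], VariantSite] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = [a for a in (rec.alts or ())]
            if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
                continue  # indels excluded
            genotypes: dict[str, tuple[str, ...]] = {}
            ok = True
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(g is None for g in gt):
                    ok = False
                    break
                alleles = tuple(
                    sorted(rec.alleles[g] for g in gt)
                )
                genotypes[s] = alleles
            if not ok:
                continue
            sites[(rec.chrom, rec.pos - 1)] = VariantSite(
                rec.chrom, rec.pos - 1, rec.ref, alts, genotypes
            )
    return sites


def read_trio_vcf(
    offspring: str | os.PathLike,
    mother: str | os.PathLike,
    father: str | os.PathLike,
) -> list[VariantSite]:
    """Three-way intersection of trio VCFs, mirroring ``bcftools isec -n +3``.

    Only SNV sites present in all three files are returned, with the
    genotypes of the three samples merged under sample names
    ``offspring``, ``mother`` and ``father``.  Positions are internal
    0-based.
    """
    off = _sites_from_vcf(offspring)
    mom = _sites_from_vcf(mother)
    dad = _sites_from_vcf(father)
    keys = sorted(set(off) & set(mom) & set(dad))
    out: list[VariantSite] = []
    for key in keys:
        o, m, f = off[key], mom[key], dad[key]
        alts = sorted(set(o.alt_alleles) | set(m.alt_alleles) | set(f.alt_alleles))
        out.append(
            VariantSite(
                o.chrom,
                o.pos,
                o.ref_allele,
                alts,
                {
                    "offspring": next(iter(o.genotypes_by_sample.values())),
                    "mother": next(iter(m.genotypes_by_sample.values())),
                    "father": next(iter(f.genotypes_by_sample.values())),
                },
            )
        )
    return out


def write_vcf(
    path: str | os.PathLike,
    sites: list[VariantSite],
    sample: str,
    contigs: dict[str, int],
) -> None:
    """Write single-sample SNV calls as uncompressed VCF 4.2.

    ``sites`` must carry a genotype for ``sample``; internal 0-based
    positions are shifted to 1-based VCF POS on output.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            gt = site.genotypes_by_sample[sample]
            alleles = (site.ref_allele, *site.alt_alleles)
            rec = vcf.new_record(
                contig=site.chrom,
                start=site.pos,
                stop=site.pos + 1,
                alleles=alleles,
            )
            rec.samples[sample]["GT"] = tuple(alleles.index(a) for a in gt)
            vcf.write(rec)
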