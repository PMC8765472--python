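"""Interallelic (homologous-chromosome) chimera detection from trio data.

Reads are phased at trio-informative variant sites — positions where at
least one parent carries an allele absent from the other parent.  A read
whose parent-of-origin labels switch exactly once (M+P+ or P+M+) is an
interallelic chimera; reads with two or more switches, or carrying any
allele found in neither parent, are eliminated.  The raw chimera
percentage is deflated by the somatic mutation rate — the fraction of
genotype-comparable reads with a non-parental allele — via

    corrected% = raw% x (1 - mutation_rate)

Under the independence model in which a base mutates to any of the three
other bases with probability 0.75 per allele, the biallelic unexpected-
genotype probability is 0.75 x 0.75 = 0.5625 (~56%), and a hemizygous X
in a male offspring is expected to retain the maternal allele at ~25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from microchimera.io_core import VariantSite

MATERNAL = "M"
PATERNAL = "P"
AMBIGUOUS = "ambiguous"
NON_PARENTAL = "non_parental"

MODEL_P_ALLELE = 0.75
MODEL_P_BIALLELIC = 0.5625
MODEL_P_HEMIZYGOUS_EXPECTED = 0.25


@dataclass
class InformativeSite:
    """A variant site with parent-of-origin diagnostic alleles.

    ``diagnostic_alleles`` maps an allele to M or P when it occurs in
    exactly one parent's genotype; alleles shared by both parents carry
    no signal and are labelled ambiguous at read time.
    """

    site: VariantSite
    diagnostic_alleles: dict[str, str] = field(default_factory=dict)
    informative: bool = False


def select_informative_sites(
    trio_sites: Iterable[VariantSite],
) -> list[InformativeSite]:
    """Flag sites where at least one parent has at least one unique allele.

    Sites lacking a maternal or paternal genotype are skipped.
    """
    out: list[InformativeSite] = []
    for site in trio_sites:
        gt = site.genotypes_by_sample
        if "mother" not in gt or "father" not in gt:
            continue
        mom, dad = set(gt["mother"]), set(gt["father"])
        diagnostic = {a: MATERNAL for a in mom - dad}
        diagnostic.update({a: PATERNAL for a in dad - mom})
        out.append(InformativeSite(site, diagnostic, informative=bool(diagnostic)))
    return out


@dataclass
class AlleleLabeledRead:
    """Per-read parent-of-origin labels and the resulting class."""

    read_id: str
    labels: list[str] = field(default_factory=list)
    # maternal | paternal | interallelic_chimera | eliminated_multiswitch
    # | eliminated_mutated | uninformative
    read_class: str = "uninformative"
    switch_index: Optional[int] = None
    compartment: str = "autosomes"


def label_read(
    read_id: str,
    observations: Sequence[tuple[str, int, str]],
    site_index: dict[tuple[str, int], InformativeSite],
    compartment: str = "autosomes",
) -> AlleleLabeledRead:
    """Classify one read from its allele observations at trio sites.

    ``observations`` are (chrom, 0-based pos, observed allele) at sites
    covered by the read.  Any allele absent from both parents eliminates
    the read as mutated; otherwise the M/P label sequence (ambiguous
    labels skipped) decides: zero transitions -> maternal/paternal, one
    -> interallelic chimera (``switch_index`` = index in ``labels`` of
    the first post-switch site), two or more -> eliminated multiswitch.
    """
    labels: list[str] = []
    for chrom, pos, allele in observations:
        info = site_index.get((chrom, pos))
        if info is None:
            continue
        gt = info.site.genotypes_by_sample
        parental = set(gt["mother"]) | set(gt["father"])
        if allele not in parental:
            labels.append(NON_PARENTAL)
        elif allele in info.diagnostic_alleles:
            labels.append(info.diagnostic_alleles[allele])
        else:
            labels.append(AMBIGUOUS)

    read = AlleleLabeledRead(read_id, labels, compartment=compartment)
    if NON_PARENTAL in labels:
        read.read_class = "eliminated_mutated"
        return read
    mp = [(i, l) for i, l in enumerate(labels) if l in (MATERNAL, PATERNAL)]
    if not mp:
        read.read_class = "uninformative"
        return read
    transitions = [
        mp[k + 1] for k in range(len(mp) - 1) if mp[k][1] != mp[k + 1][1]
    ]
    if len(transitions) == 0:
        read.read_class = "maternal" if mp[0][1] == MATERNAL else "paternal"
    elif len(transitions) == 1:
        read.read_class = "interallelic_chimera"
        read.switch_index = transitions[0][0]
    else:
        read.read_class = "eliminated_multiswitch"
    return read


def label_reads(
    observations_by_read: dict[str, Sequence[tuple[str, int, str]]],
    informative_sites: Sequence[InformativeSite],
    compartment: str = "autosomes",
) -> list[AlleleLabeledRead]:
    index = {
        (s.site.chrom, s.site.pos): s for s in informative_sites
    }
    return [
        label_read(rid, obs, index, compartment)
        for rid, obs in observations_by_read.items()
    ]


@dataclass
class MutationRateEstimate:
    """Per-read somatic mutation / sequencing-error rate.

    A read with at least one non-parental allele counts once among the
    reads at which genotypes could be compared at all.  The model
    constants are attached for reporting alongside the observed rate.
    """

    reads_compared: int
    reads_unexpected: int
    model_p_allele: float = MODEL_P_ALLELE
    model_p_biallelic: float = MODEL_P_BIALLELIC
    model_p_hemizygous_expected: float = MODEL_P_HEMIZYGOUS_EXPECTED

    @property
    def rate(self) -> float:
        return self.reads_unexpected / self.reads_compared


def estimate_mutation_rate(
    labeled_reads: Sequence[AlleleLabeledRead],
) -> MutationRateEstimate:
    """Fraction of genotype-comparable reads carrying a non-parental allele."""
    compared = [r for r in labeled_reads if r.labels]
    if not compared:
        raise ValueError("no reads with comparable genotypes")
    unexpected = sum(1 for r in compared if r.read_class == "eliminated_mutated")
    return MutationRateEstimate(len(compared), unexpected)


@dataclass
class RecombinationFrequency:
    """Raw and mutation-corrected interallelic chimera percentages."""

    raw_percent: float
    corrected_percent: float
    compartment: str
    n_maternal: int
    n_paternal: int
    n_chimera: int

    @property
    def total_classifiable(self) -> int:
        return self.n_maternal + self.n_paternal + self.n_chimera


def recombination_frequency_from_counts(
    n_maternal: int,
    n_paternal: int,
    n_chimera: int,
    mutation_rate: float,
    compartment: str = "autosomes",
) -> RecombinationFrequency:
    total = n_maternal + n_paternal + n_chimera
    if total <= 0:
        raise ValueError("no classifiable reads")
    raw = n_chimera / total * 100
    return RecombinationFrequency(
        raw_percent=raw,
        corrected_percent=raw * (1 - mutation_rate),
        compartment=compartment,
        n_maternal=n_maternal,
        n_paternal=n_paternal,
        n_chimera=n_chimera,
    )


def recombination_frequency(
    labeled_reads: Sequence[AlleleLabeledRead],
    mutation_rate: float,
    compartment: str = "autosomes",
) -> RecombinationFrequency:
    """Interallelic chimera frequency among classifiable reads.

    raw% = chimera / (maternal + paternal + chimera) x 100;
    corrected% = raw% x (1 - mutation_rate).
    """
    pool = [r for r in labeled_reads if r.compartment == compartment]
    counts = {"maternal": 0, "paternal": 0, "interallelic_chimera": 0}
    for r in pool:
        if r.read_class in counts:
            counts[r.read_class] += 1
    return recombination_frequency_from_counts(
        counts["maternal"],
        counts["paternal"],
        counts["interallelic_chimera"],
        mutation_rate,
        compartment,
    )


def classification_counts(
    labeled_reads: Sequence[AlleleLabeledRead],
) -> dict[str, int]:
    out = {
        "maternal": 0,
        "paternal": 0,
        "interallelic_chimera": 0,
        "eliminated_multiswitch": 0,
        "eliminated_mutated": 0,
        "uninformative": 0,
    }
    for r in labeled_reads:
        out[r.read_class] += 1
    return out


def hemizygous_check(
    maternal_alleles: Sequence[str], observed_alleles: Sequence[str]
) -> float:
    """Fraction of hemizygous-X genotype observations matching the
    maternal allele (expected ~0.25 under the 0.75-per-allele model)."""
    if not maternal_alleles:
        raise ValueError("no X-chromosome observations")
    if len(maternal_alleles) != len(observed_alleles):
        raise ValueError("allele lists differ in length")
    match = sum(1 for m, o in zip(maternal_alleles, observed_alleles) if m == o)
    return match / len(maternal_alleles)
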