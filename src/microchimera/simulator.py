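"""Seeded synthetic data: genomes with planted repeats, reads with
implanted chimeric junctions, and trio genotypes with allelic switches.

Every generator is deterministic for a given seed and emits a
machine-readable truth record per read, so detection recall, junction
accuracy and switch/mutation-rate recovery can be scored exactly.

The defaults emulate the study conditions at toy scale: a few 50 kb
chromosomes standing in for hg38, Alu-like (~300 bp) and L1-like (~1 kb)
repeat families, long ~1-2 kb reads binned at 0.2 kb (or ~0.2 kb reads
binned at 0.05 kb), dual-junction homology tracts of 20-60 bases, and a
1% substitution error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from microchimera.io_core import GenomeSequence, Interval, ReadRecord, VariantSite

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LIST = ["A", "C", "G", "T"]


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Genome


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One interspersed repeat family to plant: ``copies`` copies of a
    ``unit_len``-base consensus, each independently diverged by a per-base
    substitution fraction (0 = identical copies, the multi-mapping stress
    case)."""

    name: str
    unit_len: int
    copies: int
    divergence: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")


@dataclass
class SimGenomeConfig:
    n_chromosomes: int = 3
    chrom_lengths: Sequence[int] = (50_000, 50_000, 50_000)
    repeat_plan: Sequence[RepeatFamilySpec] = ()
    seed: int = 0
    bin_size: int = 200  # only used to validate that chromosomes are usable

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must have n_chromosomes entries")
        for length in self.chrom_lengths:
            if length < 10 * self.bin_size:
                raise ValueError(
                    f"chromosome length {length} < 10 x bin_size {self.bin_size}"
                )


def make_genome(
    config: SimGenomeConfig,
) -> tuple[list[GenomeSequence], list[Interval]]:
    """Generate a random genome with non-overlapping planted repeat copies.

    Returns the chromosomes and a repeat BED-style interval list whose
    names carry the RepeatMasker-style family string.  Deterministic for
    a seed: identical config -> byte-identical FASTA/BED.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    arrays = {
        name: _random_dna(rng, length)
        for name, length in zip(chrom_names, config.chrom_lengths)
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_names}
    repeats: list[Interval] = []
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()

    for fam in config.repeat_plan:
        consensus = _random_dna(rng, fam.unit_len)
        for _ in range(fam.copies):
            placed = False
            for _attempt in range(200):
                ci = int(rng.choice(config.n_chromosomes, p=probs))
                chrom = chrom_names[ci]
                max_start = config.chrom_lengths[ci] - fam.unit_len
                if max_start <= 0:
                    continue
                start = int(rng.integers(0, max_start))
                end = start + fam.unit_len
                if any(s < end and start < e for s, e in occupied[chrom]):
                    continue
                copy = consensus.copy()
                if fam.divergence > 0:
                    mask = rng.random(fam.unit_len) < fam.divergence
                    # substitute with a uniformly chosen *different* base
                    shift = rng.integers(1, 4, size=int(mask.sum()))
                    idx = np.searchsorted(BASES, copy[mask])
                    copy[mask] = BASES[(idx + shift) % 4]
                arrays[chrom][start:end] = copy
                occupied[chrom].append((start, end))
                repeats.append(Interval(chrom, start, end, fam.name))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place all {fam.copies} copies of {fam.name}: "
                    "repeats exceed chromosome capacity"
                )

    genome = [GenomeSequence(n, _arr_to_str(arrays[n])) for n in chrom_names]
    repeats.sort(key=lambda iv: (iv.chrom, iv.start))
    return genome, repeats


# ---------------------------------------------------------------------------
# Chimeric implants


@dataclass
class ChimeraImplant:
    """A planned inter-chromosomal junction to implant into one read.

    ``pos_a``/``pos_b`` are the breakpoints on the donor chromosomes (the
    read leaves A just before ``pos_a`` and continues on B at ``pos_b``).
    Dual junctions share a ``homology_len`` tract (default range 20-60 in
    the generators); gapped junctions carry ``insert_len`` random bases
    aligned to neither donor.
    """

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    junction_type: str  # dual | base_to_base | gapped
    homology_len: int = 0
    insert_len: int = 0
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.junction_type not in ("dual", "base_to_base", "gapped"):
            raise ValueError(f"unknown junction_type {self.junction_type!r}")
        if (self.homology_len > 0) != (self.junction_type == "dual"):
            raise ValueError("homology_len > 0 iff junction_type is dual")
        if (self.insert_len > 0) != (self.junction_type == "gapped"):
            raise ValueError("insert_len > 0 iff junction_type is gapped")
        if self.chrom_a == self.chrom_b:
            raise ValueError("non-homologous implants need chrom_a != chrom_b")

    @property
    def truth_gap(self) -> int:
        if self.junction_type == "dual":
            return -self.homology_len
        if self.junction_type == "gapped":
            return self.insert_len
        return 0


@dataclass
class TruthRecord:
    read_id: str
    label: str  # non_chimeric | aub_chimeric | allelic_switch | mutated | eliminated_expected
    implant: Optional[ChimeraImplant] = None
    switch_site_index: Optional[int] = None


def implant_chimeric_reads(
    genome: list[GenomeSequence],
    implants: Sequence[ChimeraImplant],
    read_len: int,
    flank_min: Optional[int] = None,
    bin_size: int = 200,
    seed: int = 0,
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Build one chimeric read per implant; truth gap = -homology / 0 / +insert.

    The junction is placed mid-bin so the transition bin is genuinely
    unalignable.  For dual junctions the homology tract is planted into
    the genome itself (the A-side suffix is copied over the B-side bases
    upstream of ``pos_b``), because a negative gap is only recoverable
    when the two donor loci really share the tract.  **Mutates** the
    passed genome sequences; implant before simulating background reads
    so that both are drawn from the same final genome.
    """
    if flank_min is None:
        flank_min = 2 * bin_size
    rng = np.random.default_rng(seed)
    by_name = {g.chrom_name: g for g in genome}
    # junction read coordinate: centre of the middle bin
    a_len = (read_len // (2 * bin_size)) * bin_size + bin_size // 2

    reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []
    for k, imp in enumerate(implants):
        insert = imp.insert_len if imp.junction_type == "gapped" else 0
        b_len = read_len - a_len - insert
        if a_len < flank_min or b_len < flank_min:
            raise ValueError(
                f"implant {k}: flanks {a_len}/{b_len} shorter than "
                f"flank_min {flank_min} (undetectable by design)"
            )
        ga, gb = by_name[imp.chrom_a], by_name[imp.chrom_b]
        if imp.pos_a < a_len or imp.pos_b + b_len > gb.length:
            raise ValueError(f"implant {k}: breakpoint too close to a chromosome end")

        def _different_base(*avoid: str) -> str:
            pool = [b for b in "ACGT" if b not in avoid]
            return pool[int(rng.integers(0, len(pool)))]

        def _set_base(gs: GenomeSequence, pos: int, base: str) -> None:
            gs.sequence = gs.sequence[:pos] + base + gs.sequence[pos + 1 :]

        h = imp.homology_len
        if imp.junction_type == "dual":
            if imp.pos_b < h + 1:
                raise ValueError(f"implant {k}: pos_b < homology_len + 1")
            tract = ga.sequence[imp.pos_a - h : imp.pos_a]
            gb.sequence = (
                gb.sequence[: imp.pos_b - h] + tract + gb.sequence[imp.pos_b :]
            )
        # Cap the junction so chance agreement with the donor continuations
        # cannot extend the effective homology: the truth gap must be the
        # exact gap any base-resolved refinement recovers.
        if imp.junction_type in ("dual", "base_to_base"):
            if gb.sequence[imp.pos_b] == ga.sequence[imp.pos_a]:
                _set_base(gb, imp.pos_b, _different_base(ga.sequence[imp.pos_a]))
            if gb.sequence[imp.pos_b - h - 1] == ga.sequence[imp.pos_a - h - 1]:
                _set_base(
                    gb, imp.pos_b - h - 1, _different_base(ga.sequence[imp.pos_a - h - 1])
                )
        a_part = ga.sequence[imp.pos_a - a_len : imp.pos_a]
        b_part = gb.sequence[imp.pos_b : imp.pos_b + b_len]
        if insert:
            mid = list(_arr_to_str(_random_dna(rng, insert)))
            avoid_first = [ga.sequence[imp.pos_a]]
            avoid_last = [gb.sequence[imp.pos_b - 1]]
            if insert == 1:
                avoid_first = avoid_last = avoid_first + avoid_last
            if mid[0] in avoid_first:
                mid[0] = _different_base(*avoid_first)
            if mid[-1] in avoid_last:
                mid[-1] = _different_base(*avoid_last)
            middle = "".join(mid)
        else:
            middle = ""
        read_id = imp.read_id or f"implant_{k}"
        imp.read_id = read_id
        reads.append(ReadRecord(read_id, a_part + middle + b_part))
        truths.append(TruthRecord(read_id, "aub_chimeric", implant=imp))
    return reads, truths


def random_implants(
    genome: list[GenomeSequence],
    n_per_type: int,
    read_len: int,
    seed: int,
    homology_range: tuple[int, int] = (20, 60),
    insert_range: tuple[int, int] = (10, 40),
    bin_size: int = 200,
) -> list[ChimeraImplant]:
    """Draw implants of all three junction types at random clean positions."""
    rng = np.random.default_rng(seed)
    a_len = (read_len // (2 * bin_size)) * bin_size + bin_size // 2
    names = [g.chrom_name for g in genome]
    lens = {g.chrom_name: g.length for g in genome}
    implants: list[ChimeraImplant] = []
    # reserve donor regions so one implant's genome edits (homology tract,
    # junction caps) cannot fall inside another implant's flanks
    reserved: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def _reserve(chrom: str, pos: int) -> bool:
        margin = read_len // 2 + 200  # covers the longest flank plus caps
        lo, hi = pos - margin, pos + margin
        if any(s < hi and lo < e for s, e in reserved[chrom]):
            return False
        reserved[chrom].append((lo, hi))
        return True

    types = ["dual", "base_to_base", "gapped"] * n_per_type
    for k, jt in enumerate(types):
        h = int(rng.integers(*homology_range)) if jt == "dual" else 0
        ins = int(rng.integers(*insert_range)) if jt == "gapped" else 0
        for _attempt in range(200):
            ca, cb = rng.choice(len(names), size=2, replace=False)
            ca, cb = names[int(ca)], names[int(cb)]
            pos_a = int(rng.integers(a_len + 1, lens[ca] - read_len))
            pos_b = int(rng.integers(max(h, 1) + 1, lens[cb] - read_len))
            if _reserve(ca, pos_a):
                if _reserve(cb, pos_b):
                    break
                reserved[ca].pop()
        else:
            raise ValueError("could not place implants without overlap")
        implants.append(
            ChimeraImplant(ca, pos_a, cb, pos_b, jt, h, ins, f"implant_{k}_{jt}")
        )
    return implants


# ---------------------------------------------------------------------------
# Background reads


def simulate_reads(
    genome: list[GenomeSequence],
    n_reads: int,
    read_len: int = 1000,
    length_sigma: float = 0.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Uniformly placed single-chromosome reads from either strand.

    ``length_sigma`` > 0 draws lognormal lengths around ``read_len``
    (ONT-like spread); 0 gives fixed lengths.  Errors are i.i.d. base
    substitutions at ``error_rate``.  Deterministic per seed; placement
    and error noise use independent streams, so the same seed yields the
    same fragment placements at any error rate.
    """
    ss_place, ss_err = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss_place)
    rng_err = np.random.default_rng(ss_err)
    lengths = np.asarray([g.length for g in genome], dtype=float)
    probs = lengths / lengths.sum()
    arrays = {
        g.chrom_name: np.frombuffer(g.sequence.encode(), dtype=np.uint8)
        for g in genome
    }
    names = [g.chrom_name for g in genome]
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b

    reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []
    for i in range(n_reads):
        if length_sigma > 0:
            length = int(rng.lognormal(np.log(read_len), length_sigma))
            length = max(length, 1)
        else:
            length = read_len
        ci = int(rng.choice(len(names), p=probs))
        chrom = names[ci]
        arr = arrays[chrom]
        length = min(length, len(arr))
        start = int(rng.integers(0, len(arr) - length + 1))
        frag = arr[start : start + length].copy()
        if rng.random() < 0.5:
            frag = comp[frag[::-1]]
        if error_rate > 0:
            mask = rng_err.random(length) < error_rate
            n_err = int(mask.sum())
            if n_err:
                idx = np.searchsorted(BASES, frag[mask])
                frag[mask] = BASES[(idx + rng_err.integers(1, 4, size=n_err)) % 4]
        rid = f"bg_{i}"
        reads.append(ReadRecord(rid, _arr_to_str(frag)))
        truths.append(TruthRecord(rid, "non_chimeric"))
    return reads, truths


# ---------------------------------------------------------------------------
# Trio simulation


@dataclass
class TrioSimConfig:
    """Trio genotype/read generator settings.

    ``switch_rate_s``: fraction of offspring reads carrying exactly one
    mid-read maternal/paternal haplotype switch (the interallelic-chimera
    truth).  ``mutation_rate_m``: fraction carrying one non-parental
    allele (the somatic-mutation/sequencing-error truth).  The two
    classes are disjoint, so truth labels are unambiguous.
    """

    het_site_density: float = 5.0  # sites per kb
    informative_fraction: float = 0.8
    # fraction of informative sites using a het/hom parent pattern, where
    # only one allele is diagnostic and the shared allele labels as
    # ambiguous; 0 keeps every informative site fully diagnostic so the
    # switch-rate truth is exactly recoverable
    het_pattern_fraction: float = 0.0
    switch_rate_s: float = 0.05
    mutation_rate_m: float = 0.2
    read_length: int = 300
    n_reads: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.switch_rate_s <= 1 and 0 <= self.mutation_rate_m <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.switch_rate_s + self.mutation_rate_m > 1:
            raise ValueError("s + m must be <= 1 for unambiguous truth labels")


@dataclass
class TrioSimResult:
    sites: list[VariantSite]  # genotypes for offspring / mother / father
    reads: list[ReadRecord]
    observations: dict[str, list[tuple[str, int, str]]]  # read -> (chrom,pos,allele)
    truths: list[TruthRecord]


_INFORMATIVE_PATTERNS = [
    # (mother genotype, father genotype) as (ref?, alt?) templates
    lambda r, a: ((r, r), (a, a)),  # both alleles diagnostic
    lambda r, a: ((a, a), (r, r)),
    lambda r, a: ((r, a), (r, r)),  # alt diagnostic maternal, ref ambiguous
    lambda r, a: ((r, r), (r, a)),  # alt diagnostic paternal
]


def simulate_trio(
    genome: list[GenomeSequence], config: TrioSimConfig
) -> TrioSimResult:
    """Simulate trio genotypes and offspring reads with truth labels.

    Parents receive genotypes at SNV sites along the genome; a
    configurable fraction of sites are informative (one parent owns a
    unique allele).  Each offspring read samples one parental haplotype;
    a fraction ``s`` switches haplotype exactly once between two adjacent
    covered informative sites, and a disjoint fraction ``m`` carries one
    allele found in neither parent.
    """
    rng = np.random.default_rng(config.seed)
    sites: list[VariantSite] = []
    transmitted: list[tuple[str, str]] = []  # (maternal, paternal) allele per site
    informative_flags: list[bool] = []

    for g in genome:
        n_sites = int(round(config.het_site_density * g.length / 1000))
        positions = np.sort(
            rng.choice(g.length, size=min(n_sites, g.length), replace=False)
        )
        for pos in positions:
            ref = g.sequence[pos]
            if ref == "N":
                continue
            alt = _BASE_LIST[
                (_BASE_LIST.index(ref) + int(rng.integers(1, 4))) % 4
            ]
            informative = bool(rng.random() < config.informative_fraction)
            if informative:
                if rng.random() < config.het_pattern_fraction:
                    pattern = _INFORMATIVE_PATTERNS[2 + int(rng.integers(0, 2))]
                else:
                    pattern = _INFORMATIVE_PATTERNS[int(rng.integers(0, 2))]
                mom, dad = pattern(ref, alt)
            else:
                mom = dad = (ref, alt)  # both parents het: no unique allele
            mat = mom[int(rng.integers(0, 2))]
            pat = dad[int(rng.integers(0, 2))]
            sites.append(
                VariantSite(
                    g.chrom_name,
                    int(pos),
                    ref,
                    [alt],
                    {
                        "mother": tuple(sorted(mom)),
                        "father": tuple(sorted(dad)),
                        "offspring": tuple(sorted((mat, pat))),
                    },
                )
            )
            transmitted.append((mat, pat))
            informative_flags.append(informative)

    if not any(informative_flags):
        raise ValueError("simulated trio has zero informative sites")

    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    site_pos = {c: np.asarray([sites[i].pos for i in idx]) for c, idx in by_chrom.items()}

    arrays = {
        g.chrom_name: np.frombuffer(g.sequence.encode(), dtype=np.uint8)
        for g in genome
    }
    lengths = np.asarray([g.length for g in genome], dtype=float)
    probs = lengths / lengths.sum()
    names = [g.chrom_name for g in genome]

    reads: list[ReadRecord] = []
    observations: dict[str, list[tuple[str, int, str]]] = {}
    truths: list[TruthRecord] = []

    def parental_alleles(i: int) -> set[str]:
        gt = sites[i].genotypes_by_sample
        return set(gt["mother"]) | set(gt["father"])

    for r in range(config.n_reads):
        u = rng.random()
        want_switch = u < config.switch_rate_s
        want_mut = (not want_switch) and u < config.switch_rate_s + config.mutation_rate_m
        # resample placement until the read covers enough informative sites
        for _ in range(500):
            ci = int(rng.choice(len(names), p=probs))
            chrom = names[ci]
            arr = arrays[chrom]
            if len(arr) < config.read_length:
                continue
            start = int(rng.integers(0, len(arr) - config.read_length + 1))
            pos_arr = site_pos.get(chrom)
            if pos_arr is None:
                continue
            lo = int(np.searchsorted(pos_arr, start))
            hi = int(np.searchsorted(pos_arr, start + config.read_length))
            covered = [by_chrom[chrom][j] for j in range(lo, hi)]
            covered_inf = [i for i in covered if informative_flags[i]]
            need = 2 if want_switch else 1
            if len(covered_inf) >= need:
                break
        else:
            raise ValueError(
                "could not place a read over enough informative sites; "
                "increase het_site_density"
            )

        rid = f"trio_{r}"
        hap = int(rng.integers(0, 2))  # 0 = maternal, 1 = paternal
        hap_of_site = {i: hap for i in covered}
        switch_index: Optional[int] = None
        if want_switch:
            b = int(rng.integers(0, len(covered_inf) - 1))
            boundary_site = covered_inf[b + 1]
            for i in covered:
                if i >= boundary_site:
                    hap_of_site[i] = 1 - hap
            switch_index = boundary_site

        obs: list[tuple[str, int, str]] = []
        alleles_at = {}
        for i in covered:
            allele = transmitted[i][hap_of_site[i]]
            alleles_at[i] = allele
        if want_mut:
            target = covered[int(rng.integers(0, len(covered)))]
            pool = [b for b in _BASE_LIST if b not in parental_alleles(target)]
            if not pool:
                pool = [b for b in _BASE_LIST if b != alleles_at[target]]
            alleles_at[target] = pool[int(rng.integers(0, len(pool)))]
        for i in covered:
            obs.append((sites[i].chrom, sites[i].pos, alleles_at[i]))

        frag = arr[start : start + config.read_length].copy()
        for i in covered:
            frag[sites[i].pos - start] = ord(alleles_at[i])
        reads.append(ReadRecord(rid, _arr_to_str(frag)))
        observations[rid] = obs
        label = (
            "allelic_switch" if want_switch else "mutated" if want_mut else "non_chimeric"
        )
        truths.append(TruthRecord(rid, label, switch_site_index=switch_index))

    return TrioSimResult(sites, reads, observations, truths)


def simulate_hemizygous_observations(
    n_observations: int, mutation_prob: float, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Hemizygous-X genotype observations from a male offspring.

    Each observation is the maternal allele with probability
    ``1 - mutation_prob``, otherwise one of the three other bases.
    Returns (maternal alleles, observed alleles) per observation.
    """
    rng = np.random.default_rng(seed)
    maternal = [_BASE_LIST[int(i)] for i in rng.integers(0, 4, size=n_observations)]
    observed = []
    for a in maternal:
        if rng.random() < mutation_prob:
            others = [b for b in _BASE_LIST if b != a]
            observed.append(others[int(rng.integers(0, 3))])
        else:
            observed.append(a)
    return maternal, observed
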