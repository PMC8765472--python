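"""Shared fixtures: one seeded end-to-end detection run and one trio run,
built once per session and reused by the unit and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from microchimera import simulator
from microchimera.allelic_phasing import (
    AlleleLabeledRead,
    label_reads,
    select_informative_sites,
)
from microchimera.binning_alignment import BinningParams, ToyAligner
from microchimera.chimera_detection import DetectionResult, call_events
from microchimera.io_core import GenomeSequence, Interval
from microchimera.simulator import TruthRecord


@dataclass
class DetectionRun:
    genome: list[GenomeSequence]
    repeats: list[Interval]
    aligner: ToyAligner
    params: BinningParams
    reads: list
    chimera_truth: list[TruthRecord]
    background_truth: list[TruthRecord]
    result: DetectionResult

    @property
    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.read_id: t for t in self.chimera_truth}


def build_detection_run(seed: int = 0, n_per_type: int = 17, n_background: int = 200):
    """Error-free pipeline run: 4 x 80 kb genome with planted Alu-like and
    L1-like repeats, 3 x n_per_type implanted junctions, uniform background."""
    config = simulator.SimGenomeConfig(
        n_chromosomes=4,
        chrom_lengths=[80_000] * 4,
        repeat_plan=(
            simulator.RepeatFamilySpec("SINE/AluSim", 300, 12, 0.08),
            simulator.RepeatFamilySpec("LINE/L1Sim", 1000, 6, 0.10),
        ),
        seed=seed,
    )
    genome, repeats = simulator.make_genome(config)
    implants = simulator.random_implants(genome, n_per_type, 1000, seed=seed + 100)
    chim_reads, chim_truth = simulator.implant_chimeric_reads(
        genome, implants, 1000, seed=seed + 200
    )
    bg_reads, bg_truth = simulator.simulate_reads(
        genome, n_background, 1000, error_rate=0.0, seed=seed + 300
    )
    aligner = ToyAligner(genome)
    params = BinningParams()
    reads = chim_reads + bg_reads
    result = call_events(reads, aligner, params)
    return DetectionRun(
        genome, repeats, aligner, params, reads, chim_truth, bg_truth, result
    )


@pytest.fixture(scope="session")
def detection_run() -> DetectionRun:
    return build_detection_run(seed=0)


@dataclass
class TrioRun:
    config: simulator.TrioSimConfig
    sim: simulator.TrioSimResult
    labeled: list[AlleleLabeledRead]


def build_trio_run(
    seed: int = 0,
    n_reads: int = 20_000,
    switch_rate: float = 0.04,
    mutation_rate: float = 0.50,
) -> TrioRun:
    genome, _ = simulator.make_genome(
        simulator.SimGenomeConfig(n_chromosomes=2, chrom_lengths=[60_000] * 2, seed=seed)
    )
    config = simulator.TrioSimConfig(
        het_site_density=20,
        switch_rate_s=switch_rate,
        mutation_rate_m=mutation_rate,
        read_length=300,
        n_reads=n_reads,
        seed=seed + 1,
    )
    sim = simulator.simulate_trio(genome, config)
    informative = select_informative_sites(sim.sites)
    labeled = label_reads(sim.observations, informative)
    return TrioRun(config, sim, labeled)


@pytest.fixture(scope="session")
def trio_run() -> TrioRun:
    return build_trio_run(seed=7)
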