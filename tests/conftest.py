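import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the `oracles` helper module

from strcall.core import ReadAlignment, ReferenceGenome
from strcall.simulator import (
    SimulationConfig,
    preset_indel_jitter,
    preset_genotype_recovery,
    preset_population_f1,
    preset_population_f6,
    simulate_dataset,
    simulate_population,
    simulate_reference,
)


def make_read(start, cigar, bases, seq_name="chr1", quals=30, name="r1", sample="s"):
    """Small helper constructing a validated alignment."""
    q = [quals] * len(bases) if isinstance(quals, int) else list(quals)
    aln = ReadAlignment(name, seq_name, start, list(cigar), bases, q, 60, sample)
    aln.validate()
    return aln


@pytest.fixture(scope="session")
def tiny_genome():
    return ReferenceGenome({"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGT" * 10})


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded end-to-end dataset: genome, STRs, truth, reads."""
    cfg = SimulationConfig(
        seed=11, genome_length=60_000, str_variant_probability=1.0,
        snv_rate=5e-4, indel_rate=3e-4, depth=30,
    )
    genome, strs, truth, reads, read_errors = simulate_dataset(cfg)
    return {"config": cfg, "genome": genome, "strs": strs, "truth": truth,
            "reads": reads, "read_errors": read_errors}


@pytest.fixture(scope="session")
def jitter_dataset():
    """The realignment-consistency scenario: STR indels with jittered anchors."""
    cfg = preset_indel_jitter(seed=1)
    genome, strs, truth, reads, _ = simulate_dataset(cfg)
    return {"config": cfg, "genome": genome, "strs": strs, "truth": truth, "reads": reads}


@pytest.fixture(scope="session")
def recovery_dataset():
    """The genotype-recovery scenario: matched SNV/indel/STR site counts."""
    cfg = preset_genotype_recovery(seed=1)
    genome, strs, truth, reads, _ = simulate_dataset(cfg)
    return {"config": cfg, "genome": genome, "strs": strs, "truth": truth, "reads": reads}


def _population(preset, seed):
    cfg = preset(seed)
    genome, _ = simulate_reference(cfg, cfg.rng())
    records, samples, ledger = simulate_population(genome, cfg)
    return {"config": cfg, "genome": genome, "records": records,
            "samples": samples, "ledger": ledger}


@pytest.fixture(scope="session")
def population_f1():
    return _population(preset_population_f1, seed=1)


@pytest.fixture(scope="session")
def population_f6():
    return _population(preset_population_f6, seed=1)
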