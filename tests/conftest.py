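"""Shared fixtures: small hand-built assemblies and one full synthetic run.

The expensive fixtures (simulated genomes, full pipeline runs) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ploidbin.fragmentation import chunk_assembly
from ploidbin.io import AssemblyRecord
from ploidbin.pipeline import PipelineConfig, run_kmer_pipeline
from ploidbin.simulate import default_scenarios, simulate
from ploidbin.validation import fragment_truth_labels


@pytest.fixture
def tiny_assembly() -> list[AssemblyRecord]:
    return [
        AssemblyRecord("s1", "ACGTACGTACGTACGTACGT"),
        AssemblyRecord("s2", "TTTTTTTTTTGGGGGGGGGG"),
    ]


@pytest.fixture(scope="session")
def tobacco_sim():
    return simulate(default_scenarios()["tobacco_like"])


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    # study conditions for the synthetic tetraploid: 21-mers at genome
    # frequency >= 10, 10 kb fragments
    return PipelineConfig(k=21, min_count=10, fragment_length=10_000,
                          min_length=2_500, n_subgenomes=2, seed=42)


@pytest.fixture(scope="session")
def tobacco_run(tobacco_sim, pipeline_config):
    return run_kmer_pipeline(tobacco_sim.assembly, pipeline_config)


@pytest.fixture(scope="session")
def tobacco_truth(tobacco_sim, tobacco_run) -> np.ndarray:
    return fragment_truth_labels(tobacco_run.fragments, tobacco_sim.truth)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
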