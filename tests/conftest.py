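import dataclasses

import numpy as np
import pytest

from editscan.synthetic_data import (
    ArtifactPlan,
    FixtureSpec,
    simulate_genome_with_paralogs,
    simulate_reads_with_artifacts,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def build_fixture(spec: FixtureSpec):
    """Generate genome + reads + candidate variants + truth for a spec."""
    rng = np.random.default_rng(spec.seed)
    genome, annotation, layout = simulate_genome_with_paralogs(
        spec.genome, rng, junction_overhang=spec.artifacts.junction_overhang)
    reads, variants, truth = simulate_reads_with_artifacts(
        genome, annotation, layout, spec, rng)
    return genome, annotation, layout, reads, variants, truth


@pytest.fixture(scope="session")
def artifact_fixture():
    """Seeded fixture with true editing plus all three artifact classes."""
    spec = FixtureSpec(seed=1)
    return spec, build_fixture(spec)


@pytest.fixture(scope="session")
def clean_fixture():
    """No artifacts, error-free reads: every variant is true editing."""
    spec = FixtureSpec(
        seed=2,
        artifacts=ArtifactPlan(n_paralog=0, n_junction=0, n_indel=0))
    return spec, build_fixture(spec)
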