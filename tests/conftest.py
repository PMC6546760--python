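import numpy as np
import pytest

from ribosnitch.fixtures import (
    FixtureSpec,
    make_genome_and_annotation,
    make_mutation_cohort,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small generated genome + annotation + cohorts, shared per session."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(seed=5)
    fasta, gtf = make_genome_and_annotation(spec, out)
    somatic, germline = make_mutation_cohort(fasta, gtf, spec, out)
    return {
        "spec": spec,
        "fasta": fasta,
        "gtf": gtf,
        "somatic": somatic,
        "germline": germline,
        "dir": out,
    }


@pytest.fixture(scope="session")
def toy_genome():
    """Plain dict genome for coordinate-level unit tests."""
    return {
        "chr1": "ACGTGGAAGTGGACGTTGGATTTTGGGCCCAAATTTGGGCCCAAA",
        "chr2": "AAGTGGCCTTAAGGCCTTAA",
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
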