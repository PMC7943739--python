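import pytest

import ighvrare as iv
from ighvrare.cohorts import haplotyping_cohort


@pytest.fixture(scope="session")
def db():
    return iv.example_locus()


@pytest.fixture(scope="session")
def nonoise_subject(db):
    """One noise-free simulated subject with its annotation (shared)."""
    specs, truth = haplotyping_cohort(seed=11, n_subjects=1, n_reads=2000)
    reads, log = iv.simulate_repertoire(specs[0], db)
    ann = iv.annotate_sequences(
        [r.read_id for r in reads], [r.sequence for r in reads], db)
    return specs[0], reads, ann, truth[specs[0].subject_id]
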