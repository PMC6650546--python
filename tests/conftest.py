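import pytest

from codonaudit import AuditConfig, run_audit
from codonaudit.simulate import SyntheticGenomeSpec, generate_genome


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic genome under the default (planted) study conditions."""
    return generate_genome(SyntheticGenomeSpec())


@pytest.fixture(scope="session")
def default_report(default_dataset):
    """Full audit of the default synthetic genome."""
    ds = default_dataset
    return run_audit(
        ds.sequences, ds.gene_sets, ds.trna_pool, ds.expression, AuditConfig()
    )


@pytest.fixture(scope="session")
def unplanted_dataset():
    """Negative control: operon drawn from the background conditions."""
    return generate_genome(SyntheticGenomeSpec(planted_enabled=False))
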