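import pytest

import promlit as pl


@pytest.fixture(scope="session")
def small_corpus():
    """The hand-written ~20-row fixture with its manifest."""
    return pl.fixture_small()


@pytest.fixture(scope="session")
def synthetic_corpus():
    """A mid-sized generated corpus shared by the slower tests."""
    config = pl.GeneratorConfig(seed=42, n_compounds=1500)
    return pl.generate(config), config


@pytest.fixture(scope="session")
def synthetic_pipeline(synthetic_corpus):
    """Set-1 pipeline outputs for the shared synthetic corpus."""
    (measurements, publications, manifest), _ = synthetic_corpus
    kept, audit = pl.curate(measurements, publications, pl.SET1_POLICY)
    records = pl.build_records(kept)
    cprofiles = pl.compound_profiles(records)
    return {
        "measurements": measurements,
        "publications": publications,
        "manifest": manifest,
        "kept": kept,
        "audit": audit,
        "records": records,
        "compound_profiles": cprofiles,
    }
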