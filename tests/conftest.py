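import numpy as np
import pytest

from reglocus.simulate import SimConfig, emit_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """In-study fixture tables written once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return emit_fixtures(out)


@pytest.fixture
def single_snp_config():
    """Minimal one-SNP panel at the replication-cohort scale."""
    from reglocus.simulate import SnpSpec

    return SimConfig(
        seed=0,
        snp_panel=(SnpSpec("rs_test", 46_349_000, 0.18),),
        causal_snp="rs_test",
        n_cases=200,
        n_controls=900,
    )
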