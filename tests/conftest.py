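import pytest

from traitscreen.pipeline import desk_config, run_pipeline


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-scale screen (20 factors, r=20, 40 environments,
    ~17k season simulations), shared across tests that inspect its results."""
    outdir = tmp_path_factory.mktemp("desk_run")
    config = desk_config(seed=1, outdir=str(outdir))
    tables = run_pipeline(config)
    return config, tables
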