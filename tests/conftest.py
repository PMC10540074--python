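import pytest

from pangevo.simulate import make_end_to_end_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete miniature study (4 clusters x 5 genomes) shared by the
    pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("study") / "fixture"
    make_end_to_end_fixture(seed=7, outdir=outdir)
    return outdir
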