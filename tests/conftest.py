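import pytest
from hypothesis import HealthCheck, settings

from ntnl_forge import motifscan, synthdata

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """The default 60-gene study bed at seed 0."""
    return synthdata.generate_genome(synthdata.default_spec(0))


@pytest.fixture(scope="session")
def seed_profile():
    return motifscan.build_profile(synthdata.make_seed_alignment(8, 10))


@pytest.fixture(scope="session")
def written_bundle(default_bundle, tmp_path_factory):
    """The default bundle serialised to FASTA/GFF3/TSV."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = default_bundle.write(outdir)
    return default_bundle, paths
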